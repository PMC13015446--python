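"""Image volumes, brain masks, repetition sets, and intensity standardization.

A :class:`Volume` holds a 3D scalar image or a 4D multi-channel image
(channel last, as in NIfTI's 4th dimension).  All denoising losses and
image-quality metrics in this package are restricted to a :class:`BrainMask`,
and network inputs/targets are standardized to zero mean / unit standard
deviation over the masked voxels of each channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BrainMask",
    "RepetitionSet",
    "StandardizationParams",
    "compute_standardization",
    "standardize",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]


@dataclass
class Volume:
    """A 3D (x, y, z) or 4D (x, y, z, c) intensity grid.

    Parameters
    ----------
    data
        Floating-point intensity array.  A trailing channel axis is optional.
    voxel_size
        Physical voxel extent in mm per spatial axis.
    channel_names
        Optional labels for the channel axis (e.g. ``"b0"``, ``"dwi_03"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3D or 4D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def channels_view(self) -> np.ndarray:
        """Return the data as a 4D (x, y, z, c) view, never copying if 4D."""
        if self.data.ndim == 4:
            return self.data
        return self.data[..., np.newaxis]

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with the same geometry but different data."""
        if data.ndim == 4 and data.shape[3] == 1 and self.data.ndim == 3:
            data = data[..., 0]
        return Volume(data, self.voxel_size, self.channel_names)


@dataclass
class BrainMask:
    """Boolean grid marking brain-tissue voxels of an associated Volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no true voxel")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class RepetitionSet:
    """An ordered list of co-registered noisy repetitions sharing one mask."""

    repetitions: list[Volume]
    mask: BrainMask

    def __post_init__(self) -> None:
        if len(self.repetitions) < 1:
            raise ValueError("need at least one repetition")
        ref = self.repetitions[0]
        for rep in self.repetitions[1:]:
            if rep.spatial_shape != ref.spatial_shape or rep.n_channels != ref.n_channels:
                raise ValueError("repetitions must share shape and channel count")
        if self.mask.spatial_shape != ref.spatial_shape:
            raise ValueError("mask shape does not match repetitions")

    @property
    def n(self) -> int:
        return len(self.repetitions)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.repetitions[0].spatial_shape

    @property
    def n_channels(self) -> int:
        return self.repetitions[0].n_channels

    def mean_volume(self) -> Volume:
        stack = np.stack([r.data for r in self.repetitions], axis=0)
        return self.repetitions[0].like(stack.mean(axis=0))


@dataclass
class StandardizationParams:
    """Per-channel mean and standard deviation of masked intensities."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.std = np.atleast_1d(np.asarray(self.std, dtype=float))
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have equal length")
        if np.any(self.std <= 0):
            raise ValueError("std must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.mean.size


class DegenerateInputError(ValueError):
    """Raised when masked intensities cannot support standardization."""


def compute_standardization(volume: Volume, mask: BrainMask) -> StandardizationParams:
    """Per-channel population mean/std of intensities inside the brain mask.

    Raises
    ------
    DegenerateInputError
        If any channel is constant inside the mask (zero variance).
    """
    if mask.spatial_shape != volume.spatial_shape:
        raise ValueError("mask shape does not match volume")
    vals = volume.channels_view()[mask.data]  # (n_masked, c)
    mean = vals.mean(axis=0)
    std = vals.std(axis=0)  # population std (ddof=0)
    if np.any(std == 0):
        bad = np.flatnonzero(std == 0).tolist()
        raise DegenerateInputError(f"constant intensity inside mask for channel(s) {bad}")
    return StandardizationParams(mean, std)


def standardize(volume: Volume, params: StandardizationParams, inverse: bool = False) -> Volume:
    """Apply (v - mu)/s per channel, or the inverse map v*s + mu.

    The same affine map is applied to every voxel, inside and outside the
    mask; only the parameters are mask-derived.
    """
    if params.n_channels != volume.n_channels:
        raise ValueError(
            f"params have {params.n_channels} channels, volume has {volume.n_channels}"
        )
    data = volume.channels_view().astype(float, copy=True)
    if inverse:
        data = data * params.std + params.mean
    else:
        data = (data - params.mean) / params.std
    return volume.like(data)


# ---------------------------------------------------------------------------
# NIfTI I/O: channels live in the 4th NIfTI dimension, voxel size in the header.

def load_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return Volume(data, tuple(float(z) for z in zooms))


def save_volume(volume: Volume, path) -> None:
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine), str(path))


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(np.asarray(img.dataobj) > 0)


def save_mask(mask: BrainMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), np.eye(4)), str(path))
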