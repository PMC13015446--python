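"""Block extraction and reassembly with overlap averaging.

Whole brain volumes are denoised blockwise: the volume is covered by the
smallest number of equally sized, possibly overlapping blocks, each block is
denoised independently, and the denoised blocks are assembled back with
voxelwise averaging over the overlapped regions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .volumes import Volume

__all__ = ["BlockGrid", "plan_blocks", "extract_blocks", "assemble_blocks"]


@dataclass
class BlockGrid:
    """Geometry of a blockwise cover of a volume.

    ``origins`` are 0-based corner coordinates of half-open blocks
    ``[origin, origin + block_shape)``; every block lies fully inside the
    volume and their union covers it.
    """

    block_shape: tuple[int, int, int]
    origins: list[tuple[int, int, int]]
    spatial_shape: tuple[int, int, int]

    @property
    def n_blocks(self) -> int:
        return len(self.origins)

    def to_json(self) -> str:
        return json.dumps(
            {
                "block_shape": list(self.block_shape),
                "origins": [list(o) for o in self.origins],
                "spatial_shape": list(self.spatial_shape),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BlockGrid":
        d = json.loads(text)
        return cls(
            tuple(d["block_shape"]),
            [tuple(o) for o in d["origins"]],
            tuple(d["spatial_shape"]),
        )


def _axis_origins(extent: int, block: int) -> list[int]:
    """Evenly spaced origins of the minimal k = ceil(extent/block) cover."""
    k = math.ceil(extent / block)
    if k == 1:
        return [0]
    last = extent - block
    # round to nearest integer on an even spacing from 0 to last
    return [round(i * last / (k - 1)) for i in range(k)]


def plan_blocks(spatial_shape, block_shape) -> BlockGrid:
    """Minimal even-overlap cover of ``spatial_shape`` by ``block_shape`` blocks.

    Per axis, ``k = ceil(extent / block)`` blocks are placed with origins
    evenly spaced from 0 to ``extent - block``.  A block extent larger than
    the volume extent is clamped to it (no padding is ever introduced).
    """
    spatial_shape = tuple(int(s) for s in spatial_shape)
    block_shape = tuple(int(b) for b in block_shape)
    if len(spatial_shape) != 3 or len(block_shape) != 3:
        raise ValueError("expected 3 spatial axes")
    if any(s <= 0 for s in spatial_shape) or any(b <= 0 for b in block_shape):
        raise ValueError("shapes must be positive")
    block_shape = tuple(min(b, s) for b, s in zip(block_shape, spatial_shape))
    per_axis = [_axis_origins(s, b) for s, b in zip(spatial_shape, block_shape)]
    origins = [(x, y, z) for x in per_axis[0] for y in per_axis[1] for z in per_axis[2]]
    return BlockGrid(block_shape, origins, spatial_shape)


def _check_grid(grid: BlockGrid, spatial_shape) -> None:
    if tuple(spatial_shape) != tuple(grid.spatial_shape):
        raise ValueError(f"grid was planned for {grid.spatial_shape}, volume is {tuple(spatial_shape)}")


def extract_blocks(volume: Volume, grid: BlockGrid) -> list[np.ndarray]:
    """Copy out each half-open block region (4D arrays, channel last)."""
    _check_grid(grid, volume.spatial_shape)
    data = volume.channels_view()
    bx, by, bz = grid.block_shape
    return [data[x : x + bx, y : y + by, z : z + bz].copy() for x, y, z in grid.origins]


def assemble_blocks(blocks: list[np.ndarray], grid: BlockGrid, spatial_shape=None) -> np.ndarray:
    """Assemble blocks into a volume, averaging voxels covered by several blocks.

    Returns a 4D (x, y, z, c) array; wrap with ``Volume.like`` to restore
    geometry metadata.
    """
    if spatial_shape is None:
        spatial_shape = grid.spatial_shape
    _check_grid(grid, spatial_shape)
    if len(blocks) != grid.n_blocks:
        raise ValueError(f"{len(blocks)} blocks for {grid.n_blocks} grid origins")
    n_channels = blocks[0].shape[3]
    acc = np.zeros(tuple(spatial_shape) + (n_channels,), dtype=float)
    count = np.zeros(tuple(spatial_shape) + (1,), dtype=float)
    bx, by, bz = grid.block_shape
    for blk, (x, y, z) in zip(blocks, grid.origins):
        if blk.shape != (bx, by, bz, n_channels):
            raise ValueError("block shape does not match grid block_shape")
        acc[x : x + bx, y : y + by, z : z + bz] += blk
        count[x : x + bx, y : y + by, z : z + bz] += 1.0
    if np.any(count == 0):
        raise ValueError("grid does not cover the volume")
    return acc / count
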