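"""Overlapping cubic blocks: splitting, filtering, reassembly, random crops.

Maps are processed in fixed-size cubes cut on a stride lattice.  The last
block along each axis is clamped inward so it stays flush with the map
boundary; maps smaller than one block are zero-padded up to block size and
the padding is cropped again at assembly time.  Overlapping predictions are
combined by a plain count-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_io import DensityMap

__all__ = ["BlockSet", "split_blocks", "filter_nonempty", "assemble_blocks",
           "random_crop", "axis_offsets"]


def axis_offsets(dim: int, block_size: int, stride: int) -> list[int]:
    """Stride-lattice start offsets along one axis, last one clamped inward."""
    if dim <= block_size:
        return [0]
    offsets = list(range(0, dim - block_size + 1, stride))
    if offsets[-1] != dim - block_size:
        offsets.append(dim - block_size)
    return offsets


@dataclass
class BlockSet:
    """Cubic sub-volumes plus the integer offsets of their low corners."""

    blocks: list[np.ndarray]
    offsets: list[tuple[int, int, int]]
    source_shape: tuple[int, int, int]
    block_size: int
    stride: int
    padding: tuple[int, int, int] = (0, 0, 0)  # zero-padding applied per axis (at the high end)

    def __post_init__(self):
        if len(self.blocks) != len(self.offsets):
            raise ValueError("blocks and offsets must have the same length")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("offsets must be unique")
        b = self.block_size
        for blk in self.blocks:
            if blk.shape != (b, b, b):
                raise ValueError(f"every block must be {b}^3, got {blk.shape}")

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(s + p for s, p in zip(self.source_shape, self.padding))


def split_blocks(dmap: DensityMap | np.ndarray, block_size: int,
                 stride: int) -> BlockSet:
    """Split a map into overlapping block_size^3 cubes on a stride lattice."""
    if block_size <= 0 or stride <= 0:
        raise ValueError("block_size and stride must be positive")
    if stride > block_size:
        raise ValueError("stride must not exceed block_size (coverage gap)")
    data = dmap.data if isinstance(dmap, DensityMap) else np.asarray(dmap)
    source_shape = data.shape
    padding = tuple(max(0, block_size - s) for s in source_shape)
    if any(padding):
        data = np.pad(data, tuple((0, p) for p in padding))
    axes = [axis_offsets(n, block_size, stride) for n in data.shape]
    offsets = [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]]
    blocks = [
        data[i:i + block_size, j:j + block_size, k:k + block_size].copy()
        for i, j, k in offsets
    ]
    return BlockSet(blocks, offsets, tuple(source_shape), block_size, stride,
                    padding)


def filter_nonempty(input_blocks: BlockSet, target_blocks: BlockSet,
                    min_fraction: float = 0.0) -> tuple[BlockSet, BlockSet]:
    """Keep only pairs whose *target* block contains structure.

    A pair survives when the target block has at least one voxel > 0 and its
    fraction of positive voxels is >= min_fraction.  Empty (all-zero) target
    blocks are always dropped.
    """
    if input_blocks.offsets != target_blocks.offsets:
        raise ValueError("input and target BlockSets must share offsets")
    keep = []
    for idx, tblk in enumerate(target_blocks.blocks):
        count = int((tblk > 0).sum())
        if count > 0 and count / tblk.size >= min_fraction:
            keep.append(idx)

    def subset(bs: BlockSet) -> BlockSet:
        return BlockSet([bs.blocks[i] for i in keep],
                        [bs.offsets[i] for i in keep],
                        bs.source_shape, bs.block_size, bs.stride, bs.padding)

    return subset(input_blocks), subset(target_blocks)


def assemble_blocks(blocks: BlockSet,
                    block_data: list[np.ndarray] | None = None) -> np.ndarray:
    """Mean-accumulate blocks back into a full array of source_shape.

    ``block_data`` substitutes processed blocks (e.g. network outputs) for
    the stored ones; offsets and geometry come from the BlockSet.
    """
    data = blocks.blocks if block_data is None else block_data
    if len(data) != len(blocks.offsets):
        raise ValueError("one array per offset required")
    b = blocks.block_size
    acc = np.zeros(blocks.padded_shape, dtype=np.float64)
    cnt = np.zeros(blocks.padded_shape, dtype=np.int32)
    for blk, (i, j, k) in zip(data, blocks.offsets):
        acc[i:i + b, j:j + b, k:k + b] += blk
        cnt[i:i + b, j:j + b, k:k + b] += 1
    if (cnt == 0).any():
        raise ValueError("BlockSet does not cover the full grid")
    out = acc / cnt
    sx, sy, sz = blocks.source_shape
    return out[:sx, :sy, :sz]


def random_crop(input_block: np.ndarray, target_block: np.ndarray,
                crop_size: int, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Cut the same uniformly random crop_size^3 corner crop from both blocks."""
    if input_block.shape != target_block.shape:
        raise ValueError("paired blocks must share a shape")
    edge = input_block.shape[0]
    if input_block.shape != (edge,) * 3:
        raise ValueError("blocks must be cubic")
    if crop_size > edge:
        raise ValueError("crop_size exceeds block edge")
    corner = rng.integers(0, edge - crop_size + 1, size=3)
    sl = tuple(slice(c, c + crop_size) for c in corner)
    return input_block[sl], target_block[sl]
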