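"""Downsampling pyramids for volumes and label lattices.

Intensities are reduced with a 2x2x2 box mean (partial edge blocks
average only the voxels that exist), labels with a 2x2x2 majority vote
(ties broken by the smallest label, so results are independent of
iteration order).  A pyramid level with factor ``f`` has per-axis extent
``ceil(dim / f)``; level planning keeps adding factor-of-two levels while
the finest existing level is still at or above the voxel budget and the
next level would not shrink the largest axis below ``min_extent``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyGridError
from .volume_io import compute_stats

DEFAULT_MIN_EXTENT = 32
DEFAULT_MAX_TOTAL_VOXELS = 2**22


@dataclass(frozen=True)
class LevelPlan:
    """Ordered power-of-two downsampling factors; 1 is the original."""

    factors: tuple[int, ...]

    def __post_init__(self) -> None:
        f = self.factors
        if not f or f[0] != 1:
            raise ValueError("level plan must start with factor 1")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("factors must be strictly increasing")
        if any(x & (x - 1) for x in f):
            raise ValueError("factors must be powers of two")

    def __iter__(self):
        return iter(self.factors)


def level_dims(dims: tuple[int, int, int], factor: int) -> tuple[int, int, int]:
    return tuple(math.ceil(d / factor) for d in dims)


def plan_levels(
    dims: tuple[int, int, int],
    min_extent: int = DEFAULT_MIN_EXTENT,
    max_total_voxels: int = DEFAULT_MAX_TOTAL_VOXELS,
) -> LevelPlan:
    """Choose pyramid factors for a grid of ``dims``.

    Factor 1 is always present.  Another level is appended while the
    current finest level still holds at least ``max_total_voxels`` voxels
    (i.e. the budget is an exclusive cap) and halving keeps the largest
    axis at or above ``min_extent``.
    """
    if any(d <= 0 for d in dims):
        raise EmptyGridError(f"non-positive dims {dims}")
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    factors = [1]
    while True:
        f = factors[-1]
        total = math.prod(level_dims(dims, f))
        nxt = f * 2
        if total < max_total_voxels:
            break
        if max(level_dims(dims, f)) <= min_extent:
            break  # already at or below the floor; halving further is pointless
        if max(level_dims(dims, nxt)) < min_extent:
            break
        factors.append(nxt)
    return LevelPlan(tuple(factors))


def _block_reduce_sum(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum and voxel count over 2x2x2 blocks (partial blocks at edges)."""
    out = np.asarray(data, dtype=np.float64)
    counts = []
    for axis in range(3):
        n = out.shape[axis]
        idx = np.arange(0, n, 2)
        out = np.add.reduceat(out, idx, axis=axis)
        counts.append(np.minimum(2, n - idx))
    cnt = (
        counts[0][:, None, None] * counts[1][None, :, None] * counts[2][None, None, :]
    )
    return out, cnt


def downsample_volume(data: np.ndarray, factor: int = 2) -> np.ndarray:
    """Halve a float volume by 2x2x2 box mean; edges use partial blocks."""
    if factor != 2:
        raise ValueError("pyramids are built by repeated halving (factor must be 2)")
    data = np.asarray(data)
    if data.size == 0:
        raise EmptyGridError("cannot downsample an empty grid")
    sums, cnt = _block_reduce_sum(data)
    return (sums / cnt).astype(np.float32)


def downsample_lattice(labels: np.ndarray, factor: int = 2) -> np.ndarray:
    """Halve a label lattice by 2x2x2 majority vote, smallest label wins ties.

    Background 0 participates like any other label.
    """
    if factor != 2:
        raise ValueError("pyramids are built by repeated halving (factor must be 2)")
    labels = np.asarray(labels)
    if labels.size == 0:
        raise EmptyGridError("cannot downsample an empty lattice")
    out_shape = tuple(math.ceil(d / 2) for d in labels.shape)
    # pad odd axes with a sentinel that never wins the vote
    sentinel = np.int64(labels.max()) + 1
    padded = np.full(tuple(2 * d for d in out_shape), sentinel, dtype=np.int64)
    padded[: labels.shape[0], : labels.shape[1], : labels.shape[2]] = labels
    blocks = (
        padded.reshape(out_shape[0], 2, out_shape[1], 2, out_shape[2], 2)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(*out_shape, 8)
    )
    # sort so that among tied counts argmax picks the smallest label
    s = np.sort(blocks, axis=-1)
    counts = (s[..., :, None] == s[..., None, :]).sum(axis=-1)
    counts[s == sentinel] = 0
    winners = np.take_along_axis(
        s, np.argmax(counts, axis=-1)[..., None], axis=-1
    )[..., 0]
    return winners.astype(labels.dtype)


def build_pyramid(data: np.ndarray, plan: LevelPlan, kind: str = "volume") -> dict:
    """Build the level->array map plus per-level summaries.

    Returns ``{"levels": {factor: array}, "stats": {factor: ...}}`` where
    the per-level summary is min/max/mean/sigma for ``kind="volume"`` and
    a label histogram ``{label: count}`` for ``kind="lattice"``.
    Level 1 is the input itself, bit-identical.
    """
    if kind not in ("volume", "lattice"):
        raise ValueError(f"unknown pyramid kind {kind!r}")
    data = np.asarray(data)
    down = downsample_volume if kind == "volume" else downsample_lattice
    levels: dict[int, np.ndarray] = {}
    current = data
    prev_f = None
    for f in plan:
        if prev_f is not None:
            for _ in range(int(math.log2(f // prev_f))):
                current = down(current)
        levels[f] = current
        prev_f = f
    if kind == "volume":
        stats = {f: compute_stats(arr) for f, arr in levels.items()}
    else:
        stats = {f: label_histogram(arr) for f, arr in levels.items()}
    return {"levels": levels, "stats": stats}


def label_histogram(labels: np.ndarray) -> dict[int, int]:
    values, counts = np.unique(np.asarray(labels), return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}
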