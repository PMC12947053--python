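"""Greedy overlap-constrained selection of high-uncertainty subvolumes.

A cubic d×d×d window slides over the voxel-wise uncertainty map; each
candidate position is scored by the cumulative (summed) uncertainty it
encloses, computed exactly with a 3D summed-area table.  Candidates are
then accepted greedily in descending score order, rejecting any whose
volumetric overlap with an already-accepted kernel exceeds the overlap
constraint (default 40% of the kernel volume), and stopping once the
best remaining score falls below a fraction (default 10%) of the top
accepted score.  The kernel edge follows the power-of-two round-down
rule applied to the median tumor extent: 42 mm -> 32, 83 mm -> 64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelRegion:
    """A cubic subvolume: minimum-corner voxel index, edge, score, rank."""

    corner: tuple[int, int, int]
    d: int
    score: float = 0.0
    rank: int = -1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("kernel edge must be >= 1")

    def slices(self) -> tuple[slice, slice, slice]:
        i, j, k = self.corner
        return slice(i, i + self.d), slice(j, j + self.d), slice(k, k + self.d)


@dataclass
class SelectionConfig:
    d: int = 32
    max_overlap: float = 0.4
    stop_fraction: float = 0.1
    stride: int = 1
    #: optional absolute score floor; candidates below it are never accepted
    min_score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.max_overlap < 1:
            raise ValueError("max_overlap must lie in [0, 1)")
        if not 0 < self.stop_fraction <= 1:
            raise ValueError("stop_fraction must lie in (0, 1]")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def window_sums(u: np.ndarray, d: int, stride: int = 1) -> np.ndarray:
    """Exact d^3-window sums over all in-bounds corners at the stride.

    Uses a zero-padded 3D summed-area table; the entry at grid position
    (a, b, c) is the sum of ``u`` over the window with minimum corner
    (a*stride, b*stride, c*stride).
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 3:
        raise ValueError("uncertainty map must be 3D")
    if d > min(u.shape):
        raise ValueError(f"kernel edge {d} exceeds volume dimensions {u.shape}")
    sat = np.zeros(tuple(s + 1 for s in u.shape))
    sat[1:, 1:, 1:] = u.cumsum(0).cumsum(1).cumsum(2)
    nx, ny, nz = (np.arange(0, s - d + 1, stride) for s in u.shape)
    a, b, c = np.meshgrid(nx, ny, nz, indexing="ij")
    s = (
        sat[a + d, b + d, c + d]
        - sat[a, b + d, c + d]
        - sat[a + d, b, c + d]
        - sat[a + d, b + d, c]
        + sat[a, b, c + d]
        + sat[a, b + d, c]
        + sat[a + d, b, c]
        - sat[a, b, c]
    )
    return s


def overlap_fraction(a: KernelRegion, b: KernelRegion) -> float:
    """Shared voxels of two equal-edge kernels as a fraction of d^3."""
    if a.d != b.d:
        raise ValueError("kernels must share one edge length")
    inter = 1.0
    for ca, cb in zip(a.corner, b.corner):
        lo, hi = max(ca, cb), min(ca + a.d, cb + b.d)
        if hi <= lo:
            return 0.0
        inter *= hi - lo
    return inter / float(a.d**3)


def select_kernels(u: np.ndarray, config: SelectionConfig) -> list[KernelRegion]:
    """Greedy descending-score selection under the overlap constraint.

    Ties in score break by lexicographic corner order, so the selection
    is fully deterministic.  An all-zero uncertainty map yields an empty
    selection (nothing needs refinement).
    """
    scores = window_sums(u, config.d, config.stride)
    if scores.size == 0 or float(scores.max()) <= 0.0:
        return []
    flat = scores.ravel()
    # stable sort on (-score, corner) => descending score, lexicographic ties
    order = np.lexsort((np.arange(flat.size), -flat))
    shape = scores.shape
    accepted: list[KernelRegion] = []
    threshold = -np.inf
    for pos in order:
        score = float(flat[pos])
        if accepted and score < threshold:
            break
        if config.min_score is not None and score < config.min_score:
            break
        a, b, c = np.unravel_index(pos, shape)
        cand = KernelRegion(
            (int(a) * config.stride, int(b) * config.stride, int(c) * config.stride),
            config.d,
            score=score,
        )
        if all(
            overlap_fraction(cand, prev) <= config.max_overlap for prev in accepted
        ):
            accepted.append(
                KernelRegion(cand.corner, cand.d, score=score, rank=len(accepted))
            )
            if len(accepted) == 1:
                threshold = config.stop_fraction * score
    return accepted


def choose_kernel_size(median_extent: float) -> int:
    """Largest power of two not exceeding the median tumor extent (mm)."""
    if median_extent < 1:
        raise ValueError("median extent must be >= 1")
    return int(2 ** np.floor(np.log2(median_extent)))
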