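"""Local 3D refinement and coverage-aware probability fusion.

For every selected high-uncertainty kernel the corresponding 4-channel
MP-MRI subvolume is cropped (no resampling) and handed to the local 3D
segmenter.  Overlapping local predictions are averaged voxel-wise into a
composite 3D probability, with a coverage count N per voxel.  The final
probability is then

    P_fused = sigmoid(w2D * P2D + w3D * P3Dcomposite + b)   where N >= 1
    P_fused = P2D                                           where N == 0

with non-negative weights w2D, w3D.  Voxels no kernel covers keep the
global 2D prediction untouched — the refinement is strictly local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .localization import KernelRegion, SelectionConfig, select_kernels
from .uncertainty import UncertaintyVolume, binarize
from .volumes import LabelVolume, MPMRIVolume, ProbabilityVolume


@dataclass
class LocalPrediction:
    """A (d, d, d) probability grid for one kernel."""

    kernel: KernelRegion
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (self.kernel.d,) * 3:
            raise ValueError("local prediction shape must match the kernel edge")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("local probabilities must lie in [0, 1]")


@dataclass
class CompositeMap:
    """Voxel-wise average of overlapping local predictions + coverage N."""

    probs: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.shape != self.coverage.shape:
            raise ValueError("probs and coverage must share one grid")


@dataclass
class FusionWeights:
    """Eq.-(2)-style fusion parameters; both weights are non-negative.

    ``b=None`` selects the calibration-preserving default
    b = -(w2D + w3D) / 2, which maps P2D = P3D = 0.5 to a fused 0.5.
    """

    w2d: float
    w3d: float
    b: float | None = None

    def __post_init__(self) -> None:
        if self.w2d < 0 or self.w3d < 0:
            raise ValueError("fusion weights must be non-negative")
        if self.b is None:
            self.b = -(self.w2d + self.w3d) / 2.0
        if not np.isfinite(self.b):
            raise ValueError("bias must be finite")


def extract_subvolume(volume: MPMRIVolume, kernel: KernelRegion) -> np.ndarray:
    """Exact (4, d, d, d) crop of the MP-MRI volume at the kernel."""
    shape = volume.grid_shape
    for c, s in zip(kernel.corner, shape):
        if c < 0 or c + kernel.d > s:
            raise ValueError(f"kernel {kernel.corner} (d={kernel.d}) out of bounds")
    sl = kernel.slices()
    return volume.data[:, sl[0], sl[1], sl[2]].copy()


def extract_label(label: LabelVolume, kernel: KernelRegion) -> np.ndarray:
    """Paired (d, d, d) label crop for training/validating local backends."""
    sl = kernel.slices()
    return label.data[sl[0], sl[1], sl[2]].copy()


def build_composite(
    locals_: Sequence[LocalPrediction], grid_shape: tuple[int, int, int]
) -> CompositeMap:
    """Average local predictions per voxel; coverage counts contributors."""
    acc = np.zeros(grid_shape)
    cov = np.zeros(grid_shape, dtype=np.int64)
    seen: set[tuple] = set()
    for lp in locals_:
        key = (lp.kernel.corner, lp.kernel.d)
        if key in seen:
            warnings.warn(f"duplicate kernel {key} counted twice in composite")
        seen.add(key)
        sl = lp.kernel.slices()
        acc[sl] += lp.probs
        cov[sl] += 1
    probs = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0)
    return CompositeMap(probs, cov)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def fuse(
    p2d: ProbabilityVolume | np.ndarray,
    composite: CompositeMap,
    weights: FusionWeights,
) -> ProbabilityVolume:
    """Coverage-dependent sigmoid-weighted fusion of 2D and 3D predictions.

    Where coverage is zero the 2D probability passes through bit-identical
    (no sigmoid is applied); elsewhere the weighted linear combination is
    squashed through the logistic function.
    """
    p2d_arr = p2d.data if isinstance(p2d, ProbabilityVolume) else np.asarray(p2d)
    if p2d_arr.shape != composite.probs.shape:
        raise ValueError("P2D and composite grids must match")
    covered = composite.coverage >= 1
    fused = p2d_arr.copy()
    z = (
        weights.w2d * p2d_arr[covered]
        + weights.w3d * composite.probs[covered]
        + weights.b
    )
    fused[covered] = _sigmoid(z)
    target = p2d.target if isinstance(p2d, ProbabilityVolume) else "WT"
    return ProbabilityVolume(fused, target=target)


def run_refinement_stage(
    volume: MPMRIVolume,
    u2d: UncertaintyVolume,
    p2d: ProbabilityVolume,
    predictor3d: Callable[[np.ndarray], np.ndarray],
    config: SelectionConfig,
    weights: FusionWeights,
) -> tuple[ProbabilityVolume, LabelVolume, CompositeMap, list[KernelRegion]]:
    """select -> extract -> predict -> composite -> fuse -> binarize.

    An empty kernel selection degrades gracefully: the fused output is
    the 2D prediction and the final mask its strict-0.5 binarisation.
    The oracle backend's per-kernel ``bind`` hook is honoured when
    present so label-oracle predictors know which crop they see.
    """
    kernels = select_kernels(u2d.data, config)
    grid_shape = volume.grid_shape
    if not kernels:
        fused = ProbabilityVolume(p2d.data.copy(), target=p2d.target)
        composite = CompositeMap(
            np.zeros(grid_shape), np.zeros(grid_shape, dtype=np.int64)
        )
    else:
        locals_ = []
        for kern in kernels:
            sub = extract_subvolume(volume, kern)
            if hasattr(predictor3d, "bind"):
                predictor3d.bind(kern.corner)
            locals_.append(LocalPrediction(kern, predictor3d(sub)))
        composite = build_composite(locals_, grid_shape)
        fused = fuse(p2d, composite, weights)
    mask = LabelVolume(binarize(fused.data), target=p2d.target)
    return fused, mask, composite, kernels
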