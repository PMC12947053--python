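"""Projection-ensemble aggregation: mean map, binary mask, entropy map.

For every pixel the ensemble of back-projected predictions (one per
projection origin) is summarised three ways:

* mean probability over valid predictions (the global 2D prediction
  P2D),
* a binary mask, thresholded strictly above 0.5,
* Shannon entropy of the ensemble after linearly discretising the
  [0, 1] probability range into B bins (B = 100 by default):

      U = -sum_t f(t) * ln f(t)

  over the nonzero bin frequencies f(t).  Entropy is 0 at unanimity
  and ln k when k bins are equally filled, bounded by ln B.

Low entropy means the prediction is stable across deformed views (high
confidence); high entropy flags voxels — typically ambiguous boundaries
— where views disagree and local 3D refinement is worthwhile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .backends import SlicePredictor
from .projection import (
    ProjectionParams,
    back_project,
    generate_origin_grid,
    project_slice,
)
from .volumes import BrainROI, LabelVolume, MPMRIVolume, ProbabilityVolume

DEFAULT_BINS = 100


@dataclass
class PredictionStack:
    """Back-projected ensemble predictions for one slice.

    ``data`` has shape (num_origins, H, W); ``valid`` marks, per member,
    the pixels whose back-projection landed inside the deformed grid.
    """

    data: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("PredictionStack data must be (n, H, W)")
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape:
            raise ValueError("validity mask shape mismatch")
        checked = self.data[self.valid]
        if checked.size and (checked.min() < 0 or checked.max() > 1):
            raise ValueError("stack probabilities must lie in [0, 1]")
        if self.data.shape[0] < 2:
            warnings.warn("fewer than 2 ensemble members: entropy is degenerate")


@dataclass
class UncertaintyVolume:
    """Per-voxel Shannon entropy (nats) of the projection ensemble."""

    data: np.ndarray
    bins: int = DEFAULT_BINS
    #: pixels that had zero valid ensemble predictions (entropy forced to 0)
    no_valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < -1e-12 or self.data.max() > np.log(self.bins) + 1e-9:
            raise ValueError("entropy outside [0, ln(bins)]")


def _bin_indices(probs: np.ndarray, bins: int) -> np.ndarray:
    # uniform bins on [0,1]; the last bin is right-closed so p == 1.0 counts
    idx = np.floor(probs * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def entropy_map(stack: PredictionStack, bins: int = DEFAULT_BINS) -> UncertaintyVolume:
    """Eq.-style ensemble entropy per pixel over discretised predictions."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    n, h, w = stack.data.shape
    idx = _bin_indices(stack.data, bins)
    counts = np.zeros((bins, h * w), dtype=np.int64)
    flat_idx = idx.reshape(n, -1)
    flat_valid = stack.valid.reshape(n, -1)
    cols = np.arange(h * w)
    for i in range(n):
        sel = flat_valid[i]
        np.add.at(counts, (flat_idx[i, sel], cols[sel]), 1)
    total = counts.sum(axis=0)
    no_valid = (total == 0).reshape(h, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / np.maximum(total, 1)
        ent = -np.where(f > 0, f * np.log(np.maximum(f, 1e-300)), 0.0).sum(axis=0)
    ent = ent.reshape(h, w)
    ent[no_valid] = 0.0
    return UncertaintyVolume(ent, bins=bins, no_valid=no_valid)


def mean_probability(stack: PredictionStack) -> np.ndarray:
    """Per-pixel mean over valid ensemble predictions; invalid-only -> 0."""
    weights = stack.valid.astype(np.float64)
    total = weights.sum(axis=0)
    s = (stack.data * weights).sum(axis=0)
    return np.where(total > 0, s / np.maximum(total, 1.0), 0.0)


def binarize(mean: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask via a strictly-greater comparison (0.5 itself -> 0)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(mean) > threshold).astype(np.uint8)


def run_uncertainty_stage(
    volume: MPMRIVolume,
    predictor: SlicePredictor,
    interval: int = 16,
    params: ProjectionParams | None = None,
    roi: BrainROI | None = None,
    bins: int = DEFAULT_BINS,
    target: str = "WT",
) -> tuple[ProbabilityVolume, LabelVolume, UncertaintyVolume]:
    """Slice-by-slice ensemble prediction over the whole volume.

    For each axial slice (third axis): generate origins (restricted to
    the brain ROI when given), deform the 4-channel slice per origin,
    predict on each deformed view, back-project, then aggregate into the
    mean probability P2D, its binary mask, and the entropy map U2D.
    Fully deterministic given a deterministic backend.
    """
    params = params or ProjectionParams()
    _, h, w, depth = volume.data.shape
    p2d = np.zeros((h, w, depth))
    ent = np.zeros((h, w, depth))
    no_valid = np.zeros((h, w, depth), dtype=bool)
    for z in range(depth):
        roi_slice = roi.data[:, :, z] if roi is not None else None
        try:
            origins = generate_origin_grid(h, w, interval, roi_slice)
        except ValueError:
            warnings.warn(
                f"slice {z}: no origins inside ROI, falling back to full grid"
            )
            origins = generate_origin_grid(h, w, interval, None)
        preds = np.empty((len(origins), h, w))
        valid = np.empty((len(origins), h, w), dtype=bool)
        mp_slice = volume.data[:, :, :, z]
        for i, origin in enumerate(origins):
            deformed = project_slice(mp_slice, origin, params)
            prob = np.asarray(predictor(deformed.data), dtype=np.float64)
            preds[i], valid[i] = back_project(prob, origin, params, (h, w))
        stack = PredictionStack(preds, valid)
        p2d[:, :, z] = mean_probability(stack)
        u = entropy_map(stack, bins=bins)
        ent[:, :, z] = u.data
        no_valid[:, :, z] = u.no_valid
    prob_vol = ProbabilityVolume(p2d, target=target, spacing=volume.spacing)
    mask_vol = LabelVolume(
        binarize(p2d), target=target, spacing=volume.spacing
    )
    return prob_vol, mask_vol, UncertaintyVolume(ent, bins=bins, no_valid=no_valid)
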