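"""Spherical (fisheye-style) slice deformation and its inverse.

Each 2D axial slice is remapped onto a virtual sphere tangent to the
image plane at a chosen projection origin.  The transform used here is a
gnomonic projection onto the tangent sphere with equidistant unrolling:
an output pixel at radial distance rho from the origin samples the
source image at radius

    s(rho) = R * tan(rho / R)

along the same direction, with inverse rho(s) = R * arctan(s / R).
Content near the origin is relatively magnified (local scale
ds/drho = sec^2(rho/R) equals 1 at the origin and grows with rho, i.e.
the periphery is compressed in the deformed view), while the full field
of view is retained up to the horizon rho = pi*R/2.  Varying the origin
over a uniform grid yields the test-time ensemble of deformed views from
which segmentation uncertainty is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import BrainROI


@dataclass(frozen=True)
class ProjectionOrigin:
    """0-based (row, col) pixel coordinates of a projection origin."""

    row: int
    col: int


@dataclass
class ProjectionParams:
    """Parameters of the spherical deformation.

    R is the virtual sphere radius in pixels; content beyond the horizon
    radius pi*R/2 from the origin is undefined under the forward map and
    takes ``fill`` (MR background is 0 after skull stripping).
    """

    radius: float = 64.0
    order: int = 1  # 0 nearest, 1 bilinear
    fill: float = 0.0
    output_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.order not in (0, 1):
            raise ValueError("interpolation order must be 0 or 1")


@dataclass
class DeformedSlice:
    data: np.ndarray  # (C, H, W) or (H, W)
    origin: ProjectionOrigin
    params: ProjectionParams = field(repr=False, default_factory=ProjectionParams)


def generate_origin_grid(
    height: int,
    width: int,
    interval: int,
    roi: np.ndarray | BrainROI | None = None,
) -> list[ProjectionOrigin]:
    """Uniform origin grid at a fixed pixel interval, optionally ROI-masked.

    Origins start at ``interval // 2`` in each dimension and repeat every
    ``interval`` pixels, row-major.  A 256x256 slice at the default
    8-pixel interval yields exactly 1024 origins.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if interval > min(height, width):
        raise ValueError("interval exceeds the slice dimensions")
    mask = None
    if roi is not None:
        mask = roi.data if isinstance(roi, BrainROI) else np.asarray(roi)
        if mask.shape != (height, width):
            raise ValueError("ROI slice shape mismatch")
    off = interval // 2
    origins = [
        ProjectionOrigin(r, c)
        for r in range(off, height, interval)
        for c in range(off, width, interval)
        if mask is None or mask[r, c]
    ]
    if not origins:
        raise ValueError(
            "no projection origins inside the ROI; use a denser interval"
        )
    return origins


def _radial_coords(
    out_shape: tuple[int, int],
    origin: ProjectionOrigin,
    radius: float,
    inverse: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source-sampling coordinates for the forward or inverse remap.

    Forward: output radius rho -> source radius R*tan(rho/R) (undefined at
    rho >= pi*R/2).  Inverse: source radius s -> deformed radius
    R*arctan(s/R) (always defined).  Returns (rows, cols, defined-mask).
    """
    rr, cc = np.meshgrid(
        np.arange(out_shape[0], dtype=np.float64),
        np.arange(out_shape[1], dtype=np.float64),
        indexing="ij",
    )
    dr, dc = rr - origin.row, cc - origin.col
    rho = np.hypot(dr, dc)
    if inverse:
        s = radius * np.arctan(rho / radius)
        defined = np.ones_like(rho, dtype=bool)
    else:
        horizon = np.pi * radius / 2.0
        defined = rho < horizon
        s = np.zeros_like(rho)
        s[defined] = radius * np.tan(rho[defined] / radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 0, s / np.maximum(rho, 1e-300), 1.0)
    return origin.row + dr * scale, origin.col + dc * scale, defined


def _remap(
    img: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    defined: np.ndarray,
    order: int,
    fill: float,
) -> np.ndarray:
    out = map_coordinates(
        np.asarray(img, dtype=np.float64),
        np.stack([rows, cols]),
        order=order,
        mode="grid-constant",  # blends with fill at the border instead of hard-clipping
        cval=fill,
    )
    out[~defined] = fill
    return out


def project_slice(
    slice_data: np.ndarray,
    origin: ProjectionOrigin,
    params: ProjectionParams,
) -> DeformedSlice:
    """Deform a (C, H, W) or (H, W) slice about a projection origin.

    All channels are remapped identically; the origin pixel maps to
    itself.  Raises if R is so small that the whole image collapses
    inside one pixel (pi*R/2 < 1).
    """
    img = np.asarray(slice_data, dtype=np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    h, w = img.shape[1:]
    if not (0 <= origin.row < h and 0 <= origin.col < w):
        raise ValueError("projection origin outside the slice")
    if np.pi * params.radius / 2.0 < 1.0:
        raise ValueError("sphere radius too small: entire image collapses")
    out_shape = params.output_shape or (h, w)
    rows, cols, defined = _radial_coords(out_shape, origin, params.radius, inverse=False)
    out = np.stack(
        [_remap(ch, rows, cols, defined, params.order, params.fill) for ch in img]
    )
    return DeformedSlice(out[0] if squeeze else out, origin, params)


def back_project(
    prediction: np.ndarray,
    origin: ProjectionOrigin,
    params: ProjectionParams,
    out_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pull a prediction on the deformed grid back to the original grid.

    An original-grid pixel at source radius s samples the deformed grid
    at rho(s) = R*arctan(s/R) < pi*R/2, so the pull-back is defined
    everywhere; the validity mask marks pixels whose sample lands inside
    the deformed image bounds.  Probabilities are clamped to [0, 1]
    after interpolation.
    """
    pred = np.asarray(prediction, dtype=np.float64)
    if pred.ndim != 2:
        raise ValueError("prediction must be a 2D grid")
    deformed_shape = params.output_shape or pred.shape
    if pred.shape != tuple(deformed_shape):
        raise ValueError(
            f"prediction shape {pred.shape} does not match deformed grid "
            f"{tuple(deformed_shape)}"
        )
    out_shape = out_shape or pred.shape
    rows, cols, _ = _radial_coords(out_shape, origin, params.radius, inverse=True)
    inside = (
        (rows >= 0)
        & (rows <= pred.shape[0] - 1)
        & (cols >= 0)
        & (cols <= pred.shape[1] - 1)
    )
    out = _remap(pred, rows, cols, np.ones_like(inside), params.order, params.fill)
    return np.clip(out, 0.0, 1.0), inside


def project_ensemble(
    slice_data: np.ndarray,
    origins: Sequence[ProjectionOrigin],
    params: ProjectionParams,
) -> list[DeformedSlice]:
    """One deformed multi-channel slice per origin, in origin-list order."""
    if len(origins) == 0:
        raise ValueError("empty origin list")
    return [project_slice(slice_data, o, params) for o in origins]
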