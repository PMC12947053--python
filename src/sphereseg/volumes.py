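"""Volumetric data types, NIfTI I/O, and the synthetic tumor phantom.

The framework operates on co-registered multi-parametric MRI (MP-MRI):
four channels in the fixed order FLAIR, T1, T1ce, T2, on a common voxel
grid that is assumed to be 1 mm isotropic (the standard BraTS convention).
Reference segmentations come as three nested binary targets:

* ET — enhancing tumor,
* TC — tumor core (ET plus necrotic / non-enhancing core, NCR/NET),
* WT — whole tumor (TC plus peritumoral edema, ED),

so ET ⊆ TC ⊆ WT voxel-wise.  The phantom generator emulates exactly this
structure with nested ellipsoids and a per-tissue contrast table, which
makes every downstream stage testable without any external dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

CHANNEL_NAMES = ("flair", "t1", "t1ce", "t2")
TARGETS = ("ET", "TC", "WT")

#: tissue classes used by the phantom, innermost tumor tissue last
TISSUE_CLASSES = ("background", "brain", "ED", "NCR", "ET")

#: default per-tissue mean intensity per channel (FLAIR, T1, T1ce, T2).
#: Values are on a normalised [0, 1] scale; edema is hyperintense on
#: FLAIR/T2, enhancing tumor is hyperintense on T1ce.
DEFAULT_CONTRAST: dict[str, tuple[float, float, float, float]] = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "brain": (0.40, 0.50, 0.50, 0.40),
    "ED": (0.80, 0.40, 0.45, 0.75),
    "NCR": (0.50, 0.30, 0.35, 0.60),
    "ET": (0.60, 0.45, 0.90, 0.55),
}


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class MPMRIVolume:
    """A 4-channel MRI volume: ``data`` has shape (4, X, Y, Z)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 4:
            raise ValueError(
                f"MPMRIVolume needs a (4, X, Y, Z) array, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("MPMRIVolume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        _warn_if_anisotropic(self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class LabelVolume:
    """A binary reference mask for one target (ET, TC or WT)."""

    data: np.ndarray
    target: str = "WT"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"LabelVolume must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"LabelVolume values must be binary, found {uniq}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)


@dataclass
class ProbabilityVolume:
    """Per-voxel probabilities in [0, 1] for one target."""

    data: np.ndarray
    target: str = "WT"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ProbabilityVolume must be 3D")
        if np.any(np.isnan(self.data)):
            raise ValueError("NaN probabilities are forbidden")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)


@dataclass
class BrainROI:
    """Binary intracranial mask restricting projection origins and metrics."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("BrainROI must be 3D")
        if not np.all(np.isin(np.unique(arr), (0, 1))):
            raise ValueError("BrainROI values must be binary")
        self.data = arr.astype(np.uint8)


def _warn_if_anisotropic(spacing: Sequence[float]) -> None:
    if len(set(float(s) for s in spacing)) > 1:
        warnings.warn(
            "non-isotropic spacing: the framework treats voxel and mm units "
            "as interchangeable at 1 mm isotropic resolution",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(
    path: str | Path,
    *,
    kind: str | None = None,
    target: str = "WT",
):
    """Read a NIfTI file as an :class:`MPMRIVolume` or :class:`LabelVolume`.

    A 4D file is interpreted as a multi-channel volume stored (X, Y, Z, 4)
    with the canonical channel order FLAIR, T1, T1ce, T2 — the order is a
    storage convention and is never guessed from filenames.  A 3D file is
    returned as a LabelVolume when ``kind='label'`` (values must be {0,1}),
    otherwise as a single-channel probability/intensity grid is not
    supported — use :func:`read_case` for per-modality files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine)
    if arr.ndim == 4:
        return MPMRIVolume(np.moveaxis(arr, -1, 0), spacing=spacing, affine=affine)
    if arr.ndim == 3:
        if kind == "probability":
            return ProbabilityVolume(arr, target=target, spacing=spacing, affine=affine)
        return LabelVolume(arr, target=target, spacing=spacing, affine=affine)
    raise ValueError(f"unsupported NIfTI dimensionality {arr.ndim}")


def read_case(
    channel_paths: Sequence[str | Path],
    *,
    channel_order: Sequence[str] = CHANNEL_NAMES,
) -> MPMRIVolume:
    """Assemble an MP-MRI volume from one single-channel file per modality.

    ``channel_paths`` must be given in the order named by ``channel_order``
    (default FLAIR, T1, T1ce, T2); the order is taken from the explicit
    argument, never inferred from filenames.
    """
    if tuple(channel_order) != CHANNEL_NAMES:
        order = [CHANNEL_NAMES.index(c) for c in channel_order]
        channel_paths = [channel_paths[order.index(i)] for i in range(4)]
    if len(channel_paths) != 4:
        raise ValueError("exactly 4 channel files required")
    arrs, spacing, affine = [], None, None
    for p in channel_paths:
        img = nib.load(str(Path(p)))
        arrs.append(np.asarray(img.dataobj, dtype=np.float64))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = np.asarray(img.affine)
    if len({a.shape for a in arrs}) > 1:
        raise ValueError("all channels must share one grid")
    return MPMRIVolume(np.stack(arrs), spacing=spacing, affine=affine)


def write_volume(vol, path: str | Path) -> Path:
    """Write any of the volume types to NIfTI (4D stored as X,Y,Z,C)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, MPMRIVolume):
        arr = np.moveaxis(vol.data, 0, -1)
    else:
        arr = vol.data
    affine = getattr(vol, "affine", None)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
    spacing = getattr(vol, "spacing", (1.0, 1.0, 1.0))
    img.header.set_zooms(tuple(spacing) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def save_probability(volume: ProbabilityVolume, path: str | Path) -> Path:
    """Write a probability volume to NIfTI; values are re-validated first."""
    if volume.data.min() < 0 or volume.data.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return write_volume(volume, path)


# ---------------------------------------------------------------------------
# Synthetic phantom


@dataclass
class PhantomSpec:
    """Recipe for a synthetic MP-MRI case with nested tumor subregions.

    Ellipsoid semi-axes are in mm, interpreted as voxels on the 1 mm grid.
    ``et``/``ncr``/``ed`` define the boundaries of ET, TC (= ET ∪ NCR/NET)
    and WT (= TC ∪ ED) respectively; each must contain the previous one.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    center: tuple[float, float, float] | None = None
    et_axes: tuple[float, float, float] = (6.0, 5.0, 5.0)
    ncr_axes: tuple[float, float, float] = (10.0, 9.0, 8.0)
    ed_axes: tuple[float, float, float] = (16.0, 14.0, 12.0)
    brain_axes: tuple[float, float, float] | None = None
    contrast: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.center is None:
            self.center = tuple(s / 2.0 for s in self.grid_shape)
        if self.brain_axes is None:
            self.brain_axes = tuple(0.45 * s for s in self.grid_shape)
        for inner, outer, names in (
            (self.et_axes, self.ncr_axes, ("ET", "NCR/NET")),
            (self.ncr_axes, self.ed_axes, ("NCR/NET", "ED")),
            (self.ed_axes, self.brain_axes, ("ED", "brain")),
        ):
            if any(a > b for a, b in zip(inner, outer)):
                raise ValueError(
                    f"{names[0]} ellipsoid not nested inside {names[1]} ellipsoid"
                )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "contrast"
        }
        payload["contrast"] = {k: list(v) for k, v in self.contrast.items()}
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        raw = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.items()
            if k != "contrast"
        } | {"contrast": {k: tuple(v) for k, v in raw.get("contrast", {}).items()}}
        return cls(**raw)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: Sequence[float],
    axes: Sequence[float],
) -> np.ndarray:
    """Voxel-center-in-ellipsoid mask: ((x-cx)/ax)^2 + ... <= 1."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MPMRIVolume, dict[str, LabelVolume], BrainROI]:
    """Generate a synthetic case: MP-MRI volume, nested labels, brain ROI.

    Deterministic for a fixed ``spec.seed``.  With ``noise_sd == 0`` the
    intensities equal the contrast-table means exactly per tissue class.
    """
    shape = tuple(spec.grid_shape)
    et = _ellipsoid_mask(shape, spec.center, spec.et_axes)
    tc = _ellipsoid_mask(shape, spec.center, spec.ncr_axes)
    wt = _ellipsoid_mask(shape, spec.center, spec.ed_axes)
    brain = _ellipsoid_mask(shape, spec.center, spec.brain_axes)
    tc |= et
    wt |= tc
    brain |= wt

    class_map = np.zeros(shape, dtype=np.uint8)  # 0 background
    class_map[brain] = 1
    class_map[wt] = 2  # ED
    class_map[tc] = 3  # NCR/NET
    class_map[et] = 4  # ET

    data = np.zeros((4,) + shape, dtype=np.float64)
    for idx, name in enumerate(TISSUE_CLASSES):
        means = spec.contrast[name if name in spec.contrast else name.upper()]
        for c in range(4):
            data[c][class_map == idx] = means[c]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    labels = {
        "ET": LabelVolume(et.astype(np.uint8), target="ET"),
        "TC": LabelVolume(tc.astype(np.uint8), target="TC"),
        "WT": LabelVolume(wt.astype(np.uint8), target="WT"),
    }
    return MPMRIVolume(data), labels, BrainROI(brain.astype(np.uint8))
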