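"""End-to-end orchestration of the three-stage workflow.

Stage 1 (global): spherical-projection ensemble over every axial slice
-> mean 2D probability, binary mask, entropy uncertainty map.
Stage 2 (localisation): greedy overlap-constrained selection of cubic
high-uncertainty kernels on the entropy map.
Stage 3 (local + fusion): 3D prediction per kernel, composite average,
sigmoid-weighted fusion with the global map, final binarisation, and
metric reporting against the reference labels.

The :class:`PipelineConfig` captures every tunable with the documented
defaults: kernel edge 32 voxels for ET/TC and 64 for WT, 40% overlap
cap, 8-pixel origin interval at full 256x256 scale (coarser for desk
runs), sphere radius 64 px, and PSO with population 20 over 50
iterations when weight optimisation is requested.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import backends
from .fusion import FusionWeights, run_refinement_stage
from .localization import SelectionConfig, choose_kernel_size
from .metrics import evaluate_case
from .optimize import SwarmConfig, optimize_fusion_weights
from .projection import ProjectionParams
from .uncertainty import run_uncertainty_stage
from .volumes import (
    BrainROI,
    LabelVolume,
    MPMRIVolume,
    PhantomSpec,
    ProbabilityVolume,
    generate_phantom,
    write_volume,
)

DEFAULT_KERNEL_SIZE = {"ET": 32, "TC": 32, "WT": 64}

#: default mock 2D backend per target: (channel index, center, softness).
#: ET/TC threshold the T1ce channel (enhancing tissue is hyperintense
#: there); WT thresholds FLAIR (edema is hyperintense).  These are crude
#: single-channel classifiers by design — their boundary errors are what
#: the uncertainty-guided refinement corrects.
DEFAULT_MOCK_2D = {
    "ET": (2, 0.70, 0.05),
    "TC": (2, 0.60, 0.05),
    "WT": (0, 0.55, 0.05),
}


@dataclass
class PipelineConfig:
    target: str = "WT"
    interval: int = 16
    radius: float = 64.0
    d: int | None = None  # kernel edge; None -> per-target default
    max_overlap: float = 0.4
    stop_fraction: float = 0.1
    stride: int = 1
    bins: int = 100
    backend2d: dict[str, Any] = field(default_factory=lambda: {"type": "mock"})
    backend3d: dict[str, Any] = field(default_factory=lambda: {"type": "mock"})
    #: (w2d, w3d, b) triple, (w2d, w3d) pair, or the string "optimize"
    weights: Any = (1.0, 3.0, None)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in DEFAULT_KERNEL_SIZE:
            raise ValueError("target must be one of ET, TC, WT")
        if self.d is None:
            self.d = DEFAULT_KERNEL_SIZE[self.target]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["weights"] = list(self.weights) if isinstance(self.weights, tuple) else self.weights
        return yaml.safe_dump(d, sort_keys=False)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _build_backend2d(config: PipelineConfig):
    spec = config.backend2d
    if spec.get("type", "mock") == "mock":
        ch, center, soft = DEFAULT_MOCK_2D[config.target]
        return backends.mock_threshold_predictor(
            spec.get("channel", ch), spec.get("center", center), spec.get("softness", soft)
        )
    raise ValueError(
        f"unknown 2D backend {spec.get('type')!r}; plug external models in "
        "through the SlicePredictor contract"
    )


def _build_backend3d(config: PipelineConfig, label: LabelVolume | None):
    spec = config.backend3d
    kind = spec.get("type", "mock")
    if kind == "mock":
        ch, center, soft = DEFAULT_MOCK_2D[config.target]
        return backends.mock_threshold_predictor(
            spec.get("channel", ch), spec.get("center", center), spec.get("softness", soft)
        )
    if kind == "oracle":
        if label is None:
            raise ValueError("oracle 3D backend needs a reference label")
        return backends.OracleVolumePredictor(label.data)
    raise ValueError(f"unknown 3D backend {kind!r}")


def _effective_kernel_edge(d: int, grid_shape: tuple[int, int, int]) -> int:
    m = min(grid_shape)
    if d <= m:
        return d
    eff = choose_kernel_size(m)
    warnings.warn(
        f"kernel edge {d} exceeds the smallest volume dimension {m}; "
        f"using the largest fitting power of two, {eff}"
    )
    return eff


@dataclass
class PipelineResult:
    p2d: ProbabilityVolume
    mask2d: LabelVolume
    uncertainty: Any
    kernels: list
    composite: Any
    fused: ProbabilityVolume
    mask_final: LabelVolume
    weights: FusionWeights
    metrics_2d: dict | None
    metrics_fused: dict | None


def run_case(
    volume: MPMRIVolume,
    config: PipelineConfig,
    roi: BrainROI | None = None,
    reference: LabelVolume | None = None,
) -> PipelineResult:
    """Run the full three-stage pipeline on one case.

    ``reference`` is required when the config asks for weight
    optimisation or an oracle 3D backend, and enables metric reporting.
    """
    predictor2d = _build_backend2d(config)
    p2d, mask2d, u2d = run_uncertainty_stage(
        volume,
        predictor2d,
        interval=config.interval,
        params=ProjectionParams(radius=config.radius),
        roi=roi,
        bins=config.bins,
        target=config.target,
    )
    sel = SelectionConfig(
        d=_effective_kernel_edge(config.d, volume.grid_shape),
        max_overlap=config.max_overlap,
        stop_fraction=config.stop_fraction,
        stride=config.stride,
    )
    predictor3d = _build_backend3d(config, reference)

    if isinstance(config.weights, str) and config.weights == "optimize":
        if reference is None:
            raise ValueError("weight optimisation requires a reference label")
        # stage the refinement once with placeholder weights to freeze the
        # composite, then search (w2D, w3D) on the frozen maps
        _, _, composite, kernels = run_refinement_stage(
            volume, u2d, p2d, predictor3d, sel, FusionWeights(1.0, 1.0)
        )
        weights, _ = optimize_fusion_weights(
            [(p2d, composite, reference)], SwarmConfig(seed=config.seed)
        )
    else:
        w = tuple(config.weights)
        weights = FusionWeights(w[0], w[1], b=w[2] if len(w) > 2 else None)

    fused, mask_final, composite, kernels = run_refinement_stage(
        volume, u2d, p2d, predictor3d, sel, weights
    )
    metrics_2d = metrics_fused = None
    if reference is not None:
        metrics_2d = evaluate_case(mask2d, reference, volume.spacing)
        metrics_fused = evaluate_case(mask_final, reference, volume.spacing)
    return PipelineResult(
        p2d, mask2d, u2d, kernels, composite, fused, mask_final, weights,
        metrics_2d, metrics_fused,
    )


def write_artifacts(
    result: PipelineResult, out_dir: str | Path, config: PipelineConfig
) -> dict[str, str]:
    """Persist every intermediate with provenance metadata; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.target.lower()
    paths = {
        "p2d": write_volume(result.p2d, out / f"p2d_{t}.nii.gz"),
        "mask2d": write_volume(result.mask2d, out / f"mask2d_{t}.nii.gz"),
        "uncertainty": write_volume(
            ProbabilityVolumeLike(result.uncertainty.data), out / f"uncertainty_{t}.nii.gz"
        ),
        "pfused": write_volume(result.fused, out / f"pfused_{t}.nii.gz"),
        "mask_final": write_volume(result.mask_final, out / f"mask_final_{t}.nii.gz"),
        "coverage": write_volume(
            ProbabilityVolumeLike(result.composite.coverage.astype(float)),
            out / f"coverage_{t}.nii.gz",
        ),
    }
    kernels_payload = [
        {"corner": list(k.corner), "d": k.d, "score": k.score, "rank": k.rank}
        for k in result.kernels
    ]
    (out / f"kernels_{t}.json").write_text(json.dumps(kernels_payload, indent=2))
    paths["kernels"] = out / f"kernels_{t}.json"
    w = result.weights
    meta = {
        "target": config.target,
        "w2d": w.w2d,
        "w3d": w.w3d,
        "b": w.b,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "metrics_2d": result.metrics_2d,
        "metrics_fused": result.metrics_fused,
    }
    (out / f"run_{t}.json").write_text(json.dumps(meta, indent=2, default=float))
    paths["run_meta"] = out / f"run_{t}.json"
    return {k: str(v) for k, v in paths.items()}


@dataclass
class ProbabilityVolumeLike:
    """Thin wrapper so non-probability grids reuse the NIfTI writer."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None


def simulate_cases(
    out_dir: str | Path,
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[Path]:
    """Write ``n_cases`` phantom case directories with a manifest.

    Case-to-case variation comes from jittering the tumor ellipsoid axes
    and the noise realisation, both derived deterministically from
    ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    dirs = []
    for i in range(n_cases):
        jitter = rng.uniform(0.85, 1.15, size=3)
        spec = PhantomSpec(
            grid_shape=base.grid_shape,
            et_axes=tuple(a * j for a, j in zip(base.et_axes, jitter)),
            ncr_axes=tuple(a * j for a, j in zip(base.ncr_axes, jitter)),
            ed_axes=tuple(a * j for a, j in zip(base.ed_axes, jitter)),
            contrast=base.contrast,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, labels, roi = generate_phantom(spec)
        case_dir = out / f"case_{i:03d}"
        case_dir.mkdir(exist_ok=True)
        for c, name in enumerate(("flair", "t1", "t1ce", "t2")):
            write_volume(
                ProbabilityVolumeLike(volume.data[c]), case_dir / f"{name}.nii.gz"
            )
        for tgt, lab in labels.items():
            write_volume(lab, case_dir / f"seg_{tgt.lower()}.nii.gz")
        write_volume(ProbabilityVolumeLike(roi.data.astype(float)), case_dir / "roi.nii.gz")
        spec.to_json(case_dir / "phantom_spec.json")
        dirs.append(case_dir)
    manifest = {"n_cases": n_cases, "seed": seed, "cases": [d.name for d in dirs]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return dirs


def load_case(case_dir: str | Path) -> tuple[MPMRIVolume, dict[str, LabelVolume], BrainROI]:
    """Load a simulated (or equivalently laid out) case directory."""
    from .volumes import read_case, read_volume

    case_dir = Path(case_dir)
    vol = read_case([case_dir / f"{n}.nii.gz" for n in ("flair", "t1", "t1ce", "t2")])
    labels = {
        tgt: read_volume(case_dir / f"seg_{tgt.lower()}.nii.gz", target=tgt)
        for tgt in ("ET", "TC", "WT")
    }
    roi_path = case_dir / "roi.nii.gz"
    if roi_path.exists():
        import nibabel as nib

        roi = BrainROI(np.asarray(nib.load(str(roi_path)).dataobj).astype(np.uint8))
    else:
        roi = BrainROI(np.ones(vol.grid_shape, dtype=np.uint8))
    return vol, labels, roi
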