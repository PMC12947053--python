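"""Constructed fusion scenarios with known optimal weight orderings.

These small (32^3) scenarios pair a reference mask with two probability
sources — one informative, one weakly informative and noisy — arranged
so that either the global 2D prediction or the composite 3D prediction
carries the signal.  Optimising the fusion weights on such a scenario
must recover the constructed dominance (w3D > w2D when the 3D source is
informative, and vice versa), which is the desk-scale analogue of the
per-target weight orderings observed when the framework is trained on
real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import CompositeMap
from .volumes import LabelVolume, ProbabilityVolume

SCENARIOS = ("2d_dominant", "3d_dominant")


@dataclass
class ScenarioSpec:
    scenario: str = "3d_dominant"
    #: noise sd on the informative source (signal separation is 0.9 vs 0.1)
    noise_dominant: float = 0.05
    #: noise sd on the weak source (signal separation is 0.55 vs 0.45)
    noise_weak: float = 0.35
    grid: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.noise_dominant < 0 or self.noise_weak < 0:
            raise ValueError("noise levels must be >= 0")
        # the dominant source must stay informative: its 0.4 margin to the
        # 0.5 threshold has to dominate the noise
        if self.noise_dominant >= 0.4:
            raise ValueError(
                "noise_dominant too large: no source is informative enough"
            )


def make_fusion_scenario(
    spec: ScenarioSpec,
) -> tuple[ProbabilityVolume, CompositeMap, LabelVolume, str]:
    """Build (P2D, composite, reference, expected ordering) for the spec.

    The composite covers every voxel (coverage 1) so the weight ordering
    is identified purely by which source predicts the reference.
    Returns the expected ordering as ``"w3d>w2d"`` or ``"w2d>w3d"``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid
    g = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2.0
    ref = (sum((gi - c) ** 2 for gi in g) <= (0.3 * n) ** 2).astype(np.uint8)

    def source(informative: bool, noise: float) -> np.ndarray:
        base = np.where(ref == 1, 0.9, 0.1) if informative else np.where(
            ref == 1, 0.55, 0.45
        )
        return np.clip(base + rng.normal(0.0, noise, size=ref.shape), 0.0, 1.0)

    dominant_is_3d = spec.scenario == "3d_dominant"
    p3 = source(dominant_is_3d, spec.noise_dominant if dominant_is_3d else spec.noise_weak)
    p2 = source(not dominant_is_3d, spec.noise_dominant if not dominant_is_3d else spec.noise_weak)
    composite = CompositeMap(p3, np.ones(ref.shape, dtype=np.int64))
    expected = "w3d>w2d" if dominant_is_3d else "w2d>w3d"
    return (
        ProbabilityVolume(p2, target="WT"),
        composite,
        LabelVolume(ref, target="WT"),
        expected,
    )
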