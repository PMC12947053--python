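"""Global-best particle swarm optimisation of the fusion weights.

Each particle is a candidate weight vector (w2D, w3D) — optionally
(w2D, w3D, b) — and the swarm maximises a scalar objective, by default
the mean Dice similarity coefficient of the fused-and-binarised
segmentation over a set of training cases.  The swarm follows the
standard gbest update

    v <- inertia*v + c_cog*r1*(pbest - x) + c_soc*r2*(gbest - x)
    x <- clip(x + v, bounds)

with positions clamped to the feasible box, which enforces the
non-negativity of both weights.  Defaults: population 20, 50
iterations, inertia 0.72, cognitive = social = 1.49, velocity clamped
to half the box width per dimension.  Fully reproducible under a fixed
seed; the per-iteration global-best trace is returned and is
non-decreasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fusion import CompositeMap, FusionWeights, fuse
from .metrics import dice
from .uncertainty import binarize
from .volumes import LabelVolume, ProbabilityVolume


@dataclass
class SwarmConfig:
    population: int = 20
    iterations: int = 50
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds: tuple[tuple[float, float], ...] = ((0.0, 5.0), (0.0, 5.0))
    velocity_clamp_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for lo, hi in self.bounds:
            if hi <= lo:
                raise ValueError("each bound must be (low, high) with high > low")


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray = field(repr=False)


def pso_maximize(
    objective: Callable[[np.ndarray], float], config: SwarmConfig
) -> SwarmResult:
    """Maximise ``objective`` over the config's box with gbest PSO.

    NaN objective values are treated as -inf with a warning; the
    returned trace holds the global-best value after each iteration.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    width = hi - lo
    vmax = config.velocity_clamp_frac * width
    ndim = len(config.bounds)

    def safe_eval(x: np.ndarray) -> float:
        val = float(objective(x))
        if np.isnan(val):
            warnings.warn("objective returned NaN; treating as -inf")
            return -np.inf
        return val

    pos = lo + rng.random((config.population, ndim)) * width
    vel = (rng.random((config.population, ndim)) - 0.5) * width
    pbest = pos.copy()
    pbest_val = np.array([safe_eval(p) for p in pos])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        r1 = rng.random((config.population, ndim))
        r2 = rng.random((config.population, ndim))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for p in range(config.population):
            val = safe_eval(pos[p])
            if val > pbest_val[p]:
                pbest_val[p] = val
                pbest[p] = pos[p].copy()
                if val > gbest_val:
                    gbest_val = val
                    gbest = pos[p].copy()
        trace[it] = gbest_val
    return SwarmResult(gbest, gbest_val, trace)


def dsc_objective(
    cases: Sequence[tuple[ProbabilityVolume | np.ndarray, CompositeMap, LabelVolume]],
    b_policy: str | float = "centered",
) -> Callable[[np.ndarray], float]:
    """Mean-DSC objective over frozen training cases, as a pure function.

    Each case is (P2D, composite 3D map, reference label).  ``b_policy``
    controls the fusion bias: ``"centered"`` uses the calibration default
    b = -(w2D + w3D)/2, a float fixes it, and ``"optimize"`` expects the
    particle vector to carry b as a third dimension.
    """
    if not cases:
        raise ValueError("at least one training case is required")
    for _, _, ref in cases:
        if ref.data.sum() == 0:
            raise ValueError("empty reference labels are not usable for DSC tuning")

    def objective(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=np.float64)
        if b_policy == "optimize":
            w = FusionWeights(x[0], x[1], b=float(x[2]))
        elif b_policy == "centered":
            w = FusionWeights(x[0], x[1])
        else:
            w = FusionWeights(x[0], x[1], b=float(b_policy))
        total = 0.0
        for p2d, comp, ref in cases:
            fused = fuse(p2d, comp, w)
            total += dice(binarize(fused.data), ref.data)
        return total / len(cases)

    return objective


def optimize_fusion_weights(
    cases: Sequence[tuple[ProbabilityVolume | np.ndarray, CompositeMap, LabelVolume]],
    config: SwarmConfig | None = None,
    b_policy: str | float = "centered",
) -> tuple[FusionWeights, SwarmResult]:
    """Convenience wrapper: PSO over the DSC objective for one target."""
    config = config or SwarmConfig()
    if b_policy == "optimize" and len(config.bounds) == 2:
        config = SwarmConfig(
            **{
                **config.__dict__,
                "bounds": config.bounds + ((-5.0, 5.0),),
            }
        )
    result = pso_maximize(dsc_objective(cases, b_policy), config)
    x = result.best_position
    if b_policy == "optimize":
        weights = FusionWeights(x[0], x[1], b=float(x[2]))
    elif b_policy == "centered":
        weights = FusionWeights(x[0], x[1])
    else:
        weights = FusionWeights(x[0], x[1], b=float(b_policy))
    return weights, result
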