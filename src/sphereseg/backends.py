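"""Pluggable segmenter backends.

The framework is backbone-agnostic: the 2D slice segmenter and the 3D
subvolume segmenter are callables satisfying a small contract, so a
full self-configuring U-Net can be dropped in by wrapping its inference
call.  For desk-scale runs and tests two deterministic backends are
provided:

* a mock logistic-threshold predictor, which scores each pixel/voxel by
  a sigmoid of one channel's intensity — through the spherical
  deformation and back-projection this produces genuine inter-projection
  variability near tissue boundaries, which is what the uncertainty
  stage consumes;
* a ground-truth oracle 3D predictor for constructing end-to-end
  improvement scenarios with a perfect local refiner.

A trainable neural backend is deliberately not bundled: no deep-learning
runtime is a dependency of this package.  The ``SlicePredictor`` /
``VolumePredictor`` protocols document the adapter surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class SlicePredictor(Protocol):
    """Maps a (4, H, W) slice to an (H, W) probability grid in [0, 1]."""

    name: str

    def __call__(self, slice_data: np.ndarray) -> np.ndarray: ...


@runtime_checkable
class VolumePredictor(Protocol):
    """Maps a (4, d, d, d) tensor to a (d, d, d) probability grid."""

    name: str

    def __call__(self, subvolume: np.ndarray) -> np.ndarray: ...


def _logistic(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


@dataclass
class MockThresholdPredictor:
    """Deterministic logistic soft-threshold on one input channel.

    Output is logistic((x[channel] - center) / softness) per pixel or
    voxel; works unchanged as a 2D slice predictor or 3D volume
    predictor since the operation is pointwise.
    """

    channel: int
    center: float
    softness: float
    name: str = "mock_threshold"

    def __post_init__(self) -> None:
        if self.softness <= 0:
            raise ValueError("softness must be positive")

    def __call__(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=np.float64)
        if data.ndim not in (3, 4) or data.shape[0] != 4:
            raise ValueError("expected a (4, ...) multi-channel input")
        if not (0 <= self.channel < data.shape[0]):
            raise IndexError(f"channel {self.channel} out of range")
        return _logistic((data[self.channel] - self.center) / self.softness)


def mock_threshold_predictor(
    channel: int, center: float, softness: float
) -> MockThresholdPredictor:
    """Construct the mock backend (valid as both 2D and 3D predictor)."""
    return MockThresholdPredictor(channel, center, softness)


@dataclass
class OracleVolumePredictor:
    """3D predictor that returns the reference label inside its crop.

    Used to construct scenarios where local refinement is perfect; a
    crop is addressed by the kernel corner set via :meth:`bind`.
    """

    label: np.ndarray  # full-grid reference (X, Y, Z)
    name: str = "oracle_3d"
    _corner: tuple[int, int, int] | None = None

    def bind(self, corner: tuple[int, int, int]) -> "OracleVolumePredictor":
        self._corner = tuple(int(c) for c in corner)
        return self

    def __call__(self, subvolume: np.ndarray) -> np.ndarray:
        if self._corner is None:
            raise RuntimeError("oracle predictor needs a bound kernel corner")
        d = subvolume.shape[-1]
        i, j, k = self._corner
        return np.asarray(
            self.label[i : i + d, j : j + d, k : k + d], dtype=np.float64
        )


def conformance_check(
    predictor: Callable[[np.ndarray], np.ndarray],
    example_input: np.ndarray,
) -> np.ndarray:
    """Validate the backend contract on one example; returns the output.

    Checks spatial shape preservation, the [0, 1] range, and determinism
    across two calls on identical input.
    """
    out = np.asarray(predictor(example_input))
    if out.shape != example_input.shape[1:]:
        raise ValueError(
            f"backend broke shape contract: {out.shape} != {example_input.shape[1:]}"
        )
    if np.any(np.isnan(out)) or out.min() < 0 or out.max() > 1:
        raise ValueError("backend output must lie in [0, 1]")
    again = np.asarray(predictor(example_input))
    if not np.array_equal(out, again):
        raise ValueError("backend is not deterministic on fixed input")
    return out
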