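"""Morphogen gradients and extrinsic noise over the 1D rostrocaudal axis.

Retinoic acid (RA) diffuses from the rostral end and FGF from the caudal end.
Each deterministic profile is the steady state of a linear reaction-diffusion
balance, ``M(x) = M0 * exp(-d * sqrt(k / D))`` with ``d`` the distance from
the source boundary, degradation ``k`` (1/day) and diffusion ``D``
(length^2/day).

Temporal noise is extrinsic and multiplicative: time is divided into
intervals of length ``1/omega`` (noise frequency ``omega``, default 10/day)
and within each interval every morphogen level is multiplied by a factor
drawn uniformly from ``(1 - eta, 1 + eta)`` — independently per morphogen,
per interval and (by default) per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MORPHOGENS

__all__ = [
    "GradientParams",
    "NoiseParams",
    "MorphogenTrace",
    "steady_gradient",
    "sample_noise_trace",
    "uniform_trace",
]


@dataclass(frozen=True)
class GradientParams:
    """Steady-state gradient parameters for the RA/FGF pair.

    ``source_strength``, ``degradation`` and ``diffusion`` are per-morphogen
    (RA first, FGF second).  RA is sourced at the rostral boundary (x = 0),
    FGF at the caudal boundary (x = domain_length).
    """

    source_strength: tuple[float, float] = (5.0, 5.0)
    degradation: tuple[float, float] = (6.25, 69.44)
    diffusion: tuple[float, float] = (1.0, 1.0)
    domain_length: float = 1.0
    n_cells: int = 100

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.domain_length <= 0:
            raise ValueError("domain_length must be > 0")
        for m0, k, d in zip(self.source_strength, self.degradation, self.diffusion):
            if m0 < 0:
                raise ValueError("source strengths must be >= 0")
            if k <= 0 or d <= 0:
                raise ValueError("degradation and diffusion rates must be > 0")

    def positions(self) -> np.ndarray:
        """Cell-centre coordinates: n_cells evenly spaced points on
        ``[0, domain_length]``, rostral at 0."""
        return np.linspace(0.0, self.domain_length, self.n_cells)

    @property
    def spacing(self) -> float:
        return self.domain_length / (self.n_cells - 1)


def steady_gradient(params: GradientParams, morphogen: str) -> np.ndarray:
    """Deterministic per-cell level of one morphogen.

    ``M(x) = M0 * exp(-d * sqrt(k/D))`` with ``d`` the distance from the
    morphogen's source boundary (rostral for RA, caudal for FGF).
    """
    try:
        j = MORPHOGENS.index(morphogen)
    except ValueError:
        raise KeyError(f"unknown morphogen {morphogen!r}") from None
    x = params.positions()
    dist = x if morphogen == "RA" else params.domain_length - x
    decay = np.sqrt(params.degradation[j] / params.diffusion[j])
    return params.source_strength[j] * np.exp(-dist * decay)


def base_field(params: GradientParams) -> np.ndarray:
    """Deterministic ``(n_cells, 2)`` field of both morphogens (RA, FGF)."""
    return np.stack([steady_gradient(params, m) for m in MORPHOGENS], axis=-1)


@dataclass(frozen=True)
class NoiseParams:
    """Extrinsic-noise settings.

    ``frequency`` (1/day) sets the piecewise-constant interval length
    ``1/frequency``; ``amplitude`` is the half-width of the uniform
    multiplicative factor ``U(1 - eta, 1 + eta)``; ``per_cell`` draws an
    independent factor for every cell (local fluctuations) rather than one
    shared factor per morphogen across the whole domain.
    """

    frequency: float = 10.0
    amplitude: float = 0.3
    per_cell: bool = True

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("noise frequency must be > 0")
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("noise amplitude must be in [0, 1)")


@dataclass(frozen=True)
class MorphogenTrace:
    """A sampled piecewise-constant noisy morphogen field.

    ``base`` has shape ``(n_cells, 2)``; ``factors`` has shape
    ``(n_intervals, n_cells, 2)`` (broadcast from ``(n_intervals, 1, 2)``
    when the noise is shared across the domain).  The field is
    right-continuous at interval boundaries.
    """

    base: np.ndarray
    factors: np.ndarray
    interval: float
    duration: float

    @property
    def n_intervals(self) -> int:
        return self.factors.shape[0]

    @property
    def n_cells(self) -> int:
        return self.base.shape[0]

    def interval_of(self, t: float) -> int:
        if t < 0 or t > self.duration + 1e-12:
            raise ValueError(f"t={t} outside trace duration [0, {self.duration}]")
        return min(int(t / self.interval), self.n_intervals - 1)

    def levels(self, t: float) -> np.ndarray:
        """Field ``(n_cells, 2)`` at time ``t``."""
        return self.base * self.factors[self.interval_of(t)]

    def evaluate(self, t: float, cell: int) -> np.ndarray:
        """Per-morphogen level ``(RA, FGF)`` at time ``t`` for one cell."""
        return self.levels(t)[cell]

    def field_per_interval(self) -> np.ndarray:
        """Precomputed ``(n_intervals, n_cells, 2)`` field, for fast lookup."""
        return self.base * self.factors

    def to_frame(self):
        """Long-format factors (interval, morphogen, cell, factor)."""
        import pandas as pd

        n_int, n_cells, _ = np.broadcast_shapes(
            self.factors.shape, (self.n_intervals, self.n_cells, 2)
        )
        f = np.broadcast_to(self.factors, (n_int, n_cells, 2))
        idx = np.indices((n_int, n_cells))
        rows = []
        for j, m in enumerate(MORPHOGENS):
            rows.append(
                pd.DataFrame(
                    {
                        "interval": idx[0].ravel(),
                        "morphogen": m,
                        "cell": idx[1].ravel(),
                        "factor": f[:, :, j].ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def sample_noise_trace(
    noise: NoiseParams,
    duration: float,
    base: np.ndarray,
    rng: np.random.Generator,
) -> MorphogenTrace:
    """Sample the multiplicative noise factors over ``duration`` days.

    ``ceil(duration * frequency)`` intervals are drawn; each factor is
    uniform on ``(1 - eta, 1 + eta)``, independent per morphogen, per
    interval and (if ``per_cell``) per cell.  Reproducible from the supplied
    generator.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    base = np.asarray(base, dtype=float)
    if base.ndim != 2 or base.shape[1] != len(MORPHOGENS):
        raise ValueError("base field must have shape (n_cells, 2)")
    n_cells = base.shape[0]
    n_int = int(np.ceil(duration * noise.frequency - 1e-12))
    shape = (n_int, n_cells if noise.per_cell else 1, len(MORPHOGENS))
    eta = noise.amplitude
    if eta == 0.0:
        factors = np.ones(shape)
    else:
        factors = rng.uniform(1.0 - eta, 1.0 + eta, size=shape)
    return MorphogenTrace(
        base=base,
        factors=factors,
        interval=1.0 / noise.frequency,
        duration=duration,
    )


def uniform_trace(
    ra: float, fgf: float, n_cells: int, noise: NoiseParams, duration: float,
    rng: np.random.Generator,
) -> MorphogenTrace:
    """Noisy trace over a spatially homogeneous field (used for the
    RA-only differentiation protocol)."""
    base = np.tile(np.array([ra, fgf], dtype=float), (n_cells, 1))
    return sample_noise_trace(noise, duration, base, rng)
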