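"""Multi-cell, multi-replicate simulation protocols.

Two protocols from the study design:

* :func:`run_development` — a 1D tissue under opposing noisy RA/FGF
  gradients.  Cells are first relaxed to the morphogen-free steady state,
  then the gradients are switched on and development is integrated for
  ``t_dev`` days.  Replicates differ only in their noise realisation; stacking
  replicates gives the 2D (replicate x position) field from which occupancy
  profiles and boundary statistics are computed.
* :func:`run_differentiation` — a spatially homogeneous group of cells
  exposed to an RA step only (FGF = 0), emulating RA-driven motor-neuron
  differentiation of an ES-cell culture; every cell sees an independent noisy
  RA input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import morphogen as mg
from .network import NetworkSpec, integrate, relax_to_steady_state

__all__ = ["TissueConfig", "TissueResult", "run_development", "run_differentiation", "snapshot"]


@dataclass(frozen=True)
class TissueConfig:
    """Geometry, replication and integration settings of a tissue run."""

    n_cells: int = 100
    n_replicates: int = 50
    t_dev: float = 7.0
    dt: float = 0.01
    store_every: float = 0.1
    relax_tol: float = 1e-6
    relax_t_max: float = 100.0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.t_dev <= 0:
            raise ValueError("t_dev must be > 0")


@dataclass
class TissueResult:
    """Concentration array with provenance.

    ``data`` is indexed ``(replicate, cell, species, time)``; ``times`` are
    the stored time points (storage cadence in the config snapshot).
    """

    data: np.ndarray
    times: np.ndarray
    species: tuple[str, ...]
    config: dict
    seed: int | None
    replicate_seeds: tuple | None = None
    traces: list | None = None

    @property
    def n_replicates(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def time_index(self, t: float) -> int:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(
                f"t={t} outside stored range [{self.times[0]}, {self.times[-1]}]"
            )
        return int(np.argmin(np.abs(self.times - t)))

    def series(self, species: str) -> np.ndarray:
        """Full time course of one species, shape (replicate, cell, time)."""
        return self.data[:, :, self.species_index(species), :]

    def to_frame(self):
        """Long-format DataFrame (replicate, cell, species, time, value)."""
        import pandas as pd

        r, c, s, t = self.data.shape
        rep, cell, spec, time = np.indices((r, c, s, t))
        return pd.DataFrame(
            {
                "replicate": rep.ravel(),
                "cell": cell.ravel(),
                "species": np.array(self.species)[spec.ravel()],
                "time": self.times[time.ravel()],
                "value": self.data.ravel(),
            }
        )


def snapshot(result: TissueResult, t: float) -> np.ndarray:
    """State at the stored time nearest ``t``: shape (replicate, cell, species)."""
    return result.data[:, :, :, result.time_index(t)]


def _integrate_batch(
    spec: NetworkSpec,
    x0: np.ndarray,
    field_per_interval: np.ndarray,
    interval: float,
    t_span: float,
    dt: float,
    store_every: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a flat batch of cells under a piecewise-constant field.

    ``field_per_interval`` has shape (n_intervals, batch, 2).
    """
    n_int = field_per_interval.shape[0]

    def morph_at(t: float) -> np.ndarray:
        k = min(int((t + 1e-12) / interval), n_int - 1)
        return field_per_interval[k]

    return integrate(spec, x0, morph_at, t_span, dt=dt, store_every=store_every)


def _prerelax(spec: NetworkSpec, cfg: TissueConfig) -> np.ndarray:
    """Morphogen-free steady state of a single cell (cells are identical
    before the gradients are switched on), starting from all species at 0."""
    x0 = np.zeros(spec.n_species)
    return relax_to_steady_state(
        spec,
        x0,
        {"RA": 0.0, "FGF": 0.0},
        tol=cfg.relax_tol,
        t_max=cfg.relax_t_max,
        dt=cfg.dt,
    )


def run_development(
    spec: NetworkSpec,
    tissue: TissueConfig,
    gradient: mg.GradientParams,
    noise: mg.NoiseParams,
    seed: int,
) -> TissueResult:
    """Simulate the 1D tissue: pre-relax, switch on noisy gradients, develop.

    Each replicate gets an independent noise trace spawned from the master
    seed, so any replicate is reproducible in isolation and the result is
    deterministic given ``seed``.
    """
    if gradient.n_cells != tissue.n_cells:
        raise ValueError("gradient.n_cells must match tissue.n_cells")
    base = mg.base_field(gradient)
    x_ss = _prerelax(spec, tissue)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(tissue.n_replicates)
    traces = [
        mg.sample_noise_trace(noise, tissue.t_dev, base, np.random.default_rng(c))
        for c in children
    ]
    # stack replicates into one flat batch: (n_int, n_rep * n_cells, 2)
    fields = np.stack([tr.field_per_interval() for tr in traces], axis=1)
    n_int = fields.shape[0]
    flat = fields.reshape(n_int, tissue.n_replicates * tissue.n_cells, 2)

    x0 = np.tile(x_ss, (tissue.n_replicates * tissue.n_cells, 1))
    times, traj = _integrate_batch(
        spec, x0, flat, traces[0].interval, tissue.t_dev, tissue.dt, tissue.store_every
    )
    # (time, rep*cell, species) -> (rep, cell, species, time)
    data = traj.reshape(len(times), tissue.n_replicates, tissue.n_cells, spec.n_species)
    data = np.moveaxis(data, 0, -1)
    return TissueResult(
        data=data,
        times=times,
        species=spec.species,
        config={
            "protocol": "develop",
            "tissue": asdict(tissue),
            "gradient": asdict(gradient),
            "noise": asdict(noise),
        },
        seed=seed,
        replicate_seeds=tuple(c.spawn_key for c in children),
        traces=traces,
    )


def run_differentiation(
    spec: NetworkSpec,
    n_cells_group: int,
    ra_level: float,
    noise: mg.NoiseParams,
    duration: float,
    seed: int,
    dt: float = 0.01,
    store_every: float = 0.1,
    relax_tol: float = 1e-6,
    relax_t_max: float = 100.0,
) -> TissueResult:
    """RA-only stimulation of a homogeneous cell group (FGF forced to 0).

    Returns a single-replicate :class:`TissueResult` whose cell axis holds the
    group; cell-to-cell spread comes from independent noisy RA inputs.
    """
    if ra_level < 0:
        raise ValueError("ra_level must be >= 0")
    cfg = TissueConfig(
        n_cells=n_cells_group,
        n_replicates=1,
        t_dev=duration,
        dt=dt,
        store_every=store_every,
        relax_tol=relax_tol,
        relax_t_max=relax_t_max,
    )
    x_ss = _prerelax(spec, cfg)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trace = mg.uniform_trace(ra_level, 0.0, n_cells_group, noise, duration, rng)
    field = trace.field_per_interval()  # (n_int, n_cells, 2)
    x0 = np.tile(x_ss, (n_cells_group, 1))
    times, traj = _integrate_batch(
        spec, x0, field, trace.interval, duration, dt, store_every
    )
    data = np.moveaxis(traj, 0, -1)[np.newaxis, ...]
    return TissueResult(
        data=data,
        times=times,
        species=spec.species,
        config={
            "protocol": "differentiate",
            "tissue": asdict(cfg),
            "ra_level": ra_level,
            "noise": asdict(noise),
        },
        seed=seed,
        traces=[trace],
    )
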