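"""Sigmoidal-relaxation ODE framework for small gene/miRNA networks.

Each species :math:`X_i` (a dimensionless activity in ``[0, 1]``) relaxes on a
time scale :math:`1/\\gamma_i` toward the value of a logistic response function
of its summed regulatory input,

.. math::

    \\frac{dX_i}{dt} = \\gamma_i \\left( F(u_i) - X_i \\right), \\qquad
    F(u) = \\frac{1}{1 + e^{-\\sigma u}}, \\qquad
    u_i = b_i + \\sum_j \\omega_{j \\to i} X_j
          + \\omega_{RA \\to i}\\,RA + \\omega_{FGF \\to i}\\,FGF,

where :math:`b_i` is a basal offset, :math:`\\sigma` a shared steepness, and
:math:`\\omega_{j \\to i}` signed influence coefficients.  The two morphogens
(retinoic acid and FGF) enter as external inputs.  One time unit corresponds
to roughly one day of development.

The default instantiation is a five-species Hoxa5/Hoxc8 network (mRNA and
protein separated for each gene, plus a miRNA node ``mir_x``); see
:func:`default_network` and the packaged config for the calibrated parameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "MORPHOGENS",
    "DEFAULT_SPECIES",
    "MutantKind",
    "NetworkSpec",
    "NumericalIntegrationError",
    "ConvergenceError",
    "sigmoid",
    "regulatory_input",
    "derivatives",
    "integrate",
    "relax_to_steady_state",
    "apply_mutant",
    "default_network",
    "load_network",
]

#: External inputs, in column order after the species columns of ``omega``.
MORPHOGENS = ("RA", "FGF")

#: Species order of the default Hoxa5/Hoxc8/mir-x network.
DEFAULT_SPECIES = (
    "hoxa5_mRNA",
    "hoxa5_protein",
    "hoxc8_mRNA",
    "hoxc8_protein",
    "mir_x",
)

#: Basal offset used to silence mir-x production in the Dicer-null mutant.
DICER_NULL_BASAL = -100.0

#: Fold change of the mir-x relaxation rate in the fast-mir-x mutant.
MIRX_FAST_FACTOR = 10.0


class NumericalIntegrationError(RuntimeError):
    """Non-finite values appeared during integration."""


class ConvergenceError(RuntimeError):
    """Steady-state relaxation did not converge within ``t_max``."""


class MutantKind(str, enum.Enum):
    """In-silico genotypes of the miRNA node.

    ``dicer_null`` silences mir-x production by driving its basal offset to a
    large negative value (the sigmoid then evaluates to ~0, so mir-x decays
    dynamically).  ``mirx_fast`` multiplies the mir-x relaxation rate tenfold.
    ``mirx_null`` removes the node altogether: every edge into or out of
    mir-x is zeroed and the species is clamped at 0.
    """

    WILD_TYPE = "wild_type"
    DICER_NULL = "dicer_null"
    MIRX_FAST = "mirx_fast"
    MIRX_NULL = "mirx_null"


@dataclass(frozen=True)
class NetworkSpec:
    """Parameter set of a sigmoidal-relaxation network.

    Parameters
    ----------
    species
        Ordered, unique species identifiers.
    gamma
        Per-species relaxation rates (1/day), strictly positive.
    sigma
        Shared sigmoid steepness, strictly positive.
    basal
        Per-species basal offsets entering the sigmoid argument.
    omega
        Signed influence matrix of shape ``(n, n + 2)``; rows are targets,
        columns are the species followed by the two morphogen inputs
        (``RA``, ``FGF``).
    clamp
        Optional per-species clamp values (NaN = free).  A clamped species is
        pinned at the given value and its derivative forced to zero; used for
        the mir-x-null genotype.
    """

    species: tuple[str, ...]
    gamma: np.ndarray
    sigma: float
    basal: np.ndarray
    omega: np.ndarray
    clamp: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.species)
        if len(set(self.species)) != n:
            raise ValueError("species identifiers must be unique")
        gamma = np.asarray(self.gamma, dtype=float)
        basal = np.asarray(self.basal, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        if gamma.shape != (n,) or basal.shape != (n,):
            raise ValueError("gamma and basal must have one entry per species")
        if np.any(gamma < 0):
            raise ValueError("relaxation rates must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigmoid steepness sigma must be > 0")
        if omega.shape != (n, n + len(MORPHOGENS)):
            raise ValueError(
                f"omega must have shape ({n}, {n + len(MORPHOGENS)}), "
                f"got {omega.shape}"
            )
        if not np.all(np.isfinite(omega)):
            raise ValueError("omega entries must be finite")
        clamp = self.clamp
        if clamp is None:
            clamp = np.full(n, np.nan)
        clamp = np.asarray(clamp, dtype=float)
        if clamp.shape != (n,):
            raise ValueError("clamp must have one entry per species")
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "basal", basal)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "clamp", clamp)

    # -- index helpers -----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def input_index(self, name: str) -> int:
        """Column index (into omega) of a species or morphogen input."""
        if name in self.species:
            return self.species.index(name)
        if name in MORPHOGENS:
            return self.n_species + MORPHOGENS.index(name)
        raise KeyError(f"unknown species or morphogen {name!r}")

    @property
    def omega_species(self) -> np.ndarray:
        return self.omega[:, : self.n_species]

    @property
    def omega_inputs(self) -> np.ndarray:
        return self.omega[:, self.n_species :]

    @property
    def clamp_mask(self) -> np.ndarray:
        return ~np.isnan(self.clamp)

    # -- editing -----------------------------------------------------------
    def with_edge(self, source: str, target: str, weight: float) -> "NetworkSpec":
        """Return a copy with ``omega[target, source]`` set to ``weight``."""
        omega = self.omega.copy()
        omega[self.index(target), self.input_index(source)] = weight
        return replace(self, omega=omega)

    def edges(self) -> list[dict]:
        """Non-zero interactions as a labelled edge list."""
        cols = self.species + MORPHOGENS
        out = []
        for i, target in enumerate(self.species):
            for j, source in enumerate(cols):
                w = self.omega[i, j]
                if w != 0.0:
                    out.append({"source": source, "target": target, "weight": float(w)})
        return out

    # -- (de)serialization -------------------------------------------------
    def to_config(self) -> dict:
        cfg = {
            "species": list(self.species),
            "sigma": float(self.sigma),
            "gamma": {s: float(g) for s, g in zip(self.species, self.gamma)},
            "basal": {s: float(b) for s, b in zip(self.species, self.basal)},
            "edges": self.edges(),
        }
        if self.clamp_mask.any():
            cfg["clamp"] = {
                s: float(v)
                for s, v in zip(self.species, self.clamp)
                if not np.isnan(v)
            }
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping) -> "NetworkSpec":
        species = tuple(cfg["species"])
        n = len(species)
        gamma = np.array([cfg["gamma"][s] for s in species], dtype=float)
        basal = np.array([cfg["basal"][s] for s in species], dtype=float)
        spec = cls(
            species=species,
            gamma=gamma,
            sigma=float(cfg["sigma"]),
            basal=basal,
            omega=np.zeros((n, n + len(MORPHOGENS))),
        )
        for edge in cfg.get("edges", []):
            spec = spec.with_edge(edge["source"], edge["target"], edge["weight"])
        clamp_cfg = cfg.get("clamp")
        if clamp_cfg:
            clamp = np.full(n, np.nan)
            for s, v in clamp_cfg.items():
                clamp[spec.index(s)] = float(v)
            spec = replace(spec, clamp=clamp)
        return spec


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def sigmoid(u, sigma: float):
    """Logistic response ``F(u) = 1 / (1 + exp(-sigma * u))``.

    Strictly increasing, with range ``(0, 1)`` and ``F(0) = 0.5``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return expit(sigma * np.asarray(u, dtype=float))


def _as_morphogen_array(morphogens) -> np.ndarray:
    if isinstance(morphogens, Mapping):
        m = np.array([morphogens.get(name, 0.0) for name in MORPHOGENS], dtype=float)
    else:
        m = np.asarray(morphogens, dtype=float)
    if m.shape[-1] != len(MORPHOGENS):
        raise ValueError("morphogen levels must have a trailing axis of length 2")
    return m


def regulatory_field(spec: NetworkSpec, state, morphogens) -> np.ndarray:
    """Sigmoid arguments ``u_i`` for every species, vectorized over cells.

    ``state`` has shape ``(..., n_species)`` and ``morphogens`` broadcasts to
    ``(..., 2)`` (RA, FGF order).
    """
    x = np.asarray(state, dtype=float)
    m = _as_morphogen_array(morphogens)
    return spec.basal + x @ spec.omega_species.T + m @ spec.omega_inputs.T


def regulatory_input(spec: NetworkSpec, state, morphogens, target: str) -> float:
    """Summed regulatory input ``u_i`` of a single target species."""
    i = spec.index(target)
    return float(regulatory_field(spec, state, morphogens)[..., i])


def derivatives(spec: NetworkSpec, state, morphogens) -> np.ndarray:
    """Rates ``dX_i/dt = gamma_i (F(u_i) - X_i)``; zero for clamped species."""
    x = np.asarray(state, dtype=float)
    u = regulatory_field(spec, x, morphogens)
    dx = spec.gamma * (sigmoid(u, spec.sigma) - x)
    mask = spec.clamp_mask
    if mask.any():
        dx[..., mask] = 0.0
    return dx


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _apply_clamp(spec: NetworkSpec, x: np.ndarray) -> np.ndarray:
    mask = spec.clamp_mask
    if mask.any():
        x[..., mask] = spec.clamp[mask]
    return x


def integrate(
    spec: NetworkSpec,
    initial,
    morphogens,
    t_span: float,
    dt: float = 0.01,
    store_every: float | None = None,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the network with classical RK4 at fixed step ``dt``.

    Parameters
    ----------
    initial
        State array of shape ``(..., n_species)``; leading axes are cells (or
        any batch) integrated in parallel under the same spec.
    morphogens
        Either a constant level (mapping or array broadcastable to
        ``(..., 2)``) or a callable ``f(t) -> array``.  The input is held
        constant over each step (evaluated at the step start), which is exact
        for the piecewise-constant noisy inputs used throughout, provided
        noise-interval boundaries coincide with step boundaries.
    store_every
        Interval between stored states (defaults to ``dt``); must be an
        integer multiple of ``dt``.

    Returns
    -------
    times, trajectory
        ``times`` of shape ``(n_stored,)`` and trajectory of shape
        ``(n_stored, ..., n_species)``; the initial state is stored first.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_span < dt:
        raise ValueError("t_span must be at least one step")
    n_steps = int(round(t_span / dt))
    if abs(n_steps * dt - t_span) > 1e-9 * max(1.0, t_span):
        raise ValueError("t_span must be an integer multiple of dt")
    if store_every is None:
        stride = 1
    else:
        stride = int(round(store_every / dt))
        if stride < 1 or abs(stride * dt - store_every) > 1e-9:
            raise ValueError("store_every must be a positive multiple of dt")

    if callable(morphogens):
        morph_at = morphogens
    else:
        const = _as_morphogen_array(morphogens)
        morph_at = lambda t: const  # noqa: E731

    x = _apply_clamp(spec, np.array(initial, dtype=float))
    n_stored = n_steps // stride + 1
    traj = np.empty((n_stored,) + x.shape, dtype=float)
    times = np.empty(n_stored, dtype=float)
    traj[0] = x
    times[0] = t0
    stored = 1
    for k in range(n_steps):
        t = t0 + k * dt
        m = morph_at(t)
        k1 = derivatives(spec, x, m)
        k2 = derivatives(spec, x + 0.5 * dt * k1, m)
        k3 = derivatives(spec, x + 0.5 * dt * k2, m)
        k4 = derivatives(spec, x + dt * k3, m)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        _apply_clamp(spec, x)
        if (k + 1) % stride == 0:
            if not np.all(np.isfinite(x)):
                bad = np.argwhere(~np.isfinite(x))
                sp = spec.species[int(bad[0][-1])]
                raise NumericalIntegrationError(
                    f"non-finite value for species {sp!r} at t={t + dt:.4f}"
                )
            traj[stored] = x
            times[stored] = t0 + (k + 1) * dt
            stored += 1
    return times, traj


def relax_to_steady_state(
    spec: NetworkSpec,
    initial,
    morphogens,
    tol: float = 1e-6,
    t_max: float = 100.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Integrate under constant inputs until ``max |dX/dt| < tol``.

    Raises :class:`ConvergenceError` if the residual still exceeds ``tol`` at
    ``t_max``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    x = _apply_clamp(spec, np.array(initial, dtype=float))
    chunk = min(t_max, 5.0)
    elapsed = 0.0
    while True:
        resid = float(np.max(np.abs(derivatives(spec, x, morphogens))))
        if resid < tol:
            return x
        if elapsed >= t_max:
            raise ConvergenceError(
                f"no steady state by t_max={t_max}: residual {resid:.3e} "
                f"(tol {tol:.1e})"
            )
        step = min(chunk, t_max - elapsed)
        step = max(step, dt)
        _, traj = integrate(spec, x, morphogens, step, dt=dt, store_every=step)
        x = traj[-1]
        elapsed += step


# ---------------------------------------------------------------------------
# Mutants
# ---------------------------------------------------------------------------

def apply_mutant(
    spec: NetworkSpec, kind: MutantKind | str, mirx: str = "mir_x"
) -> NetworkSpec:
    """Return a transformed copy of ``spec`` for the requested genotype.

    The input spec is never modified.  All kinds except ``wild_type`` require
    a miRNA species (``mirx``) in the network.
    """
    kind = MutantKind(kind)
    if kind is MutantKind.WILD_TYPE:
        return replace(spec)
    if mirx not in spec.species:
        raise ValueError(f"{kind.value} requires a {mirx!r} species in the network")
    i = spec.index(mirx)
    if kind is MutantKind.DICER_NULL:
        basal = spec.basal.copy()
        basal[i] = DICER_NULL_BASAL
        return replace(spec, basal=basal)
    if kind is MutantKind.MIRX_FAST:
        gamma = spec.gamma.copy()
        gamma[i] *= MIRX_FAST_FACTOR
        return replace(spec, gamma=gamma)
    if kind is MutantKind.MIRX_NULL:
        omega = spec.omega.copy()
        omega[i, :] = 0.0
        omega[:, i] = 0.0
        clamp = spec.clamp.copy()
        clamp[i] = 0.0
        return replace(spec, omega=omega, clamp=clamp)
    raise ValueError(f"unhandled mutant kind {kind}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Packaged default
# ---------------------------------------------------------------------------

def load_network(path) -> NetworkSpec:
    """Load a :class:`NetworkSpec` from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    key = "network" if "network" in cfg else None
    return NetworkSpec.from_config(cfg[key] if key else cfg)


def _default_config() -> dict:
    text = resources.files("hoxmir.configs").joinpath("default.yaml").read_text()
    return yaml.safe_load(text)


def default_network(with_mirx_circuit: bool = True) -> NetworkSpec:
    """The calibrated five-species Hoxa5/Hoxc8 network.

    With ``with_mirx_circuit=True`` the three consensus mir-x interactions
    (RA ⊣ mir-x, Hoxc8 protein → mir-x, mir-x ⊣ Hoxa5 protein) are included
    at the default strength; otherwise the basal (miRNA-free) wiring is
    returned, in which Hoxa5 and Hoxc8 domains overlap under noise.
    """
    cfg = _default_config()
    spec = NetworkSpec.from_config(cfg["network"])
    if with_mirx_circuit:
        strength = float(cfg["mirx_circuit"]["strength"])
        for edge in cfg["mirx_circuit"]["edges"]:
            spec = spec.with_edge(
                edge["source"], edge["target"], edge["weight"] * strength
            )
    return spec
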