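"""Boundary robustness and accuracy statistics.

A cell "expresses" a protein when its level exceeds 0.5 units (strict).  The
occupancy profile is, per position along the axis, the fraction of replicate
simulations whose cell at that position expresses.  The transition zone of a
protein is the set of positions with occupancy strictly between 15% and 85%;
its width Omega measures boundary roughness, and the expression boundary sits
at the zone midpoint.  The robustness score of a simulated tissue is

    score = Omega_a5 + Omega_c8 + |Delta_a5-c8|,

the sum of both transition widths and the distance between the two expression
boundaries; low scores mean a sharp, accurate Hoxa5/Hoxc8 boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransitionZone",
    "BoundaryReport",
    "expression_calls",
    "occupancy_profile",
    "transition_zone",
    "boundary_position",
    "robustness_score",
    "boundary_report",
    "coefficient_of_variation",
    "expression_histogram",
    "half_rise_time",
]

EXPRESSION_THRESHOLD = 0.5
ZONE_LO = 0.15
ZONE_HI = 0.85


@dataclass(frozen=True)
class TransitionZone:
    """Index span of positions with intermediate occupancy.

    ``start``/``end`` are inclusive cell indices (meaningless when ``empty``);
    ``width`` is (end - start + 1) * spacing, or 0 for an empty zone.
    """

    start: int
    end: int
    width: float
    empty: bool


@dataclass(frozen=True)
class BoundaryReport:
    """Boundary statistics for the Hoxa5/Hoxc8 pair on one snapshot."""

    zone_a5: TransitionZone
    zone_c8: TransitionZone
    width_a5: float
    width_c8: float
    boundary_a5: float
    boundary_c8: float
    delta: float
    score: float

    def to_dict(self) -> dict:
        return {
            "width_a5": self.width_a5,
            "width_c8": self.width_c8,
            "boundary_a5": self.boundary_a5,
            "boundary_c8": self.boundary_c8,
            "delta": self.delta,
            "score": self.score,
        }


def expression_calls(values, threshold: float = EXPRESSION_THRESHOLD) -> np.ndarray:
    """Boolean expressing calls: strictly greater than ``threshold``.

    ``values`` is a (replicate, cell) array of one species' levels.
    """
    return np.asarray(values, dtype=float) > threshold


def occupancy_profile(calls) -> np.ndarray:
    """Per-position fraction of replicates expressing (column means)."""
    calls = np.asarray(calls, dtype=bool)
    if calls.ndim != 2 or calls.shape[0] < 1:
        raise ValueError("calls must be a (replicate, cell) matrix")
    return calls.mean(axis=0)


def transition_zone(
    profile, lo: float = ZONE_LO, hi: float = ZONE_HI, spacing: float = 1.0
) -> TransitionZone:
    """Span of positions whose occupancy lies strictly in ``(lo, hi)``.

    The zone is the min-to-max envelope of qualifying positions; for ragged
    profiles this deliberately inflates the width.  No qualifying position
    yields an empty zone of width 0.
    """
    p = np.asarray(profile, dtype=float)
    idx = np.flatnonzero((p > lo) & (p < hi))
    if idx.size == 0:
        return TransitionZone(start=-1, end=-1, width=0.0, empty=True)
    start, end = int(idx[0]), int(idx[-1])
    return TransitionZone(start=start, end=end, width=(end - start + 1) * spacing, empty=False)


def boundary_position(
    profile,
    zone: TransitionZone | None = None,
    lo: float = ZONE_LO,
    hi: float = ZONE_HI,
    spacing: float = 1.0,
) -> float:
    """Midpoint of the transition zone, in length units.

    For an empty zone (a perfectly sharp profile) the boundary is the midpoint
    between adjacent cells on opposite sides of the (lo, hi) band.  Returns
    NaN when no boundary exists in the domain: a boundary requires both an
    expressing side (occupancy >= hi somewhere) and a non-expressing side
    (occupancy <= lo somewhere).
    """
    p = np.asarray(profile, dtype=float)
    if not (np.any(p >= hi) and np.any(p <= lo)):
        return math.nan
    if zone is None:
        zone = transition_zone(p, lo=lo, hi=hi, spacing=spacing)
    if not zone.empty:
        return 0.5 * (zone.start + zone.end) * spacing
    high = p >= hi
    low = p <= lo
    for i in range(len(p) - 1):
        if (high[i] and low[i + 1]) or (low[i] and high[i + 1]):
            return (i + 0.5) * spacing
    return math.nan


def robustness_score(
    width_a5: float,
    width_c8: float,
    delta: float,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Weighted sum ``w1*Omega_a5 + w2*Omega_c8 + w3*|Delta|``.

    Any undefined component (NaN) yields +inf, ranking the topology last.
    """
    parts = (width_a5, width_c8, abs(delta))
    if any(map(math.isnan, parts)):
        return math.inf
    return sum(w * v for w, v in zip(weights, parts))


def boundary_report(
    snap: np.ndarray,
    species: tuple[str, ...],
    spacing: float = 1.0,
    threshold: float = EXPRESSION_THRESHOLD,
    lo: float = ZONE_LO,
    hi: float = ZONE_HI,
    a5: str = "hoxa5_protein",
    c8: str = "hoxc8_protein",
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> BoundaryReport:
    """Full boundary statistics from a (replicate, cell, species) snapshot."""
    species = tuple(species)
    reports = {}
    for name in (a5, c8):
        vals = snap[:, :, species.index(name)]
        prof = occupancy_profile(expression_calls(vals, threshold))
        zone = transition_zone(prof, lo=lo, hi=hi, spacing=spacing)
        pos = boundary_position(prof, zone, lo=lo, hi=hi, spacing=spacing)
        reports[name] = (zone, pos)
    zone_a5, pos_a5 = reports[a5]
    zone_c8, pos_c8 = reports[c8]
    delta = pos_a5 - pos_c8
    score = robustness_score(zone_a5.width, zone_c8.width, delta, weights=weights)
    return BoundaryReport(
        zone_a5=zone_a5,
        zone_c8=zone_c8,
        width_a5=zone_a5.width,
        width_c8=zone_c8.width,
        boundary_a5=pos_a5,
        boundary_c8=pos_c8,
        delta=delta,
        score=score,
    )


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (ddof=1) over the mean; NaN for zero mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0.0:
        return math.nan
    return float(v.std(ddof=1) / mean)


def expression_histogram(
    values, bins: int = 20, value_range: tuple[float, float] = (0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of expression levels; counts sum to the number of values."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    v = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(np.clip(v, *value_range), bins=bins, range=value_range)
    return counts, edges


def half_rise_time(times, values) -> float:
    """First time the trajectory reaches half its final value.

    Linear interpolation between stored points; NaN if the trajectory never
    crosses half of its final value.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have the same shape")
    target = 0.5 * v[-1]
    above = v >= target
    if not above.any():
        return math.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (target - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
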