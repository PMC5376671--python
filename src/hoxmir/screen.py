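"""Exhaustive screen over candidate mir-x network topologies.

Six candidate interactions involve the hypothetical miRNA: four incoming
edges (RA, FGF, Hoxa5 protein and Hoxc8 protein acting on mir-x), each
activating (+1), inhibiting (-1) or absent (0); and two outgoing edges
(mir-x acting on the Hoxa5 and Hoxc8 translation nodes), each inhibiting
(-1) or absent (0) since a miRNA represses translation of its targets.  The
Cartesian product gives 3^4 * 2^2 = 324 topologies.

Each topology is scored by simulating the noisy 1D tissue and computing the
boundary robustness score (sum of both transition widths plus the boundary
distance); topologies are ranked ascending and the consensus interactions
are the signed edges shared by every topology in the top 2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics, morphogen as mg, tissue as ts
from .network import NetworkSpec

__all__ = [
    "CANDIDATE_EDGES",
    "TopologyAssignment",
    "ScreenSettings",
    "ScreenResult",
    "enumerate_topologies",
    "topology_from_id",
    "instantiate",
    "score_topology",
    "run_screen",
    "rank_topologies",
    "consensus_interactions",
    "strength_sweep",
]

#: The six candidate edges: (source, target, allowed signed values).
#: Order fixes the canonical mixed-radix topology id.
CANDIDATE_EDGES: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("RA", "mir_x", (-1, 0, 1)),
    ("FGF", "mir_x", (-1, 0, 1)),
    ("hoxa5_protein", "mir_x", (-1, 0, 1)),
    ("hoxc8_protein", "mir_x", (-1, 0, 1)),
    ("mir_x", "hoxa5_protein", (-1, 0)),
    ("mir_x", "hoxc8_protein", (-1, 0)),
)

#: The three interactions recovered as the screen consensus.
CONSENSUS_EDGES = frozenset(
    {
        ("RA", "mir_x", -1),
        ("hoxc8_protein", "mir_x", 1),
        ("mir_x", "hoxa5_protein", -1),
    }
)


@dataclass(frozen=True)
class TopologyAssignment:
    """One signed assignment of the six candidate mir-x edges."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(CANDIDATE_EDGES):
            raise ValueError("expected one value per candidate edge")
        for v, (_, _, allowed) in zip(self.values, CANDIDATE_EDGES):
            if v not in allowed:
                raise ValueError(f"value {v} not allowed for this edge")

    @property
    def id(self) -> int:
        """Canonical mixed-radix id (first edge most significant)."""
        ident = 0
        for v, (_, _, allowed) in zip(self.values, CANDIDATE_EDGES):
            ident = ident * len(allowed) + allowed.index(v)
        return ident

    def edges(self) -> list[tuple[str, str, int]]:
        """Non-zero signed edges of the assignment."""
        return [
            (s, t, v)
            for v, (s, t, _) in zip(self.values, CANDIDATE_EDGES)
            if v != 0
        ]

    def __iter__(self):
        return iter(self.values)


def enumerate_topologies(
    edges: tuple = CANDIDATE_EDGES,
) -> list[TopologyAssignment]:
    """All assignments of the candidate edges, in canonical id order."""
    assignments: list[tuple[int, ...]] = [()]
    for _, _, allowed in edges:
        assignments = [a + (v,) for a in assignments for v in allowed]
    if edges is CANDIDATE_EDGES:
        return [TopologyAssignment(values=a) for a in assignments]
    # restricted enumerations (used for counting checks) bypass validation
    out = []
    for a in assignments:
        t = object.__new__(TopologyAssignment)
        object.__setattr__(t, "values", a)
        out.append(t)
    return out


def topology_from_id(ident: int) -> TopologyAssignment:
    """Inverse of :attr:`TopologyAssignment.id`."""
    radices = [len(allowed) for _, _, allowed in CANDIDATE_EDGES]
    total = math.prod(radices)
    if not 0 <= ident < total:
        raise ValueError(f"topology id must be in [0, {total})")
    digits = []
    for r in reversed(radices):
        digits.append(ident % r)
        ident //= r
    digits.reverse()
    values = tuple(
        CANDIDATE_EDGES[k][2][d] for k, d in enumerate(digits)
    )
    return TopologyAssignment(values=values)


def instantiate(
    base: NetworkSpec, topo: TopologyAssignment, strength: float = 1.0
) -> NetworkSpec:
    """Add the topology's non-zero edges (scaled by ``strength``) to ``base``."""
    if strength <= 0:
        raise ValueError("strength must be > 0")
    spec = base
    for source, target, v in topo.edges():
        spec = spec.with_edge(source, target, v * strength)
    return spec


@dataclass(frozen=True)
class ScreenSettings:
    """Simulation protocol shared by every topology in a screen."""

    tissue: ts.TissueConfig = field(
        default_factory=lambda: ts.TissueConfig(n_replicates=10)
    )
    gradient: mg.GradientParams = field(default_factory=mg.GradientParams)
    noise: mg.NoiseParams = field(default_factory=mg.NoiseParams)
    n_batches: int = 1
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _topology_seed(master_seed: int, topo_id: int, batch: int) -> np.random.SeedSequence:
    # seeds depend only on (master, topology, batch): screen results are
    # independent of the order in which topologies are evaluated
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(topo_id, batch))


def score_topology(
    spec: NetworkSpec,
    settings: ScreenSettings,
    master_seed: int,
    topo_id: int = 0,
) -> np.ndarray:
    """Per-batch robustness scores of one instantiated topology.

    Each batch runs ``settings.tissue.n_replicates`` noisy replicates of the
    1D development protocol and scores the end-time occupancy profiles.  The
    topology's score is the mean over batches.
    """
    scores = np.empty(settings.n_batches)
    for b in range(settings.n_batches):
        seed = _topology_seed(master_seed, topo_id, b)
        result = ts.run_development(
            spec, settings.tissue, settings.gradient, settings.noise, seed=seed
        )
        snap = ts.snapshot(result, settings.tissue.t_dev)
        report = metrics.boundary_report(
            snap,
            species=spec.species,
            spacing=settings.gradient.spacing,
            weights=settings.weights,
        )
        scores[b] = report.score
    return scores


@dataclass
class ScreenResult:
    """Ranked screen outcome.

    ``table`` columns: topology id, the six edge values, mean score, score
    standard deviation over batches, and ascending rank (ties broken by id).
    """

    table: pd.DataFrame
    strength: float
    master_seed: int
    settings: ScreenSettings

    def top(self, fraction: float = 0.02, method: str = "ceil") -> pd.DataFrame:
        n = len(self.table)
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        k = math.ceil(fraction * n) if method == "ceil" else math.floor(fraction * n)
        k = max(k, 1)
        return self.table.nsmallest(k, ["score", "topology"], keep="first")

    @property
    def best_id(self) -> int:
        return int(self.table.loc[self.table["rank"] == 0, "topology"].iloc[0])


def run_screen(
    base: NetworkSpec,
    settings: ScreenSettings,
    master_seed: int,
    strength: float = 1.0,
    topologies: list[TopologyAssignment] | None = None,
    progress: bool = False,
) -> ScreenResult:
    """Score and rank every candidate topology at one interaction strength."""
    if topologies is None:
        topologies = enumerate_topologies()
    rows = []
    edge_cols = [f"{s}->{t}" for s, t, _ in CANDIDATE_EDGES]
    for i, topo in enumerate(topologies):
        spec = instantiate(base, topo, strength)
        scores = score_topology(spec, settings, master_seed, topo_id=topo.id)
        row = {"topology": topo.id}
        row.update(dict(zip(edge_cols, topo.values)))
        row["score"] = float(np.mean(scores))
        row["score_sd"] = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
        rows.append(row)
        if progress and (i + 1) % 50 == 0:
            print(f"  scored {i + 1}/{len(topologies)} topologies")
    table = pd.DataFrame(rows)
    order = np.lexsort((table["topology"].to_numpy(), table["score"].to_numpy()))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(len(table))
    table["rank"] = ranks
    table = table.sort_values("rank").reset_index(drop=True)
    return ScreenResult(
        table=table, strength=strength, master_seed=master_seed, settings=settings
    )


def rank_topologies(scores, ids=None) -> np.ndarray:
    """Topology ids ordered by ascending score, ties broken by id."""
    scores = np.asarray(scores, dtype=float)
    ids = np.arange(len(scores)) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, scores))
    return ids[order]


def consensus_interactions(
    result: ScreenResult, fraction: float = 0.02, method: str = "ceil"
) -> set[tuple[str, str, int]]:
    """Signed edges identical and non-zero in every top-fraction topology."""
    top = result.top(fraction=fraction, method=method)
    edge_sets = [
        set(topology_from_id(int(t)).edges()) for t in top["topology"]
    ]
    consensus = set.intersection(*edge_sets) if edge_sets else set()
    return consensus


def strength_sweep(
    base: NetworkSpec,
    strengths,
    settings: ScreenSettings,
    master_seed: int,
    topologies: list[TopologyAssignment] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Full screen at each interaction strength.

    Returns one row per strength with the winning topology id, its score and
    whether the winner matches the modal winner over the sweep (stability).
    """
    rows = []
    for s in strengths:
        res = run_screen(base, settings, master_seed, strength=float(s),
                         topologies=topologies, progress=progress)
        best = res.table.iloc[0]
        rows.append(
            {
                "strength": float(s),
                "best_topology": int(best["topology"]),
                "best_score": float(best["score"]),
                "consensus": sorted(consensus_interactions(res)),
            }
        )
    df = pd.DataFrame(rows)
    modal = df["best_topology"].mode().iloc[0]
    df["stable"] = df["best_topology"] == modal
    return df
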