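"""Experiment orchestration: validated configs, protocol dispatch, artifacts.

Five packaged protocols cover the study's in-silico experiments:

``develop``
    1D tissue under noisy opposing gradients; writes occupancy profiles and
    a boundary report.
``differentiate``
    RA-only stimulation of a homogeneous cell group; writes the time course
    of Hoxa5 protein (mean/variance) and an expression histogram at the
    day-3 analogue.
``screen``
    Exhaustive 324-topology mir-x screen; writes the ranking table and the
    consensus interactions.
``sweep``
    The screen repeated over a range of interaction strengths.
``mutants``
    Paired wild-type / Dicer-null / fast-mir-x tissue runs under identical
    noise seeds; writes per-batch transition widths.

All randomness derives from the mandatory ``seed``; re-running a config
reproduces its outputs.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx, morphogen as mg, screen as sc, tissue as ts
from .config import Defaults, load_defaults
from .network import MutantKind, NetworkSpec, apply_mutant

__all__ = ["ExperimentConfig", "run_experiment", "compare_conditions", "ConfigError"]

logger = logging.getLogger("hoxmir")

PROTOCOLS = ("develop", "differentiate", "screen", "sweep", "mutants")


class ConfigError(ValueError):
    """Invalid experiment configuration; message lists offending fields."""


@dataclass(frozen=True)
class ExperimentConfig:
    """A validated experiment request.

    ``network_config`` selects the study config file (None = packaged
    default).  ``overrides`` may adjust protocol-specific knobs such as
    replicate counts, noise amplitude, strength or mutant kind.
    """

    protocol: str
    seed: int
    out_dir: str
    network_config: str | None = None
    mutant: str = "wild_type"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        problems = []
        if self.protocol not in PROTOCOLS:
            problems.append(f"protocol must be one of {PROTOCOLS}")
        if not isinstance(self.seed, int):
            problems.append("seed is mandatory and must be an integer")
        try:
            MutantKind(self.mutant)
        except ValueError:
            problems.append(f"unknown mutant kind {self.mutant!r}")
        if self.network_config is not None and not Path(self.network_config).exists():
            problems.append(f"network_config path {self.network_config!r} does not exist")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigError("seed is mandatory and must be an integer")
        known = {"protocol", "seed", "out_dir", "network_config", "mutant"}
        kwargs = {k: raw[k] for k in known if k in raw}
        kwargs["overrides"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))


def _occupancy_frame(snap, species, positions, threshold=mx.EXPRESSION_THRESHOLD):
    rows = {}
    for i, name in enumerate(species):
        calls = mx.expression_calls(snap[:, :, i], threshold)
        rows[name] = mx.occupancy_profile(calls)
    df = pd.DataFrame(rows)
    df.insert(0, "position", positions)
    return df


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _protocol_develop(d: Defaults, cfg: ExperimentConfig, out: Path) -> dict:
    ov = cfg.overrides
    tissue = replace(
        d.tissue,
        n_replicates=int(ov.get("n_replicates", d.tissue.n_replicates)),
        n_cells=int(ov.get("n_cells", d.tissue.n_cells)),
    )
    gradient = replace(d.gradient, n_cells=tissue.n_cells)
    noise = replace(d.noise, amplitude=float(ov.get("noise_amplitude", d.noise.amplitude)))
    spec = apply_mutant(d.network_wt, cfg.mutant)
    result = ts.run_development(spec, tissue, gradient, noise, seed=cfg.seed)
    snap = ts.snapshot(result, tissue.t_dev)
    report = mx.boundary_report(snap, spec.species, spacing=gradient.spacing)
    occ = _occupancy_frame(snap, spec.species, gradient.positions())
    occ.to_csv(out / "occupancy.csv", index=False)
    _write_json(out / "boundary_report.json", report.to_dict())
    return {
        "boundary": report.to_dict(),
        "occupancy": occ,
        "result": result,
        "tissue": tissue,
        "gradient": gradient,
    }


def _protocol_differentiate(d: Defaults, cfg: ExperimentConfig, out: Path) -> dict:
    ov = cfg.overrides
    diff = d.differentiation
    n_cells = int(ov.get("n_cells_group", diff["n_cells_group"]))
    ra = float(ov.get("ra_level", diff["ra_level"]))
    duration = float(ov.get("duration", diff["duration"]))
    day3 = float(ov.get("day3_time", diff["day3_time"]))
    noise = replace(d.noise, amplitude=float(ov.get("noise_amplitude", d.noise.amplitude)))
    spec = apply_mutant(d.network_wt, cfg.mutant)
    result = ts.run_differentiation(spec, n_cells, ra, noise, duration, seed=cfg.seed)
    a5 = result.series("hoxa5_protein")[0]  # (cell, time)
    course = pd.DataFrame(
        {
            "time": result.times,
            "mean": a5.mean(axis=0),
            "var": a5.var(axis=0, ddof=1),
            "cv": a5.std(axis=0, ddof=1) / np.maximum(a5.mean(axis=0), 1e-12),
        }
    )
    course.to_csv(out / "hoxa5_timecourse.csv", index=False)
    day3_vals = ts.snapshot(result, day3)[0][:, result.species_index("hoxa5_protein")]
    counts, edges = mx.expression_histogram(day3_vals, bins=20)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    hist.to_csv(out / "hoxa5_day3_histogram.csv", index=False)
    half = mx.half_rise_time(result.times, a5.mean(axis=0))
    summary = {
        "half_rise_time": half,
        "day3_mean": float(day3_vals.mean()),
        "day3_var": float(day3_vals.var(ddof=1)),
        "ra_level": ra,
        "duration": duration,
    }
    _write_json(out / "summary.json", summary)
    return {"summary": summary, "timecourse": course, "result": result}


def _protocol_screen(d: Defaults, cfg: ExperimentConfig, out: Path) -> dict:
    ov = cfg.overrides
    tissue = replace(d.tissue, n_replicates=int(ov.get("n_replicates", 30)))
    settings = sc.ScreenSettings(tissue=tissue, gradient=d.gradient, noise=replace(
        d.noise, amplitude=float(ov.get("noise_amplitude", d.noise.amplitude))))
    strength = float(ov.get("strength", d.mirx_strength))
    topologies = ov.get("topologies")
    if topologies is not None:
        topologies = [sc.topology_from_id(int(t)) for t in topologies]
    res = sc.run_screen(d.network_basal, settings, master_seed=cfg.seed,
                        strength=strength, topologies=topologies, progress=True)
    res.table.to_csv(out / "screen_ranking.csv", index=False)
    consensus = sorted(sc.consensus_interactions(res))
    _write_json(
        out / "consensus.json",
        {
            "strength": strength,
            "top_fraction": 0.02,
            "top_n": len(res.top()),
            "consensus_interactions": [
                {"source": s, "target": t, "sign": v} for s, t, v in consensus
            ],
        },
    )
    return {"screen": res, "consensus": consensus}


def _protocol_sweep(d: Defaults, cfg: ExperimentConfig, out: Path) -> dict:
    ov = cfg.overrides
    strengths = ov.get("strengths", [0.2, 0.4, 0.6, 0.8, 1.0, 1.2])
    tissue = replace(d.tissue, n_replicates=int(ov.get("n_replicates", 10)))
    settings = sc.ScreenSettings(tissue=tissue, gradient=d.gradient, noise=d.noise)
    topologies = ov.get("topologies")
    if topologies is not None:
        topologies = [sc.topology_from_id(int(t)) for t in topologies]
    df = sc.strength_sweep(d.network_basal, strengths, settings,
                           master_seed=cfg.seed, topologies=topologies)
    df2 = df.copy()
    df2["consensus"] = df2["consensus"].map(lambda e: json.dumps(e))
    df2.to_csv(out / "strength_sweep.csv", index=False)
    return {"sweep": df}


def _protocol_mutants(d: Defaults, cfg: ExperimentConfig, out: Path) -> dict:
    """Paired WT / Dicer-null / fast-mir-x boundary roughness comparison.

    Uses a finer tissue (200 cells, 60 replicates per batch) so that the
    transition-width comparison is well resolved; each batch shares its
    noise seed across genotypes.
    """
    ov = cfg.overrides
    n_batches = int(ov.get("n_batches", 10))
    n_cells = int(ov.get("n_cells", 200))
    n_rep = int(ov.get("n_replicates", 60))
    tissue = replace(d.tissue, n_cells=n_cells, n_replicates=n_rep)
    gradient = replace(d.gradient, n_cells=n_cells)
    kinds = [MutantKind.WILD_TYPE, MutantKind.DICER_NULL, MutantKind.MIRX_FAST]
    rows = []
    for b in range(n_batches):
        seed = cfg.seed + b
        for kind in kinds:
            spec = apply_mutant(d.network_wt, kind)
            res = ts.run_development(spec, tissue, gradient, d.noise, seed=seed)
            rep = mx.boundary_report(
                ts.snapshot(res, tissue.t_dev), spec.species, spacing=gradient.spacing
            )
            rows.append({"batch": b, "genotype": kind.value, **rep.to_dict()})
        logger.info("mutants: batch %d/%d done", b + 1, n_batches)
    df = pd.DataFrame(rows)
    df.to_csv(out / "mutant_boundaries.csv", index=False)
    wide = df.pivot(index="batch", columns="genotype", values="width_a5")
    summary = {
        "n_batches": n_batches,
        "dicer_wider_than_wt": int((wide["dicer_null"] > wide["wild_type"]).sum()),
        "fast_wider_than_wt": int((wide["mirx_fast"] > wide["wild_type"]).sum()),
        "mean_width_a5": {k: float(wide[k].mean()) for k in wide.columns},
    }
    _write_json(out / "summary.json", summary)
    return {"table": df, "summary": summary}


_DISPATCH = {
    "develop": _protocol_develop,
    "differentiate": _protocol_differentiate,
    "screen": _protocol_screen,
    "sweep": _protocol_sweep,
    "mutants": _protocol_mutants,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute a protocol and persist its artifact bundle under ``out_dir``.

    Returns the in-memory results alongside the paths written.  A
    ``meta.json`` sidecar records the config, seed and runtime.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = load_defaults(cfg.network_config)
    t0 = time.time()
    logger.info("protocol %s (seed %d) -> %s", cfg.protocol, cfg.seed, out)
    result = _DISPATCH[cfg.protocol](d, cfg, out)
    meta = {
        "protocol": cfg.protocol,
        "seed": cfg.seed,
        "mutant": cfg.mutant,
        "network_config": cfg.network_config,
        "overrides": cfg.overrides,
        "runtime_s": round(time.time() - t0, 2),
    }
    _write_json(out / "meta.json", meta)
    result["meta"] = meta
    result["out_dir"] = str(out)
    return result


def compare_conditions(bundle_a: dict, bundle_b: dict) -> dict:
    """Differences between two ``develop`` bundles (a minus b).

    Reports the change in transition widths, boundary distance and score,
    plus, when time courses are available, the Hoxa5 half-rise-time
    difference and the early-time across-cell variance ratio.
    """
    ba, bb = bundle_a.get("boundary"), bundle_b.get("boundary")
    if ba is None or bb is None:
        raise ValueError("compare_conditions requires two 'develop' bundles")
    if bundle_a["occupancy"].shape != bundle_b["occupancy"].shape:
        raise ValueError("bundles have incompatible tissue geometries")
    out = {
        "d_width_a5": ba["width_a5"] - bb["width_a5"],
        "d_width_c8": ba["width_c8"] - bb["width_c8"],
        "d_delta": abs(ba["delta"]) - abs(bb["delta"]),
        "d_score": ba["score"] - bb["score"],
    }
    ra, rb = bundle_a.get("result"), bundle_b.get("result")
    if ra is not None and rb is not None:
        ta = ra.series("hoxa5_protein").mean(axis=(0, 1))
        tb = rb.series("hoxa5_protein").mean(axis=(0, 1))
        out["d_half_rise"] = mx.half_rise_time(ra.times, ta) - mx.half_rise_time(rb.times, tb)
        k = ra.time_index(min(1.0, ra.times[-1]))
        va = float(ra.series("hoxa5_protein")[:, :, k].var(ddof=1))
        vb = float(rb.series("hoxa5_protein")[:, :, k].var(ddof=1))
        out["early_variance_ratio"] = va / vb if vb > 0 else math.inf
    return out
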