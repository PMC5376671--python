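"""Loading of the packaged default study configuration.

The calibrated model lives in ``configs/default.yaml``; every analysis,
test and script obtains its parameter objects through :func:`load_defaults`
so that the YAML file is the single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .morphogen import GradientParams, NoiseParams
from .network import NetworkSpec, _default_config
from .tissue import TissueConfig

__all__ = ["Defaults", "load_defaults"]


@dataclass(frozen=True)
class Defaults:
    """Bundle of the calibrated default parameter objects."""

    network_basal: NetworkSpec
    network_wt: NetworkSpec
    mirx_strength: float
    gradient: GradientParams
    noise: NoiseParams
    tissue: TissueConfig
    differentiation: dict


def _gradient_from(cfg: dict) -> GradientParams:
    return GradientParams(
        source_strength=tuple(cfg["source_strength"]),
        degradation=tuple(cfg["degradation"]),
        diffusion=tuple(cfg["diffusion"]),
        domain_length=float(cfg["domain_length"]),
        n_cells=int(cfg["n_cells"]),
    )


def _noise_from(cfg: dict) -> NoiseParams:
    return NoiseParams(
        frequency=float(cfg["frequency"]),
        amplitude=float(cfg["amplitude"]),
        per_cell=bool(cfg["per_cell"]),
    )


def _tissue_from(cfg: dict) -> TissueConfig:
    return TissueConfig(
        n_cells=int(cfg["n_cells"]),
        n_replicates=int(cfg["n_replicates"]),
        t_dev=float(cfg["t_dev"]),
        dt=float(cfg["dt"]),
        store_every=float(cfg["store_every"]),
        relax_tol=float(cfg["relax_tol"]),
        relax_t_max=float(cfg["relax_t_max"]),
    )


def load_defaults(path=None) -> Defaults:
    """Parameter objects from a study config file (packaged default if None)."""
    if path is None:
        cfg = _default_config()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    basal = NetworkSpec.from_config(cfg["network"])
    strength = float(cfg["mirx_circuit"]["strength"])
    wt = basal
    for e in cfg["mirx_circuit"]["edges"]:
        wt = wt.with_edge(e["source"], e["target"], e["weight"] * strength)
    return Defaults(
        network_basal=basal,
        network_wt=wt,
        mirx_strength=strength,
        gradient=_gradient_from(cfg["gradient"]),
        noise=_noise_from(cfg["noise"]),
        tissue=_tissue_from(cfg["tissue"]),
        differentiation=dict(cfg["differentiation"]),
    )
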