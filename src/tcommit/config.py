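"""Configuration loading and dumping (YAML or TOML).

A run is fully described by a SimulationConfig; the canonical defaults
(shipped in ``data/defaults.yaml``) mirror the fitted wild-type parameter
set and starting conditions.  A user file only needs the keys it overrides.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .colony import DivisionTimeModel, KnockdownSpec, SimulationConfig
from .epigenetics import EpigeneticParameters, RegulatoryRegion
from .grn import GRNParameters, GeneState

__all__ = ["default_config", "load_config", "config_to_dict",
           "config_from_dict", "dump_config"]


def default_config() -> SimulationConfig:
    return SimulationConfig()


def config_to_dict(config: SimulationConfig) -> Dict[str, Any]:
    grn = {f"p{i}": getattr(config.grn, f"p{i}") for i in range(1, 17)}
    for g in ("gamma_R", "gamma_T", "gamma_G", "gamma_P", "gamma_X"):
        grn[g] = getattr(config.grn, g)
    grn["kd_factors"] = list(config.grn.kd_factors)
    epi = {k: getattr(config.epigenetic, k)
           for k in ("k1", "k2", "k3", "alpha", "beta", "gamma_m", "delta",
                     "epsilon", "S", "open_fraction_threshold")}
    s = config.initial_state
    out: Dict[str, Any] = {
        "grn": grn,
        "epigenetic": epi,
        "division_times": [list(row) for row in config.division.table],
        "initial_state": {"Runx1": s.R, "Tcf7": s.T, "Gata3": s.G,
                          "PU.1": s.P, "X": s.X, "Notch": s.N},
        "initial_region": {"closed": config.initial_region.C,
                           "intermediate": config.initial_region.I,
                           "open": config.initial_region.O,
                           "total": config.initial_region.S},
        "horizon": config.horizon,
        "record_trajectories": config.record_trajectories,
    }
    if config.seed is not None:
        out["seed"] = config.seed
    if config.knockdown is not None:
        out["knockdown"] = {"gene": config.knockdown.gene,
                            "factor": config.knockdown.factor,
                            "onset": config.knockdown.onset}
    return out


def config_from_dict(data: Dict[str, Any]) -> SimulationConfig:
    base = default_config()
    grn_kw = dict(data.get("grn", {}))
    if "kd_factors" in grn_kw:
        grn_kw["kd_factors"] = tuple(grn_kw["kd_factors"])
    grn = dataclasses.replace(base.grn, **grn_kw)
    epi = dataclasses.replace(base.epigenetic, **data.get("epigenetic", {}))
    division = base.division
    if "division_times" in data:
        division = DivisionTimeModel(
            table=tuple(tuple(float(v) for v in row)
                        for row in data["division_times"]))
    state = base.initial_state
    if "initial_state" in data:
        s = data["initial_state"]
        state = GeneState(R=int(s["Runx1"]), T=int(s["Tcf7"]),
                          G=int(s["Gata3"]), P=int(s["PU.1"]),
                          X=int(s["X"]), N=int(s["Notch"]))
    region = base.initial_region
    if "initial_region" in data:
        r = data["initial_region"]
        region = RegulatoryRegion(C=int(r["closed"]),
                                  I=int(r["intermediate"]),
                                  O=int(r["open"]),
                                  S=int(r.get("total", epi.S)))
    kd = None
    if data.get("knockdown"):
        k = data["knockdown"]
        kd = KnockdownSpec(gene=k["gene"], factor=float(k.get("factor", 0.2)),
                           onset=float(k.get("onset", 0.0)))
    return SimulationConfig(
        grn=grn, epigenetic=epi, division=division, initial_state=state,
        initial_region=region, horizon=float(data.get("horizon", base.horizon)),
        knockdown=kd, seed=data.get("seed"),
        record_trajectories=bool(data.get("record_trajectories", False)),
    )


def load_config(path) -> SimulationConfig:
    """Load a YAML (.yaml/.yml) or TOML (.toml) configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib
        data = tomllib.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    return config_from_dict(data)


def dump_config(config: SimulationConfig, path: Optional[Path] = None) -> str:
    """Serialize a configuration to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
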