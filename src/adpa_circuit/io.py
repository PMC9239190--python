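"""Config and file I/O: YAML/JSON configs with unit handling, CSV dialects
for titrations, CT tables and observed-mass lists.

Internal units are nM and minutes; configs and CSVs may declare
concentrations in uM, which are converted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .binding import TitrationCurve
from .circuit import CircuitParams, CircuitState, SulfurSchedule

__all__ = [
    "load_config",
    "dump_config",
    "concentration_factor",
    "params_from_config",
    "state_from_config",
    "schedule_from_config",
    "read_titration_csv",
    "write_titration_csv",
    "read_ct_csv",
    "read_observed_masses",
]

_UNIT_FACTORS = {"nM": 1.0, "uM": 1000.0, "µM": 1000.0, "mM": 1e6}


def load_config(path) -> dict:
    """Parse a JSON or YAML config (YAML is a superset of JSON)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def concentration_factor(unit: str) -> float:
    """Multiplier converting the declared concentration unit to nM."""
    try:
        return _UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def params_from_config(block: dict) -> CircuitParams:
    _check_keys(block, CircuitParams.__dataclass_fields__, "params")
    return CircuitParams(**block)


def state_from_config(block: dict) -> CircuitState:
    _check_keys(block, ("A", "As", "S", "G"), "init")
    return CircuitState(**block)


def schedule_from_config(block: dict) -> SulfurSchedule:
    _check_keys(block, ("events", "baseline_input"), "schedule")
    events = tuple((ev["time"], ev["amount"]) if isinstance(ev, dict)
                   else tuple(ev) for ev in block.get("events", ()))
    return SulfurSchedule(events=events,
                          baseline_input=block.get("baseline_input", 0.0))


def read_titration_csv(csv_path, meta_path) -> TitrationCurve:
    """FP titration from `tf_conc_nM,anisotropy` CSV + sidecar JSON metadata."""
    df = pd.read_csv(csv_path)
    if list(df.columns[:2]) != ["tf_conc_nM", "anisotropy"]:
        raise ValueError("titration CSV must have columns tf_conc_nM,anisotropy")
    meta = json.loads(Path(meta_path).read_text())
    return TitrationCurve(points=tuple(zip(df["tf_conc_nM"], df["anisotropy"])),
                          r_free=meta["r_free"], r_bound=meta["r_bound"],
                          probe_conc=meta["probe_conc_nM"])


def write_titration_csv(curve: TitrationCurve, csv_path, meta_path) -> None:
    pd.DataFrame({"tf_conc_nM": curve.concentrations,
                  "anisotropy": curve.anisotropies}).to_csv(csv_path, index=False)
    Path(meta_path).write_text(json.dumps(
        {"r_free": curve.r_free, "r_bound": curve.r_bound,
         "probe_conc_nM": curve.probe_conc}, indent=2))


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"condition", "replicate", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    return df


def read_observed_masses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "observed_mass_da" not in df.columns:
        raise ValueError("observed-mass CSV needs column observed_mass_da")
    if "intensity" not in df.columns:
        df["intensity"] = float("nan")
    return df
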