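"""Tabular I/O and configuration for the monitoring pipeline.

The canonical on-disk form of a monitoring dataset is a wide CSV with one
row per station-month (columns ``station``, ``date``, then one column per
parameter).  Parameter specifications and pipeline settings travel as YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .synthetic import MonitoringDataset
from .wqi import Curve, ParameterSpec, default_specs

__all__ = [
    "FormatError",
    "read_monitoring_csv",
    "write_monitoring_csv",
    "write_truth",
    "specs_to_yaml",
    "specs_from_yaml",
    "PipelineConfig",
    "load_config",
    "file_sha256",
]

log = logging.getLogger("wqsource")


class FormatError(ValueError):
    """Raised when an input table does not follow the expected layout."""


def write_monitoring_csv(dataset: MonitoringDataset, path: str | Path) -> None:
    """Write a dataset as a wide CSV (station, date, one column per parameter)."""
    frame = dataset.values.reset_index()
    frame["date"] = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m")
    frame.to_csv(path, index=False, float_format="%.10g")


def read_monitoring_csv(
    path: str | Path,
    specs: Mapping[str, ParameterSpec] | None = None,
) -> MonitoringDataset:
    """Read a wide monitoring CSV into a typed dataset.

    Columns not named in the parameter specs are ignored with a warning;
    blank cells become missing values.  Dates are parsed as ISO year-month.
    Rows with unparseable dates are reported together in the raised error.
    """
    specs = specs or default_specs()
    raw = pd.read_csv(path, dtype={"station": str})
    missing = {"station", "date"} - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    known = [c for c in raw.columns if c in specs]
    if not known:
        raise FormatError(f"{path}: no known parameter columns found")
    unknown = [c for c in raw.columns if c not in specs and c not in ("station", "date")]
    if unknown:
        log.warning("%s: ignoring unknown column(s) %s", path, unknown)

    dates = pd.to_datetime(raw["date"], format="mixed", errors="coerce")
    bad = raw.index[dates.isna()]
    if len(bad):
        raise FormatError(
            f"{path}: unparseable date(s) in row(s) {[int(i) + 2 for i in bad]}"  # 1-based + header
        )
    # monthly cadence: normalize to the first of the month
    dates = dates.dt.to_period("M").dt.to_timestamp()

    values = raw[known].apply(pd.to_numeric, errors="coerce")
    values.index = pd.MultiIndex.from_arrays([raw["station"], dates], names=["station", "date"])
    stations = tuple(dict.fromkeys(raw["station"]))
    censored = pd.DataFrame(False, index=values.index, columns=values.columns)
    return MonitoringDataset(stations=stations, values=values, censored=censored)


def write_truth(dataset: MonitoringDataset, profiles_path: str | Path,
                contributions_path: str | Path) -> None:
    """Persist a synthetic dataset's ground truth as CSV sidecars."""
    if dataset.truth_model is None or dataset.truth_contributions is None:
        raise ValueError("dataset carries no ground truth")
    dataset.truth_model.profiles_frame().to_csv(profiles_path, float_format="%.10g")
    g = dataset.truth_contributions.reset_index()
    g["date"] = pd.to_datetime(g["date"]).dt.strftime("%Y-%m")
    g.to_csv(contributions_path, index=False, float_format="%.10g")


def specs_to_yaml(specs: Mapping[str, ParameterSpec], path: str | Path) -> None:
    doc = {
        "parameters": {
            name: {
                "unit": s.unit,
                "weight": s.weight,
                "curve": [list(p) for p in s.curve.points],
                "class_standards": dict(s.class_standards),
                "harmful_direction": s.harmful_direction,
                "mdl": s.mdl,
                "error_fraction": s.error_fraction,
            }
            for name, s in specs.items()
        }
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def specs_from_yaml(path: str | Path) -> dict[str, ParameterSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise FormatError(f"{path}: expected a top-level 'parameters' mapping")
    specs = {}
    for name, block in doc["parameters"].items():
        specs[name] = ParameterSpec(
            name=name,
            unit=block.get("unit", ""),
            weight=int(block["weight"]),
            curve=Curve(tuple(tuple(p) for p in block["curve"])),
            class_standards=dict(block.get("class_standards", {})),
            harmful_direction=block.get("harmful_direction", "high"),
            mdl=float(block.get("mdl", 0.0)),
            error_fraction=float(block.get("error_fraction", 0.1)),
        )
    return specs


@dataclass
class PipelineConfig:
    """Settings of the end-to-end run; every stage seed derives from ``seed``."""

    output_dir: str = "wqsource_out"
    input_csv: str | None = None          # None -> simulate
    specs_file: str | None = None
    seed: int = 0
    # simulate
    n_stations: int = 4
    n_months: int = 107
    n_sources_true: int = 5
    # forest / selection
    n_trees: int = 500
    test_fraction: float = 0.1
    k_values: tuple[int, ...] = (2, 3, 4, 5)
    selection_slack: float = 0.0
    # pmf
    pmf_p: int = 5
    pmf_n_starts: int = 20
    pmf_tol: float = 1e-7
    pmf_max_iter: int = 400

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_values"] = list(self.k_values)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "k_values" in doc:
        doc["k_values"] = tuple(doc["k_values"])
    return PipelineConfig(**doc)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
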