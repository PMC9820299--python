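"""Water-quality index (WQI) computation and grading.

The index is the weighted mean of per-parameter sub-indices

    WQI = sum_i(C_i * P_i) / sum_i(P_i)

where ``C_i`` in [0, 100] is the normalized quality score of parameter *i*
(100 = pristine, 0 = worst) obtained from a breakpoint curve, and ``P_i`` is
a small positive integer weight expressing the parameter's relevance to
drinking-water quality.  Scores are graded into five classes:
Excellent (>= 91), Good (>= 71), Moderate (>= 51), Poor (>= 26),
Very poor otherwise.

Curves and weights ship with sensible defaults for the 14 routinely
monitored surface-water parameters (see :data:`DEFAULT_SPECS`) but are
plain data and fully user-overridable; nothing downstream depends on the
specific default entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Curve",
    "ParameterSpec",
    "WQIResult",
    "GRADE_BANDS",
    "DEFAULT_SPECS",
    "default_specs",
    "normalize_parameter",
    "compute_wqi",
    "compute_wqi_table",
    "classify_wqi",
    "descriptive_stats",
]


@dataclass(frozen=True)
class Curve:
    """Piecewise-linear normalization curve: concentration -> sub-index.

    ``points`` maps strictly increasing concentrations to sub-index values
    in [0, 100].  Between breakpoints the curve interpolates linearly;
    beyond the first/last breakpoint it clamps to that breakpoint's value.
    A non-monotone sequence of sub-index values is allowed (needed for
    range-optimal parameters such as pH).
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("curve needs at least one breakpoint")
        xs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("curve breakpoints must be strictly increasing")
        for _, ci in self.points:
            if not (0.0 <= ci <= 100.0):
                raise ValueError("sub-index breakpoints must lie in [0, 100]")

    def __call__(self, value: float) -> float:
        xs = np.array([p[0] for p in self.points])
        cs = np.array([p[1] for p in self.points])
        return float(np.clip(np.interp(value, xs, cs), 0.0, 100.0))


@dataclass(frozen=True)
class ParameterSpec:
    """Everything the pipeline needs to know about one monitored parameter."""

    name: str
    unit: str
    weight: int
    curve: Curve
    #: class thresholds (e.g. GB3838-2002 classes I-V), ordered best->worst
    class_standards: Mapping[str, float] = field(default_factory=dict)
    #: direction in which exceeding a class threshold is harmful
    harmful_direction: str = "high"  # "high": above threshold is bad; "low": below
    mdl: float = 0.0
    error_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError(f"{self.name}: weight must be >= 1")
        if self.harmful_direction not in ("high", "low"):
            raise ValueError("harmful_direction must be 'high' or 'low'")
        if self.mdl < 0:
            raise ValueError(f"{self.name}: detection limit must be >= 0")
        thresholds = list(self.class_standards.values())
        ordered = sorted(thresholds) if self.harmful_direction == "high" else sorted(thresholds, reverse=True)
        if thresholds != ordered:
            raise ValueError(f"{self.name}: class thresholds must be monotone from best to worst class")


GRADE_BANDS: tuple[tuple[float, str], ...] = (
    (91.0, "Excellent"),
    (71.0, "Good"),
    (51.0, "Moderate"),
    (26.0, "Poor"),
    (0.0, "Very poor"),
)


@dataclass(frozen=True)
class WQIResult:
    value: float
    grade: str
    sub_indices: Mapping[str, float]


def normalize_parameter(value: float, spec: ParameterSpec) -> float:
    """Map a concentration onto the [0, 100] sub-index scale via the spec's curve."""
    if not math.isfinite(value):
        raise ValueError(f"{spec.name}: value must be finite, got {value!r}")
    return spec.curve(value)


def classify_wqi(value: float) -> str:
    """Grade a WQI score into one of the five quality classes."""
    if not math.isfinite(value) or not (0.0 <= value <= 100.0):
        raise ValueError(f"WQI value must lie in [0, 100], got {value!r}")
    for lower, grade in GRADE_BANDS:
        if value >= lower:
            return grade
    return "Very poor"  # pragma: no cover - unreachable, bands cover [0, 100]


def compute_wqi(record: Mapping[str, float], specs: Mapping[str, ParameterSpec]) -> WQIResult:
    """Compute the weighted-mean WQI for one sample.

    Missing (NaN) parameters are excluded from both the numerator and the
    denominator, so the index stays a proper weighted mean of whatever was
    measured.
    """
    sub: dict[str, float] = {}
    num = 0.0
    den = 0.0
    for name, value in record.items():
        if name not in specs:
            raise KeyError(f"no parameter spec for {name!r}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        ci = normalize_parameter(float(value), specs[name])
        sub[name] = ci
        num += ci * specs[name].weight
        den += specs[name].weight
    if den == 0.0:
        raise ValueError("record contains no usable parameter values")
    value = num / den
    return WQIResult(value=value, grade=classify_wqi(value), sub_indices=sub)


def compute_wqi_table(values: pd.DataFrame, specs: Mapping[str, ParameterSpec]) -> pd.DataFrame:
    """Vectorised WQI over a sample x parameter table.

    Returns a frame indexed like ``values`` with columns ``WQI``, ``grade``
    and one sub-index column ``Ci_<param>`` per input parameter.
    """
    params = [c for c in values.columns if c in specs]
    if not params:
        raise ValueError("no known parameters in table")
    ci = pd.DataFrame(index=values.index)
    for name in params:
        curve = specs[name].curve
        xs = np.array([p[0] for p in curve.points])
        cs = np.array([p[1] for p in curve.points])
        v = values[name].to_numpy(dtype=float)
        ci[name] = np.where(np.isnan(v), np.nan, np.clip(np.interp(v, xs, cs), 0.0, 100.0))
    weights = np.array([specs[name].weight for name in params], dtype=float)
    mask = ci.notna().to_numpy()
    num = np.nansum(ci.to_numpy() * weights, axis=1)
    den = (mask * weights).sum(axis=1)
    if np.any(den == 0):
        raise ValueError("some records contain no usable parameter values")
    wqi = num / den
    out = pd.DataFrame(index=values.index)
    out["WQI"] = wqi
    out["grade"] = [classify_wqi(v) for v in wqi]
    for name in params:
        out[f"Ci_{name}"] = ci[name]
    return out


def descriptive_stats(
    values: pd.DataFrame,
    specs: Mapping[str, ParameterSpec],
    station_level: bool = True,
) -> pd.DataFrame:
    """Screening statistics per parameter: mean, sd, CV% and class exceedance.

    ``values`` is a sample x parameter frame; if its index has a ``station``
    level and ``station_level`` is true, per-station rows are emitted in
    addition to the pooled ``all`` rows.  CV is reported in percent and left
    NaN (undefined) for zero-mean series.  Exceedance is the fraction of
    samples worse than each class threshold in the parameter's harmful
    direction.
    """
    if values.empty:
        raise ValueError("empty dataset")

    groups: list[tuple[str, pd.DataFrame]] = [("all", values)]
    if station_level and isinstance(values.index, pd.MultiIndex) and "station" in values.index.names:
        for st, sub in values.groupby(level="station", sort=False):
            groups.append((str(st), sub))

    rows = []
    for label, frame in groups:
        for name in frame.columns:
            if name not in specs:
                continue
            spec = specs[name]
            x = frame[name].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
            cv = float("nan") if mean == 0.0 else 100.0 * sd / mean
            row: dict[str, object] = {
                "station": label,
                "parameter": name,
                "n": int(x.size),
                "mean": mean,
                "sd": sd,
                "cv_percent": cv,
            }
            for cls, thr in spec.class_standards.items():
                if spec.harmful_direction == "high":
                    exceed = float(np.mean(x > thr))
                else:
                    exceed = float(np.mean(x < thr))
                row[f"exceed_{cls}"] = 100.0 * exceed
            rows.append(row)
    return pd.DataFrame(rows)


def _spec(
    name: str,
    unit: str,
    weight: int,
    points: Sequence[tuple[float, float]],
    standards: Mapping[str, float] | None = None,
    harmful: str = "high",
    mdl: float = 0.0,
) -> ParameterSpec:
    return ParameterSpec(
        name=name,
        unit=unit,
        weight=weight,
        curve=Curve(tuple(points)),
        class_standards=dict(standards or {}),
        harmful_direction=harmful,
        mdl=mdl,
    )


# Default specification table for the 14 routinely monitored parameters.
# Weights follow the drinking-water-relevance convention of this WQI family:
# trace metals (Fe, Mn), CODMn, NH3-N and faecal coliform carry weight 3,
# dissolved oxygen 4, and the remaining parameters 1-2.  Curves are
# step-table style piecewise-linear conventions anchored on the GB3838-2002
# class standards where those exist; all entries are overridable via config
# files and none is load-bearing for the algorithms.
DEFAULT_SPECS: dict[str, ParameterSpec] = {
    s.name: s
    for s in [
        _spec("pH", "", 1, [(4.0, 0), (6.0, 60), (6.5, 90), (7.0, 100), (8.5, 90), (9.0, 60), (11.0, 0)]),
        _spec("WT", "degC", 1, [(0.0, 60), (10.0, 80), (16.0, 95), (22.0, 100), (28.0, 80), (34.0, 40), (40.0, 0)]),
        _spec(
            "DO", "mg/L", 4,
            [(0.0, 0), (2.0, 10), (3.0, 25), (5.0, 55), (6.0, 70), (7.5, 90), (9.0, 100)],
            {"I": 7.5, "II": 6.0, "III": 5.0, "IV": 3.0, "V": 2.0},
            harmful="low", mdl=0.2,
        ),
        _spec(
            "TN", "mg/L", 2,
            [(0.1, 100), (0.5, 90), (1.0, 70), (1.5, 50), (2.0, 30), (4.0, 10), (6.0, 0)],
            {"I": 0.2, "II": 0.5, "III": 1.0, "IV": 1.5, "V": 2.0},
            mdl=0.05,
        ),
        _spec(
            "NH3-N", "mg/L", 3,
            [(0.01, 100), (0.15, 95), (0.5, 80), (1.0, 60), (1.5, 40), (2.0, 25), (5.0, 0)],
            {"I": 0.15, "II": 0.5, "III": 1.0, "IV": 1.5, "V": 2.0},
            mdl=0.025,
        ),
        _spec("NO3-N", "mg/L", 2, [(0.5, 100), (2.0, 90), (5.0, 70), (10.0, 50), (20.0, 20), (50.0, 0)], mdl=0.08),
        _spec(
            "TP", "mg/L", 2,
            [(0.01, 100), (0.1, 90), (0.2, 70), (0.3, 50), (0.4, 30), (1.0, 10), (2.0, 0)],
            {"I": 0.02, "II": 0.1, "III": 0.2, "IV": 0.3, "V": 0.4},
            mdl=0.01,
        ),
        _spec(
            "CODMn", "mg/L", 3,
            [(1.0, 100), (2.0, 90), (4.0, 75), (6.0, 60), (10.0, 40), (15.0, 20), (30.0, 0)],
            {"I": 2.0, "II": 4.0, "III": 6.0, "IV": 10.0, "V": 15.0},
            mdl=0.5,
        ),
        _spec("Cl", "mg/L", 1, [(10.0, 100), (50.0, 90), (100.0, 80), (250.0, 60), (500.0, 30), (1000.0, 0)],
              {"III": 250.0}, mdl=1.0),
        _spec("SO4", "mg/L", 1, [(10.0, 100), (50.0, 90), (100.0, 80), (250.0, 60), (500.0, 30), (1000.0, 0)],
              {"III": 250.0}, mdl=5.0),
        _spec(
            "F.coli", "colonies/L", 3,
            [(20.0, 100), (200.0, 90), (2000.0, 70), (10000.0, 50), (20000.0, 30), (40000.0, 15), (100000.0, 0)],
            {"I": 200.0, "II": 2000.0, "III": 10000.0, "IV": 20000.0, "V": 40000.0},
            mdl=20.0,
        ),
        _spec("Fe", "mg/L", 3, [(0.05, 100), (0.1, 90), (0.3, 70), (0.5, 50), (1.0, 30), (2.0, 10), (5.0, 0)],
              {"III": 0.3}, mdl=0.03),
        _spec("Mn", "mg/L", 3, [(0.01, 100), (0.05, 90), (0.1, 70), (0.3, 50), (0.5, 30), (1.0, 10), (2.0, 0)],
              {"III": 0.1}, mdl=0.01),
        _spec("F", "mg/L", 1, [(0.1, 100), (0.5, 90), (1.0, 70), (1.5, 40), (2.0, 20), (4.0, 0)],
              {"III": 1.0}, mdl=0.05),
    ]
}

#: canonical ordering of the 14 default parameters
DEFAULT_PARAMETERS: tuple[str, ...] = tuple(DEFAULT_SPECS)


def default_specs(overrides: Mapping[str, Mapping] | None = None) -> dict[str, ParameterSpec]:
    """Copy of the default spec table, optionally with per-parameter overrides.

    ``overrides`` maps parameter name to a dict of ParameterSpec field
    replacements, e.g. ``{"TN": {"weight": 4}}``.
    """
    specs = dict(DEFAULT_SPECS)
    for name, fields in (overrides or {}).items():
        base = specs[name]
        kwargs = {
            "name": base.name,
            "unit": base.unit,
            "weight": base.weight,
            "curve": base.curve,
            "class_standards": dict(base.class_standards),
            "harmful_direction": base.harmful_direction,
            "mdl": base.mdl,
            "error_fraction": base.error_fraction,
        }
        for key, value in fields.items():
            if key == "curve" and not isinstance(value, Curve):
                value = Curve(tuple(tuple(p) for p in value))
            kwargs[key] = value
        specs[name] = ParameterSpec(**kwargs)
    return specs
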