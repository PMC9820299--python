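"""Source contributions to WQI variation.

Combines the forest's normalized feature importances ``fn_i`` with the
PMF species-contribution shares ``c_ji`` and the surrogate model's error:

    p_j = (1 - MAPE) * sum_i fn_i * c_ji

reported in percent, with the model error (MAPE, in percent) carried as an
explicit final line.  When the importances sum to one and every species
column of ``c`` sums to one, the source contributions plus the model error
total exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forest import ImportanceVector

__all__ = [
    "ApportionmentTable",
    "LabelRule",
    "DEFAULT_LABEL_RULES",
    "apportion_wqi",
    "label_sources",
]


@dataclass(frozen=True)
class LabelRule:
    """A factor earns ``label`` if its mean share over ``species`` is >= ``min_share``."""

    label: str
    species: tuple[str, ...]
    min_share: float


FALLBACK_LABEL = "unexplained variability"

#: dominance rules for the classic river pollution-source types
DEFAULT_LABEL_RULES: tuple[LabelRule, ...] = (
    LabelRule("microbial contamination", ("F.coli",), 0.6),
    LabelRule("heavy metal pollution", ("Fe", "Mn"), 0.6),
    LabelRule("non-point source agricultural pollution", ("TN", "NO3-N", "SO4", "Cl", "F"), 0.45),
    LabelRule("nutrient contamination", ("TP",), 0.5),
)


@dataclass
class ApportionmentTable:
    """Per-source percentage contribution to WQI variation plus model error."""

    table: pd.DataFrame           # columns: source, contribution_percent
    model_error_percent: float
    uncovered_percent: float = 0.0
    labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total_percent(self) -> float:
        return (
            float(self.table["contribution_percent"].sum())
            + self.model_error_percent
            + self.uncovered_percent
        )

    def to_frame(self) -> pd.DataFrame:
        rows = self.table.copy()
        extra = []
        if self.uncovered_percent > 0:
            extra.append({"source": "uncovered importance",
                          "contribution_percent": self.uncovered_percent})
        extra.append({"source": "model error", "contribution_percent": self.model_error_percent})
        return pd.concat([rows, pd.DataFrame(extra)], ignore_index=True)


def apportion_wqi(
    importance: ImportanceVector,
    c: pd.DataFrame,
    mape: float,
    labels: Sequence[str] | None = None,
) -> ApportionmentTable:
    """Attribute WQI variation to pollution sources.

    ``c`` is the factor x species contribution-share table (columns sum to
    one); ``mape`` is the surrogate model's mean absolute percentage error
    as a fraction in [0, 1).  Parameters carrying importance but absent
    from the PMF species set are reported as an explicit "uncovered
    importance" line rather than silently renormalized.
    """
    if not (0.0 <= mape < 1.0):
        raise ValueError("mape must be a fraction in [0, 1)")
    if not importance.defined:
        raise ValueError("importance vector is undefined")
    fn = importance.as_dict()
    unknown = set(c.columns) - set(fn)
    if unknown:
        raise ValueError(f"contribution matrix names parameters without importances: {sorted(unknown)}")
    covered = [name for name in fn if name in c.columns]
    uncovered = [name for name in fn if name not in c.columns]

    cmat = c[covered].to_numpy(dtype=float)
    if np.any(cmat < -1e-12):
        raise ValueError("contribution shares must be nonnegative")
    fn_cov = np.array([fn[name] for name in covered])
    p_frac = (1.0 - mape) * (cmat @ fn_cov)          # per-factor fraction
    uncovered_frac = (1.0 - mape) * sum(fn[name] for name in uncovered)

    n_factors = len(c.index)
    if labels is None:
        labels = [str(ix) for ix in c.index]
    if len(labels) != n_factors:
        raise ValueError("one label per factor required")

    table = pd.DataFrame(
        {"source": list(labels), "contribution_percent": 100.0 * p_frac}
    ).sort_values("contribution_percent", ascending=False, kind="stable").reset_index(drop=True)
    return ApportionmentTable(
        table=table,
        model_error_percent=100.0 * mape,
        uncovered_percent=100.0 * uncovered_frac,
        labels=tuple(labels),
    )


def label_sources(
    c: pd.DataFrame,
    rules: Sequence[LabelRule] = DEFAULT_LABEL_RULES,
) -> tuple[str, ...]:
    """Name each factor by the first dominance rule it satisfies.

    A rule fires when the factor's mean contribution share over the rule's
    species reaches the rule's threshold; factors matching no rule fall
    back to "unexplained variability".
    """
    labels = []
    for _, row in c.iterrows():
        label = FALLBACK_LABEL
        for rule in rules:
            species = [s for s in rule.species if s in c.columns]
            if not species:
                continue
            if float(np.nanmean([row[s] for s in species])) >= rule.min_share:
                label = rule.label
                break
        labels.append(label)
    return tuple(labels)
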