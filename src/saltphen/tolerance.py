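"""Composite salt-tolerance index.

Workflow: per-indicator relative values (treatment mean as % of control mean)
→ polarity-aware min–max standardization across genotypes → unweighted mean
of the standardized values per genotype → descending rank (1 = most
tolerant).  The indicator set is configurable; the shipped default is the 15
shoot/root/leaf physio-biochemical parameters used for wheat genotype
screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorSpec",
    "ToleranceScore",
    "DEFAULT_INDICATORS",
    "relative_value",
    "standardize_column",
    "standardize_matrix",
    "composite_score",
    "rank_genotypes",
    "assess",
]

POLARITIES = ("positive", "negative")


@dataclass(frozen=True)
class IndicatorSpec:
    """One tolerance indicator: which assay/tissue it comes from and its polarity.

    ``polarity`` states how the *relative value* correlates with tolerance:
    ``positive`` — larger relative value means more tolerant (growth,
    osmolytes, antioxidants, chlorophyll); ``negative`` — larger relative
    value means more damage (lipid peroxidation, Na+/K+ ratio).
    """

    index_id: str
    name: str
    tissue: str
    polarity: str
    assay: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")


@dataclass(frozen=True)
class ToleranceScore:
    genotype: str
    score: float
    rank: int
    tied: bool = False


# Default 15-parameter panel.  Polarities reproduce the published
# standardized table: dry weights and chlorophyll behave as positively
# correlated there (least reduction → SV of 1), so they default to positive;
# lipid peroxidation and Na+/K+ remain negative.
DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("I1", "Dry weight of shoot", "shoot", "positive", "dry_weight"),
    IndicatorSpec("I2", "Dry weight of root", "root", "positive", "dry_weight"),
    IndicatorSpec("I3", "Proline content in shoot", "shoot", "positive", "proline"),
    IndicatorSpec("I4", "Proline content in root", "root", "positive", "proline"),
    IndicatorSpec("I5", "Soluble sugar content in shoot", "shoot", "positive", "soluble_sugar"),
    IndicatorSpec("I6", "Soluble sugar content in root", "root", "positive", "soluble_sugar"),
    IndicatorSpec("I7", "Total phenolics content in shoot", "shoot", "positive", "tpc"),
    IndicatorSpec("I8", "Total phenolics content in root", "root", "positive", "tpc"),
    IndicatorSpec("I9", "Lipid peroxidation in shoot", "shoot", "negative", "mda"),
    IndicatorSpec("I10", "Lipid peroxidation in root", "root", "negative", "mda"),
    IndicatorSpec("I11", "Antioxidant potential of shoot", "shoot", "positive", "antioxidant"),
    IndicatorSpec("I12", "Antioxidant potential of root", "root", "positive", "antioxidant"),
    IndicatorSpec("I13", "Na+/K+ ratio in shoot", "shoot", "negative", "na_k_ratio"),
    IndicatorSpec("I14", "Na+/K+ ratio in root", "root", "negative", "na_k_ratio"),
    IndicatorSpec("I15", "Total chlorophyll content of leaf", "leaf", "positive", "total_chlorophyll"),
)


def relative_value(treated_mean: float, control_mean: float) -> float:
    """Treatment mean as a percentage of the control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * treated_mean / control_mean


def standardize_column(
    values: Sequence[float], polarity: str, indicator: str = ""
) -> np.ndarray:
    """Min–max standardize one indicator column across genotypes.

    positive: X' = (X - Xmin)/(Xmax - Xmin);
    negative: X' = 1 - (X - Xmin)/(Xmax - Xmin).
    A constant column leaves the formula undefined and raises.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 genotypes to standardize")
    if not np.all(np.isfinite(x)):
        raise ValueError("relative values must be finite")
    lo, hi = x.min(), x.max()
    if lo == hi:
        label = f" for indicator {indicator!r}" if indicator else ""
        raise ValueError(
            f"constant column{label}: min == max, standardization undefined"
        )
    sv = (x - lo) / (hi - lo)
    return sv if polarity == "positive" else 1.0 - sv


def standardize_matrix(
    relative: pd.DataFrame, polarities: Mapping[str, str]
) -> pd.DataFrame:
    """Standardize a (indicator × genotype) relative-value matrix row-wise.

    ``relative`` has indicators as the index and genotypes as columns;
    ``polarities`` maps each indicator index label to its polarity.
    """
    missing = [i for i in relative.index if i not in polarities]
    if missing:
        raise ValueError(f"no polarity configured for indicators: {missing}")
    rows = {
        ind: standardize_column(relative.loc[ind].to_numpy(), polarities[ind], str(ind))
        for ind in relative.index
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=relative.columns).loc[
        relative.index
    ]


def composite_score(standardized: pd.DataFrame) -> pd.Series:
    """Unweighted mean of the standardized values per genotype (column)."""
    if standardized.isna().any().any():
        absent = [
            str(i) for i in standardized.index[standardized.isna().any(axis=1)]
        ]
        raise ValueError(f"missing standardized values for indicators: {absent}")
    return standardized.mean(axis=0)


def rank_genotypes(scores: Mapping[str, float] | pd.Series) -> list[ToleranceScore]:
    """Rank genotypes by composite score, descending (rank 1 = most tolerant).

    Ties share the lower rank number (minimum-rank convention) and are
    flagged.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("no scores to rank")
    out = []
    vals = s.to_numpy()
    for genotype, score in s.items():
        rank = 1 + int(np.sum(vals > score))
        tied = int(np.sum(vals == score)) > 1
        out.append(ToleranceScore(str(genotype), float(score), rank, tied))
    out.sort(key=lambda t: (t.rank, t.genotype))
    return out


def assess(
    relative: pd.DataFrame, polarities: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series, list[ToleranceScore]]:
    """Full assessment: standardized matrix, composite scores, and ranking."""
    sv = standardize_matrix(relative, polarities)
    scores = composite_score(sv)
    return sv, scores, rank_genotypes(scores)


def default_polarities(
    indicators: Iterable[IndicatorSpec] = DEFAULT_INDICATORS,
) -> dict[str, str]:
    return {spec.index_id: spec.polarity for spec in indicators}
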