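"""Group-comparison statistics: one-way ANOVA, Fisher's LSD with compact
letter display, and the exact Fisher 2×2 test.

The LSD test uses the pooled ANOVA error variance:
LSD_ij = t(1 - α/2, df_within) * sqrt(MSE * (1/n_i + 1/n_j)), a pair being
significant iff |mean_i - mean_j| > LSD_ij.  By default the test is
"protected": pairwise decisions are only made when the ANOVA F test itself is
significant at α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "AnovaResult",
    "LsdResult",
    "one_way_anova",
    "fisher_lsd",
    "compact_letter_display",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class AnovaResult:
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_error: float
    f_statistic: float
    p_value: float


@dataclass
class LsdResult:
    """Pairwise LSD decisions plus the per-level means and letter display."""

    anova: AnovaResult
    alpha: float
    protected: bool
    means: dict[str, float]
    ns: dict[str, int]
    lsd: dict[tuple[str, str], float]  # threshold per (unordered) pair
    significant: dict[tuple[str, str], bool]
    letters: dict[str, str] = field(default_factory=dict)

    def is_significant(self, a: str, b: str) -> bool:
        if a == b:
            return False
        key = (a, b) if (a, b) in self.significant else (b, a)
        return self.significant[key]

    @property
    def lsd_value(self) -> float:
        """Single LSD threshold; only defined for a balanced design."""
        vals = set(round(v, 12) for v in self.lsd.values())
        if len(vals) != 1:
            raise ValueError("unequal group sizes: no single LSD value")
        return next(iter(self.lsd.values()))


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need >= 2 factor levels")
    for level, obs in groups.items():
        if len(obs) < 2:
            raise ValueError(f"level {level!r} has < 2 observations")
        if not np.all(np.isfinite(np.asarray(obs, dtype=float))):
            raise ValueError(f"level {level!r} contains non-finite values")


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard between/within sums-of-squares decomposition.

    P-value from the F(k-1, N-k) distribution.  Identical groups give F = 0,
    p = 1; a zero within-group variance with differing means gives
    F = inf, p = 0.
    """
    _validate_groups(groups)
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_e = ss_within / df_w
    if ms_e == 0:
        f = 0.0 if ms_b == 0 else math.inf
        p = 1.0 if ms_b == 0 else 0.0
    else:
        f = ms_b / ms_e
        p = float(_sps.f.sf(f, df_b, df_w))
    return AnovaResult(df_b, df_w, ss_between, ss_within, ms_b, ms_e, f, p)


def fisher_lsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    protected: bool = True,
) -> LsdResult:
    """Fisher's least-significant-difference test on all level pairs.

    With ``protected=True`` (default) pairwise significance is declared only
    when the omnibus ANOVA is itself significant at ``alpha``; the LSD
    thresholds are reported either way.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    anova = one_way_anova(groups)
    levels = list(groups)
    means = {g: float(np.mean(groups[g])) for g in levels}
    ns = {g: len(groups[g]) for g in levels}
    t_crit = float(_sps.t.ppf(1 - alpha / 2, anova.df_within))
    gate_open = (not protected) or (anova.p_value <= alpha)
    lsd: dict[tuple[str, str], float] = {}
    sig: dict[tuple[str, str], bool] = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            thr = t_crit * math.sqrt(anova.ms_error * (1 / ns[a] + 1 / ns[b]))
            lsd[(a, b)] = thr
            sig[(a, b)] = gate_open and abs(means[a] - means[b]) > thr
    result = LsdResult(anova, alpha, protected, means, ns, lsd, sig)
    result.letters = compact_letter_display(means, result.is_significant)
    return result


def compact_letter_display(means, significant) -> dict[str, str]:
    """Assign letters so that two levels share a letter iff not significantly
    different (insert-and-absorb algorithm).

    ``significant`` is either a callable ``(a, b) -> bool`` or a symmetric
    nested mapping ``sig[a][b] -> bool``.
    """
    levels = sorted(means, key=lambda g: -means[g])
    if callable(significant):
        is_sig = significant
    else:
        for a in levels:
            for b in levels:
                if a != b and significant[a][b] != significant[b][a]:
                    raise ValueError("significance matrix is not symmetric")
        is_sig = lambda a, b: significant[a][b]  # noqa: E731

    # Insert-and-absorb: start from one all-inclusive letter column and split
    # it on every significant pair, absorbing columns that become subsets.
    columns: list[set] = [set(levels)]
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if not is_sig(a, b):
                continue
            new_cols: list[set] = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            columns = [
                c
                for c in new_cols
                if c and not any(c < other for other in new_cols)
            ]
            # drop exact duplicates, order-preserving
            seen: list[set] = []
            for c in columns:
                if c not in seen:
                    seen.append(c)
            columns = seen

    # Letter order follows the highest-mean member of each column.
    columns.sort(key=lambda c: min(levels.index(g) for g in c))
    letters = {g: "" for g in levels}
    for idx, col in enumerate(columns):
        ch = chr(ord("a") + idx) if idx < 26 else f"({idx + 1})"
        for g in levels:
            if g in col:
                letters[g] += ch
    return letters


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sided: str = "two"
) -> float:
    """Exact Fisher test p-value for the 2×2 table [[a, b], [c, d]].

    Two-sided p is the total hypergeometric probability (margins fixed) of
    all tables at most as probable as the observed one, with a 1 + 1e-7
    relative guard on the tie comparison.  One-sided options: ``"greater"`` /
    ``"less"`` test enrichment of cell ``a``.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # a degenerate margin fixes the table completely
    dist = _sps.hypergeom(n, r1, c1)
    k_lo = max(0, c1 - (c + d))
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(a)
    if sided == "two":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif sided == "greater":
        p = float(pmf[ks >= a].sum())
    elif sided == "less":
        p = float(pmf[ks <= a].sum())
    else:
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    return min(p, 1.0)
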