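"""Group statistics for per-condition pumping rates.

One-way ANOVA across lipid-composition conditions, Tukey's honestly
significant difference test (Tukey-Kramer form for unequal replication),
a compact letter display for figure annotation, and five-number boxplot
summaries (median, quartiles, whiskers to the extremes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "TukeyResult",
    "BoxplotSummary",
    "anova_oneway",
    "tukey_hsd",
    "letter_display",
    "boxplot_summary",
    "significance_tier",
]


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise comparisons at family error rate ``alpha``.

    ``table`` has one row per unordered pair with columns
    group1, group2, mean_diff, q, p_adj, significant.
    """

    table: pd.DataFrame
    alpha: float
    groups: tuple[str, ...]

    def p_adj(self, a: str, b: str) -> float:
        t = self.table
        row = t[((t.group1 == a) & (t.group2 == b)) | ((t.group1 == b) & (t.group2 == a))]
        if row.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(row.p_adj.iloc[0])


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise InsufficientDataError(f"group {name!r} has n < 2")
        if not np.all(np.isfinite(arr)):
            raise DegenerateDataError(f"group {name!r} contains non-finite values")
        out[name] = arr
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in out.values())
    if ss_within == 0:
        raise DegenerateDataError("zero pooled within-group variance")
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    arrs = _validate_groups(groups)
    f, p = sps.f_oneway(*arrs.values())
    return float(f), float(p)


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey's HSD with the Tukey-Kramer correction for unequal group sizes.

    For each pair the studentized-range statistic is
    q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) and the adjusted p-value
    is the survival function of the studentized range with k groups and the
    pooled within-group degrees of freedom.
    """
    arrs = _validate_groups(groups)
    names = list(arrs)
    k = len(names)
    n_tot = sum(a.size for a in arrs.values())
    df_within = n_tot - k
    msw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values()) / df_within

    rows = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = arrs[a], arrs[b]
        diff = float(xa.mean() - xb.mean())
        se = np.sqrt(msw / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        q = abs(diff) / se
        p = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
        rows.append((a, b, diff, float(q), p, p <= alpha))
    table = pd.DataFrame(
        rows, columns=["group1", "group2", "mean_diff", "q", "p_adj", "significant"]
    )
    return TukeyResult(table=table, alpha=alpha, groups=tuple(names))


def letter_display(result: TukeyResult, alpha: float | None = None) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different at ``alpha``
    (default: the family alpha of the Tukey result).
    """
    alpha = result.alpha if alpha is None else alpha
    groups = list(result.groups)
    sig_pairs = [
        (r.group1, r.group2)
        for r in result.table.itertuples()
        if r.p_adj <= alpha
    ]
    # Piepho-style: start from one all-inclusive letter, split on each
    # significant pair, absorb redundant subsets.
    letters: list[set[str]] = [set(groups)]
    for a, b in sig_pairs:
        new = []
        for s in letters:
            if a in s and b in s:
                new.extend([s - {a}, s - {b}])
            else:
                new.append(s)
        # absorb sets contained in another
        letters = [s for s in new if s and not any(s < t for t in new)]
        # deduplicate
        uniq = []
        for s in letters:
            if s not in uniq:
                uniq.append(s)
        letters = uniq
    letters.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letters):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Median, quartiles (linear interpolation) and whiskers at the extremes."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("empty group")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return BoxplotSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(arr.min()),
        whisker_high=float(arr.max()),
    )


def significance_tier(p: float) -> str:
    """ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
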