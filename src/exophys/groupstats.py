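"""Group statistics: ANOVA/Tukey-Kramer, Mann-Whitney, rank utilities, ECDF.

These are the comparisons applied across experimental groups (one value
per cell or replicate): one-way ANOVA with the Tukey-Kramer post test for
three or more groups (unequal n supported), the Mann-Whitney U test for
two-group comparisons of non-normal quantities, Dunn's rank-based post
test (used with Kruskal-Wallis), and empirical cumulative distributions
for event-parameter summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from exophys.errors import ParameterError

__all__ = [
    "GroupTable",
    "anova_tukey",
    "mann_whitney",
    "dunn_test",
    "ecdf",
    "significance_stars",
]


@dataclass
class GroupTable:
    """A labelled group of numeric observations (one per cell/replicate)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ParameterError(f"group {self.label!r} must hold >= 1 value")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"group {self.label!r} contains non-finite values")


def significance_stars(p: float) -> str:
    """Conventional significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_tukey(groups: Sequence[GroupTable]) -> dict:
    """One-way ANOVA with Tukey-Kramer pairwise post test.

    The Tukey-Kramer form of the studentized-range test supports unequal
    group sizes.  Returns the omnibus F and p plus a pairwise table with
    p-values and significance stars.
    """
    if len(groups) < 3:
        raise ParameterError("need at least 3 groups (use mann_whitney for two)")
    for g in groups:
        if g.values.size < 2:
            raise ParameterError(f"group {g.label!r} needs at least 2 values")
    F, p = stats.f_oneway(*(g.values for g in groups))
    values = np.concatenate([g.values for g in groups])
    labels = np.concatenate([[g.label] * g.values.size for g in groups])
    tk = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    table["p-adj"] = tk.pvalues
    table["stars"] = [significance_stars(pv) for pv in tk.pvalues]
    return {"F": float(F), "p": float(p), "pairwise": table}


def mann_whitney(a: GroupTable, b: GroupTable) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact for small samples (both n <= 8, no ties); the normal
    approximation with tie correction otherwise.  Identical samples (all
    ranks tied) return p = 1.
    """
    x, y = a.values, b.values
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return 1.0
    if x.size <= 8 and y.size <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(min(res.pvalue, 1.0))


def dunn_test(
    groups: Mapping[str, np.ndarray],
    control: str | None = None,
    adjust: str = "bonferroni",
) -> dict[str, float]:
    """Dunn's rank-based post test with tie correction.

    Pairwise z statistics on pooled mean ranks,

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with the tie term ``T = sum(t^3 - t) / (12 (N - 1))``.  When
    ``control`` is given only comparisons against the control are made
    (and adjusted for); otherwise all pairs.  Returns a mapping of group
    (or "a|b" pair) to adjusted two-sided p.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    i0 = 0
    for g, arr in zip(labels, arrays):
        mean_ranks[g] = ranks[i0:i0 + arr.size].mean()
        i0 += arr.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    if control is not None:
        pairs = [(control, g) for g in labels if g != control]
    else:
        pairs = [(labels[i], labels[j]) for i in range(len(labels))
                 for j in range(i + 1, len(labels))]
    m = len(pairs)
    out: dict[str, float] = {}
    for gi, gj in pairs:
        ni, nj = groups[gi].size, groups[gj].size
        se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(p * m, 1.0)
        elif adjust != "none":
            raise ParameterError(f"unknown adjustment {adjust!r}")
        key = gj if control is not None else f"{gi}|{gj}"
        out[key] = float(p)
    return out


def ecdf(values: Sequence[float] | np.ndarray) -> pd.DataFrame:
    """Right-continuous empirical CDF as a (value, cumfreq) step table.

    One row per sorted unique value; ``cumfreq`` rises from >0 to exactly
    1 at the sample maximum.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("ecdf of an empty sample is undefined")
    res = stats.ecdf(v)
    return pd.DataFrame({
        "value": res.cdf.quantiles,
        "cumfreq": res.cdf.probabilities,
    })
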