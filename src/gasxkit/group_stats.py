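"""Panel-level statistics: ANOVA, Tukey HSD, compact letter display, Pearson.

One- and two-way fixed-effects ANOVA (sequential sums of squares, so
unbalanced accession panels decompose sensibly), Tukey's honestly-significant-
difference test with the Tukey–Kramer harmonic-mean correction for unequal
replicate counts, and the compact letter display used to annotate trait
figures: groups sharing a letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TukeyPair",
    "TukeyResult",
    "anova",
    "tukey_hsd",
    "compact_letter_display",
    "pearson",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _letter(i: int) -> str:
    # a..z, then aa, ab, ... for pathologically many groups
    if i < 26:
        return _LETTERS[i]
    return _LETTERS[i // 26 - 1] + _LETTERS[i % 26]


def anova(
    values: Sequence[float],
    factors: Sequence[Sequence[str]] | Sequence[str],
    interaction: bool = False,
) -> pd.DataFrame:
    """One- or two-way fixed-effects ANOVA.

    Parameters
    ----------
    values : array-like of measurements.
    factors : one categorical label vector, or a sequence of two of them.
    interaction : include the two-way interaction term (two factors only).

    Returns
    -------
    DataFrame indexed by term with columns df, sum_sq, F, p and a
    ``degenerate`` flag (True when the residual variance is exactly zero, in
    which case p is reported as 0 for separated groups).

    Unbalanced designs use sequential (type I) sums of squares.
    """
    y = np.asarray(values, dtype=float)
    if np.ndim(factors[0]) == 0 or isinstance(factors[0], str):
        factor_list = [np.asarray(factors, dtype=object)]
    else:
        factor_list = [np.asarray(f, dtype=object) for f in factors]
    if len(factor_list) not in (1, 2):
        raise ValueError("anova supports one or two factors")
    if interaction and len(factor_list) != 2:
        raise ValueError("interaction requires two factors")
    data = {"y": y}
    terms = []
    for i, f in enumerate(factor_list):
        if len(f) != len(y):
            raise ValueError("factor length must match values length")
        name = f"f{i}"
        levels, counts = np.unique(f, return_counts=True)
        if len(levels) < 2:
            raise ValueError(f"factor {i} needs ≥2 levels, got {len(levels)}")
        if counts.min() < 1:
            raise ValueError(f"factor {i} has an empty level")
        data[name] = f
        terms.append(f"C({name})")
    if interaction:
        terms.append("C(f0):C(f1)")
    df = pd.DataFrame(data)
    formula = "y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid < 2:
        raise ValueError(f"need ≥2 residual degrees of freedom, got {fit.df_resid:g}")

    degenerate = fit.ssr <= 1e-12 * max(float(np.var(y) * len(y)), 1.0)
    if degenerate:
        # zero residual variance: F is infinite for any term with effect
        rows = [(term, np.nan, np.inf, 0.0) for term in terms]
        tab = pd.DataFrame(rows, columns=["term", "sum_sq", "F", "p"]).set_index("term")
        tab["df"] = np.nan
        tab["degenerate"] = True
        return tab[["df", "sum_sq", "F", "p", "degenerate"]]

    tab = sm.stats.anova_lm(fit, typ=1)
    tab = tab.loc[tab.index != "Residual", ["df", "sum_sq", "F", "PR(>F)"]]
    tab = tab.rename(columns={"PR(>F)": "p"})
    tab["degenerate"] = False
    return tab


@dataclass(frozen=True)
class TukeyPair:
    group_i: str
    group_j: str
    mean_diff: float
    q_stat: float
    p_adj: float


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD comparisons plus the compact letter display."""

    pairs: list[TukeyPair]
    alpha: float
    letters: dict[str, str]
    groups: list[str]
    ms_within: float
    df_within: float

    def pair(self, a: str, b: str) -> TukeyPair:
        for p in self.pairs:
            if {p.group_i, p.group_j} == {a, b}:
                return p
        raise KeyError((a, b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.group_i, p.group_j, p.mean_diff, p.q_stat, p.p_adj) for p in self.pairs],
            columns=["group_i", "group_j", "mean_diff", "q_stat", "p_adj"],
        )


def tukey_hsd(values: Sequence[float], groups: Sequence[str], alpha: float = 0.05) -> TukeyResult:
    """Tukey's HSD over all group pairs, with letters.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group mean square; unequal replicate counts use the
    Tukey–Kramer harmonic-mean standard error.  Letters are assigned with
    :func:`compact_letter_display` so that two groups share a letter iff
    their adjusted p exceeds ``alpha``.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    labels = sorted(set(map(str, g)))
    if len(labels) < 2:
        raise ValueError("tukey_hsd needs at least two groups")
    means = {}
    ns = {}
    ss_within = 0.0
    for lab in labels:
        sel = y[g.astype(str) == lab]
        if len(sel) < 2:
            raise ValueError(f"group {lab!r} needs ≥2 observations for Tukey HSD")
        means[lab] = float(sel.mean())
        ns[lab] = len(sel)
        ss_within += float(((sel - sel.mean()) ** 2).sum())
    df_within = len(y) - len(labels)
    ms_within = ss_within / df_within
    k = len(labels)

    pairs_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
    diffs = np.array([means[labels[j]] - means[labels[i]] for i, j in pairs_idx])
    se = np.array(
        [
            np.sqrt(ms_within / 2.0 * (1.0 / ns[labels[i]] + 1.0 / ns[labels[j]]))
            for i, j in pairs_idx
        ]
    )
    if ms_within == 0:
        q = np.where(diffs == 0, 0.0, np.inf)
        p_adj = np.where(diffs == 0, 1.0, 0.0)
    else:
        q = np.abs(diffs) / se
        p_adj = stats.studentized_range.sf(q, k, df_within)
        p_adj = np.clip(p_adj, 0.0, 1.0)

    pairs = [
        TukeyPair(labels[i], labels[j], float(d), float(qq), float(pp))
        for (i, j), d, qq, pp in zip(pairs_idx, diffs, q, p_adj)
    ]
    nonsig = np.ones((k, k), dtype=bool)
    for (i, j), pp in zip(pairs_idx, p_adj):
        nonsig[i, j] = nonsig[j, i] = pp > alpha
    letters = compact_letter_display(nonsig, labels)
    return TukeyResult(
        pairs=pairs, alpha=alpha, letters=letters, groups=labels,
        ms_within=ms_within, df_within=float(df_within),
    )


def compact_letter_display(nonsig: np.ndarray, groups: Sequence[str] | None = None) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Parameters
    ----------
    nonsig : (k, k) symmetric boolean matrix with True diagonal;
        ``nonsig[i, j]`` is True when groups i and j are NOT significantly
        different (and therefore must share a letter).
    groups : group names in matrix order (defaults to g0, g1, …).

    Returns a map group → letter string such that two groups share at least
    one letter iff their pair is non-significant.  Columns are split for each
    significant pair and then absorbed to a fixpoint, which keeps the letter
    count minimal-ish; the construction is deterministic in group order.
    """
    M = np.asarray(nonsig, dtype=bool)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("nonsig must be a square matrix")
    if not np.array_equal(M, M.T):
        raise ValueError("nonsig matrix must be symmetric")
    if not np.all(np.diag(M)):
        raise ValueError("nonsig matrix must have a True diagonal")
    k = M.shape[0]
    if groups is None:
        groups = [f"g{i}" for i in range(k)]
    groups = list(groups)
    if len(groups) != k:
        raise ValueError("group names must match matrix size")

    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if M[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    a, b = col - {j}, col - {i}
                    for cand in (a, b):
                        if cand:
                            new_cols.append(cand)
                else:
                    new_cols.append(col)
            # absorb: drop strict subsets and duplicates (first occurrence kept)
            absorbed: list[set[int]] = []
            for col in new_cols:
                if any(col < other for other in new_cols):
                    continue
                if col not in absorbed:
                    absorbed.append(col)
            columns = absorbed

    # final safety net: every non-significant pair must co-occur in a column
    for i in range(k):
        for j in range(i + 1, k):
            if M[i, j] and not any(i in col and j in col for col in columns):
                columns.append({i, j})

    # deterministic letter order: sort columns by their smallest member
    columns.sort(key=lambda col: sorted(col))
    out = {name: "" for name in groups}
    for li, col in enumerate(columns):
        for i in sorted(col):
            out[groups[i]] += _letter(li)
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
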