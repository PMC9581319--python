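"""Inference layer: balanced two-way ANOVA, post-hoc letters, gates.

Everything here is computed closed-form rather than delegated, because the
central use case — reconstructing F statistics from a published table of
cell means and standard deviations — needs the summary-statistics path,
and the raw-data path must be provably identical to it.  For a balanced
a x b design with n replicates per cell the sums of squares are

    SS_A  = b n sum_i (m_i. - m..)^2
    SS_B  = a n sum_j (m_.j - m..)^2
    SS_AB = n sum_ij (m_ij - m_i. - m_.j + m..)^2
    SS_res = sum_ij (n - 1) s_ij^2

so the whole table is a function of the cell means and SDs only; under
balance the Type I/II/III decompositions coincide.

Also provided: the arcsine-square-root transform for proportions, the
Bonferroni pairwise test with a compact letter display, Pearson
correlation with the t-transform p-value, the D'Agostino-Pearson K^2
normality omnibus and the Levene homogeneity-of-variance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InsufficientSampleError,
    InvalidInputError,
    UndefinedStatisticError,
    UnsupportedDesignError,
)

__all__ = [
    "AnovaTable",
    "arcsine_sqrt_transform",
    "two_way_anova",
    "anova_from_summaries",
    "summaries_from_table",
    "bonferroni_posthoc",
    "pearson_correlation",
    "normality_check",
    "variance_homogeneity_check",
]

_FACTOR_A = "factorA"
_FACTOR_B = "factorB"
_VALUE = "value"


@dataclass(frozen=True)
class AnovaTable:
    """Balanced two-way ANOVA with interaction.

    ``overflow`` flags an exactly-zero residual mean square (all cell SDs
    zero with unequal means); the affected F values are ``inf``.
    """

    table: pd.DataFrame  # index: A, B, A:B, Residual; cols: df, ss, ms, F, p
    a: int
    b: int
    n: int
    overflow: bool = False

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    @property
    def ms_residual(self) -> float:
        return float(self.table.loc["Residual", "ms"])

    @property
    def df_residual(self) -> int:
        return int(self.table.loc["Residual", "df"])


def arcsine_sqrt_transform(p):
    """``asin(sqrt(p))`` in radians, for proportions ``p`` in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise InvalidInputError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = {_FACTOR_A, _FACTOR_B, _VALUE} - set(table.columns)
    if missing:
        raise InvalidInputError(f"factorial table missing columns: {sorted(missing)}")
    return table


def _cell_layout(table: pd.DataFrame):
    counts = table.groupby([_FACTOR_A, _FACTOR_B], sort=True).size()
    a_levels = sorted(table[_FACTOR_A].unique())
    b_levels = sorted(table[_FACTOR_B].unique())
    if len(counts) != len(a_levels) * len(b_levels):
        raise UnsupportedDesignError("incomplete factorial grid (missing cells)")
    if counts.nunique() != 1:
        raise UnsupportedDesignError(
            "unbalanced design: closed-form path requires equal n per cell "
            "(use a regression-based ANOVA, out of scope here)"
        )
    return a_levels, b_levels, int(counts.iloc[0])


def _assemble(ss_a, ss_b, ss_ab, ss_res, a, b, n) -> AnovaTable:
    df_a, df_b, df_ab, df_res = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    dfs = np.array([df_a, df_b, df_ab, df_res], dtype=float)
    sss = np.array([ss_a, ss_b, ss_ab, ss_res], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mss = sss / dfs
        overflow = mss[3] == 0.0
        fs = mss[:3] / mss[3]  # inf (or nan for 0/0) when MS_res == 0
        ps = sps.f.sf(fs, dfs[:3], dfs[3])
    tbl = pd.DataFrame(
        {
            "df": dfs.astype(int),
            "ss": sss,
            "ms": mss,
            "F": np.append(fs, np.nan),
            "p": np.append(ps, np.nan),
        },
        index=["A", "B", "A:B", "Residual"],
    )
    return AnovaTable(table=tbl, a=a, b=b, n=n, overflow=bool(overflow))


def two_way_anova(table: pd.DataFrame) -> AnovaTable:
    """Closed-form balanced two-way ANOVA with interaction on raw replicates.

    ``table`` is long-format with columns ``factorA``, ``factorB``,
    ``value``; the design must be a complete grid with equal n >= 2 per
    cell.
    """
    table = _check_table(table)
    a_levels, b_levels, n = _cell_layout(table)
    if n < 2:
        raise UnsupportedDesignError("need >= 2 replicates per cell for a residual term")
    a, b = len(a_levels), len(b_levels)

    g = table.groupby([_FACTOR_A, _FACTOR_B], sort=True)[_VALUE]
    means = g.mean().unstack()  # a x b
    m = means.to_numpy(dtype=float)
    grand = m.mean()
    row = m.mean(axis=1)
    col = m.mean(axis=0)
    ss_a = b * n * np.sum((row - grand) ** 2)
    ss_b = a * n * np.sum((col - grand) ** 2)
    ss_ab = n * np.sum((m - row[:, None] - col[None, :] + grand) ** 2)
    ss_res = float(g.apply(lambda v: np.sum((v - v.mean()) ** 2)).sum())
    return _assemble(ss_a, ss_b, ss_ab, ss_res, a, b, n)


def summaries_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Exact per-cell (mean, sd, n) summaries of a raw factorial table."""
    table = _check_table(table)
    out = (
        table.groupby([_FACTOR_A, _FACTOR_B], sort=True)[_VALUE]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )
    return out


def anova_from_summaries(cells: pd.DataFrame) -> AnovaTable:
    """Two-way ANOVA reconstructed from per-cell means and SDs.

    ``cells`` has columns ``factorA``, ``factorB``, ``mean``, ``sd``,
    ``n`` covering a complete balanced grid.  Feeding the exact summaries
    of a raw table reproduces :func:`two_way_anova` on that table.
    """
    required = {_FACTOR_A, _FACTOR_B, "mean", "sd", "n"}
    missing = required - set(cells.columns)
    if missing:
        raise InvalidInputError(f"summary table missing columns: {sorted(missing)}")
    a_levels = sorted(cells[_FACTOR_A].unique())
    b_levels = sorted(cells[_FACTOR_B].unique())
    if len(cells) != len(a_levels) * len(b_levels):
        raise UnsupportedDesignError("incomplete grid of summary cells")
    if cells.duplicated([_FACTOR_A, _FACTOR_B]).any():
        raise UnsupportedDesignError("duplicate summary cells")
    if cells["n"].nunique() != 1:
        raise UnsupportedDesignError("unbalanced summaries (unequal n)")
    if (cells["sd"] < 0).any():
        raise InvalidInputError("cell SDs must be >= 0")
    n = int(cells["n"].iloc[0])
    if n < 2:
        raise UnsupportedDesignError("need n >= 2 per cell")
    a, b = len(a_levels), len(b_levels)

    m = (
        cells.set_index([_FACTOR_A, _FACTOR_B])["mean"]
        .unstack()
        .loc[a_levels, b_levels]
        .to_numpy(dtype=float)
    )
    s = (
        cells.set_index([_FACTOR_A, _FACTOR_B])["sd"]
        .unstack()
        .loc[a_levels, b_levels]
        .to_numpy(dtype=float)
    )
    grand = m.mean()
    row = m.mean(axis=1)
    col = m.mean(axis=0)
    ss_a = b * n * np.sum((row - grand) ** 2)
    ss_b = a * n * np.sum((col - grand) ** 2)
    ss_ab = n * np.sum((m - row[:, None] - col[None, :] + grand) ** 2)
    ss_res = (n - 1) * np.sum(s**2)
    return _assemble(ss_a, ss_b, ss_ab, ss_res, a, b, n)


# ---------------------------------------------------------------------------
# post hoc

def _compact_letters(levels: Sequence, means: dict, distinct_pairs: set) -> dict:
    # Piepho insert-and-absorb: start from one all-inclusive set, split on
    # each significant pair, drop subsets, letter sets by their best mean.
    sets: list[set] = [set(levels)]
    for i, j in sorted(distinct_pairs):
        new_sets = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb: remove sets contained in another
        sets = [
            s
            for k, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and k > l) for l, t in enumerate(new_sets))
        ]
    sets.sort(key=lambda s: -max(means[lv] for lv in s))
    letters = {lv: "" for lv in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, s in enumerate(sets):
        for lv in s:
            letters[lv] += alphabet[idx]
    return {lv: "".join(sorted(letters[lv])) for lv in levels}


def bonferroni_posthoc(
    table: pd.DataFrame, effect: str = "A", alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise comparisons within one factor at the Bonferroni level.

    Pairwise t statistics use the pooled residual mean square of the
    two-way ANOVA; each of the m pairs is tested at ``alpha / m``.
    Returns a frame with one row per level: mean, n and the compact
    letter display (levels sharing a letter are not significantly
    different), plus the pairwise decisions in ``.attrs["pairs"]``.
    """
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    if effect not in ("A", "B"):
        raise InvalidInputError("effect must be 'A' or 'B'")
    table = _check_table(table)
    anova = two_way_anova(table)
    factor = _FACTOR_A if effect == "A" else _FACTOR_B
    g = table.groupby(factor, sort=True)[_VALUE]
    means = g.mean().to_dict()
    counts = g.size().to_dict()
    levels = sorted(means)
    if len(levels) < 2:
        raise InvalidInputError("post hoc needs >= 2 levels")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    ms_res, df_res = anova.ms_residual, anova.df_residual

    rows = []
    distinct = set()
    for i, j in pairs:
        se = np.sqrt(ms_res * (1.0 / counts[i] + 1.0 / counts[j]))
        if se == 0:
            t = np.inf if means[i] != means[j] else 0.0
        else:
            t = (means[i] - means[j]) / se
        p = 2.0 * sps.t.sf(abs(t), df_res)
        p_adj = min(1.0, p * m)
        sig = p < alpha / m
        if sig:
            distinct.add((i, j))
        rows.append({"level_1": i, "level_2": j, "t": t, "p": p, "p_bonferroni": p_adj,
                     "significant": sig})
    letters = _compact_letters(levels, means, distinct)
    out = pd.DataFrame(
        {
            "level": levels,
            "mean": [means[lv] for lv in levels],
            "n": [counts[lv] for lv in levels],
            "letters": [letters[lv] for lv in levels],
        }
    )
    out.attrs["pairs"] = pd.DataFrame(rows)
    out.attrs["per_comparison_alpha"] = alpha / m
    return out


# ---------------------------------------------------------------------------
# correlation and gate checks

def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise InvalidInputError("need at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(p)


def normality_check(values) -> tuple[float, float]:
    """D'Agostino-Pearson K^2 omnibus normality test.

    K^2 is the sum of squared normalizing transforms of sample skewness
    (D'Agostino) and kurtosis (Anscombe-Glynn), chi-squared with 2 df
    under normality.  Requires n >= 8 (the kurtosis transform is invalid
    below that).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise InsufficientSampleError(f"normality omnibus requires n >= 8, got {n}")
    if np.ptp(x) == 0:
        raise InsufficientSampleError("constant sample: normality test degenerate")

    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    m3 = np.mean((x - mu) ** 3)
    m4 = np.mean((x - mu) ** 4)
    b1 = m3 / m2**1.5  # skewness g1
    b2 = m4 / m2**2    # kurtosis g2 + 3

    # D'Agostino (1970) skewness z
    y = b1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    y = np.where(y == 0, 1e-30, y)
    z_skew = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # Anscombe-Glynn (1983) kurtosis z
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = 24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    x_std = (b2 - e_b2) / np.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7.0) * (n + 9.0))
        * np.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a_const = 6.0 + 8.0 / sqrt_beta1 * (
        2.0 / sqrt_beta1 + np.sqrt(1.0 + 4.0 / sqrt_beta1**2)
    )
    term = (1.0 - 2.0 / a_const) / (1.0 + x_std * np.sqrt(2.0 / (a_const - 4.0)))
    z_kurt = (1.0 - 2.0 / (9.0 * a_const) - np.sign(term) * np.abs(term) ** (1.0 / 3.0)) / np.sqrt(
        2.0 / (9.0 * a_const)
    )

    k2 = float(z_skew**2 + z_kurt**2)
    p = float(sps.chi2.sf(k2, 2))
    return k2, p


def variance_homogeneity_check(
    table: pd.DataFrame, center: str = "mean"
) -> tuple[float, float]:
    """Levene test for homogeneity of variance across factorial cells.

    ``table`` is a long-format factorial table (``factorA``, ``factorB``,
    ``value``); groups are the cells.  ``center='mean'`` gives the
    classical Levene statistic on absolute deviations from group means;
    ``center='median'`` the Brown-Forsythe variant.
    """
    table = _check_table(table)
    if center not in ("mean", "median"):
        raise InvalidInputError("center must be 'mean' or 'median'")
    groups = [
        np.asarray(v[_VALUE], dtype=float)
        for _, v in table.groupby([_FACTOR_A, _FACTOR_B], sort=True)
    ]
    return _levene(groups, center)


def _levene(groups: list[np.ndarray], center: str = "mean") -> tuple[float, float]:
    k = len(groups)
    if k < 2:
        raise InvalidInputError("Levene test needs >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise InsufficientSampleError("every group needs >= 2 observations")
    loc = np.mean if center == "mean" else np.median
    z = [np.abs(g - loc(g)) for g in groups]
    n_i = np.array([g.size for g in groups], dtype=float)
    n_tot = n_i.sum()
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = np.concatenate(z).mean()
    num = (n_tot - k) * np.sum(n_i * (zbar_i - zbar) ** 2)
    den = (k - 1) * np.sum([np.sum((zi - zb) ** 2) for zi, zb in zip(z, zbar_i)])
    if den == 0:
        raise UndefinedStatisticError("zero within-group spread: Levene undefined")
    w = float(num / den)
    p = float(sps.f.sf(w, k - 1, n_tot - k))
    return w, p
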