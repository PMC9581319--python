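"""Inference layer: ANOVA paths, post hoc letters, gates, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xylograft import synthetic_data as sd
from xylograft.errors import (
    InsufficientSampleError,
    InvalidInputError,
    UndefinedStatisticError,
    UnsupportedDesignError,
)
from xylograft.stats import (
    anova_from_summaries,
    arcsine_sqrt_transform,
    bonferroni_posthoc,
    normality_check,
    pearson_correlation,
    summaries_from_table,
    two_way_anova,
    variance_homogeneity_check,
)


def _random_table(rng, a=3, b=3, n=5, effect_a=0.0):
    rows = []
    for i in range(a):
        for j in range(b):
            for _ in range(n):
                rows.append(
                    {
                        "factorA": f"A{i}",
                        "factorB": f"B{j}",
                        "value": rng.normal(10 + effect_a * i, 2.0),
                    }
                )
    return pd.DataFrame(rows)


def _brute_force_ss(table):
    """Independent oracle: explicit loop summation of the balanced-design
    decomposition from cell, row, column and grand means."""
    cells = {}
    for _, r in table.iterrows():
        cells.setdefault((r.factorA, r.factorB), []).append(r.value)
    a_levels = sorted({k[0] for k in cells})
    b_levels = sorted({k[1] for k in cells})
    n = len(next(iter(cells.values())))
    grand = sum(v for vals in cells.values() for v in vals) / (
        len(cells) * n
    )
    cell_mean = {k: sum(v) / n for k, v in cells.items()}
    row_mean = {
        i: sum(cell_mean[(i, j)] for j in b_levels) / len(b_levels) for i in a_levels
    }
    col_mean = {
        j: sum(cell_mean[(i, j)] for i in a_levels) / len(a_levels) for j in b_levels
    }
    ss_a = len(b_levels) * n * sum((row_mean[i] - grand) ** 2 for i in a_levels)
    ss_b = len(a_levels) * n * sum((col_mean[j] - grand) ** 2 for j in b_levels)
    ss_ab = n * sum(
        (cell_mean[(i, j)] - row_mean[i] - col_mean[j] + grand) ** 2
        for i in a_levels
        for j in b_levels
    )
    ss_res = sum(
        (v - cell_mean[k]) ** 2 for k, vals in cells.items() for v in vals
    )
    return ss_a, ss_b, ss_ab, ss_res


class TestArcsine:
    @pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, math.pi / 2), (0.5, math.pi / 4)])
    def test_known_points(self, p, expected):
        assert arcsine_sqrt_transform(p) == pytest.approx(expected)

    def test_domain_enforced(self):
        with pytest.raises(InvalidInputError):
            arcsine_sqrt_transform(1.2)


class TestTwoWayAnova:
    def test_matches_brute_force_oracle(self, rng):
        table = _random_table(rng)
        at = two_way_anova(table)
        ss = _brute_force_ss(table)
        for got, want in zip(at.table["ss"][:4], ss):
            assert got == pytest.approx(want, rel=1e-9)

    def test_matches_statsmodels(self, rng):
        """Closed-form SS and F agree with the regression-based ANOVA of
        an independent library on a balanced table."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = _random_table(rng, effect_a=1.0)
        at = two_way_anova(table)
        fit = smf.ols("value ~ C(factorA) * C(factorB)", data=table).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert at.table["ss"].to_numpy() == pytest.approx(
            ref["sum_sq"].to_numpy(), rel=1e-9
        )
        assert at.table["F"][:3].to_numpy() == pytest.approx(
            ref["F"][:3].to_numpy(), rel=1e-9
        )

    def test_decomposition_sums_to_total(self, rng):
        table = _random_table(rng)
        at = two_way_anova(table)
        total = float(np.sum((table.value - table.value.mean()) ** 2))
        assert at.table["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_degrees_of_freedom(self, rng):
        at = two_way_anova(_random_table(rng, a=3, b=4, n=6))
        assert list(at.table["df"]) == [2, 3, 6, 3 * 4 * 5]

    def test_null_design_small_f(self, rng):
        """All cell means equal: effect SS reflect only sampling noise, so
        p-values are non-extreme."""
        at = two_way_anova(_random_table(rng, effect_a=0.0))
        assert at.table.loc["A", "p"] > 1e-4

    def test_unbalanced_rejected(self, rng):
        table = _random_table(rng).iloc[:-1]
        with pytest.raises(UnsupportedDesignError):
            two_way_anova(table)

    def test_missing_cell_rejected(self, rng):
        table = _random_table(rng)
        table = table[~((table.factorA == "A0") & (table.factorB == "B0"))]
        with pytest.raises(UnsupportedDesignError):
            two_way_anova(table)


class TestAnovaFromSummaries:
    def test_exact_summaries_reproduce_raw_anova(self, rng):
        for _ in range(5):
            table = _random_table(rng, effect_a=rng.uniform(0, 2))
            at_raw = two_way_anova(table)
            at_sum = anova_from_summaries(summaries_from_table(table))
            assert np.allclose(
                at_raw.table[["ss", "ms"]], at_sum.table[["ss", "ms"]], rtol=1e-9
            )
            assert np.allclose(
                at_raw.table["F"][:3], at_sum.table["F"][:3], rtol=1e-9
            )

    def test_zero_sd_unequal_means_overflows(self):
        cells = pd.DataFrame(
            {
                "factorA": ["a", "a", "b", "b"],
                "factorB": ["x", "y", "x", "y"],
                "mean": [1.0, 2.0, 3.0, 4.0],
                "sd": [0.0] * 4,
                "n": [5] * 4,
            }
        )
        at = anova_from_summaries(cells)
        assert at.overflow
        assert np.isinf(at["A"]["F"])

    def test_incomplete_grid_rejected(self):
        cells = pd.DataFrame(
            {
                "factorA": ["a", "a", "b"],
                "factorB": ["x", "y", "x"],
                "mean": [1.0, 2.0, 3.0],
                "sd": [1.0] * 3,
                "n": [5] * 3,
            }
        )
        with pytest.raises(UnsupportedDesignError):
            anova_from_summaries(cells)


class TestBonferroni:
    def test_per_comparison_threshold(self, rng):
        out = bonferroni_posthoc(_random_table(rng), "A", alpha=0.05)
        assert out.attrs["per_comparison_alpha"] == pytest.approx(0.05 / 3)

    def test_identical_means_share_letter(self, rng):
        out = bonferroni_posthoc(_random_table(rng, effect_a=0.0), "A")
        assert set(out["letters"]) == {"a"}

    def test_large_shift_gets_distinct_letter(self, rng):
        """One level shifted by 5 within-cell SDs separates cleanly."""
        table = _random_table(rng, effect_a=0.0)
        table.loc[table.factorA == "A2", "value"] += 10.0  # 5 x SD(2)
        out = bonferroni_posthoc(table, "A")
        letters = dict(zip(out["level"], out["letters"]))
        assert letters["A2"] not in (letters["A0"], letters["A1"])
        assert letters["A0"] == letters["A1"]

    def test_needs_two_levels(self, rng):
        table = _random_table(rng)
        with pytest.raises(InvalidInputError):
            bonferroni_posthoc(table[table.factorA == "A0"], "A")


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula_and_scipy(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        r, p = pearson_correlation(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGateChecks:
    def test_k2_matches_scipy_omnibus(self, rng):
        for data in (rng.normal(size=200), rng.gamma(2.0, size=150)):
            k2, p = normality_check(data)
            ref = sps.normaltest(data)
            assert k2 == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normality_calibration_on_normal_samples(self):
        """Large standard-normal samples rarely fail the omnibus test."""
        ok = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(10_000)
            ok += normality_check(x)[1] > 0.01
        assert ok >= 95

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(InsufficientSampleError):
            normality_check(np.arange(5.0))
        with pytest.raises(InsufficientSampleError):
            normality_check(np.ones(20))

    def test_levene_matches_scipy(self, rng):
        table = _random_table(rng, a=2, b=1, n=30)
        w, p = variance_homogeneity_check(table)
        groups = [g["value"].to_numpy() for _, g in table.groupby(["factorA", "factorB"])]
        ref = sps.levene(*groups, center="mean")
        assert w == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_levene_type1_near_alpha(self):
        """Equal-variance groups: rejection rate about 5% over 500 sims."""
        rej = 0
        n_sim = 500
        for seed in range(n_sim):
            g = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "factorA": np.repeat(["a", "b"], 50),
                    "factorB": "x",
                    "value": g.standard_normal(100),
                }
            )
            rej += variance_homogeneity_check(table)[1] < 0.05
        assert abs(rej / n_sim - 0.05) < 0.025
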