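"""Block classification, contingency χ², test selection, slab correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from poreflux.stats import (
    build_block_table,
    build_report,
    classify_blocks,
    compare_groups,
    contingency_chi2,
    slice_dipole_correlation,
    write_report,
)


@pytest.fixture
def block_table():
    return build_block_table(
        [
            {"condition": "control", "channel_id": "A",
             "water_count_30A": [7, 5, 4, 12, 0]},
            {"condition": "DEX", "channel_id": "B",
             "water_count_30A": [0, 1, 5, 2, 3]},
        ]
    )


class TestClassify:
    def test_threshold_inclusive(self, block_table):
        calls = classify_blocks(block_table, threshold=5)
        by_count = dict(zip(calls["water_count_30A"], calls["functional"]))
        assert by_count[5]  # "5 or more" → functional
        assert not by_count[4]
        assert not by_count[0]

    def test_all_zero_non_functional(self):
        table = build_block_table(
            [{"condition": "c", "channel_id": "A", "water_count_30A": [0, 0, 0]}]
        )
        assert not classify_blocks(table)["functional"].any()

    @given(st.integers(0, 20))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_threshold(self, thr):
        table = build_block_table(
            [{"condition": "c", "channel_id": "A",
              "water_count_30A": list(range(0, 21))}]
        )
        lo = classify_blocks(table, threshold=thr)["functional"].sum()
        hi = classify_blocks(table, threshold=thr + 1)["functional"].sum()
        assert hi <= lo

    def test_missing_column_rejected(self, block_table):
        with pytest.raises(ValueError, match="not in table"):
            classify_blocks(block_table, count_column="nope")


def brute_force_chi2(tab):
    tab = np.asarray(tab, dtype=float)
    n = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    return float(np.sum((tab - expected) ** 2 / expected))


class TestContingency:
    def test_perfect_association(self):
        res = contingency_chi2(np.array([[10, 0], [0, 10]]))
        assert res.chi2 == pytest.approx(20.0)
        assert res.p_value < 1e-4

    def test_independence(self):
        res = contingency_chi2(np.array([[5, 5], [5, 5]]))
        assert res.chi2 == 0.0
        assert res.p_value == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(1, 15)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_matches_textbook_formula(self, cells):
        tab = np.array(cells).reshape(2, 2)
        res = contingency_chi2(tab)
        assert res.chi2 == pytest.approx(brute_force_chi2(tab), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chi2(np.array([[0, 0], [5, 5]]))

    def test_dataframe_input(self):
        calls = pd.DataFrame(
            {"functional": [True] * 10 + [False] * 10,
             "hbond_to_arginine": [False] * 10 + [True] * 10}
        )
        res = contingency_chi2(calls)
        assert res.chi2 == pytest.approx(20.0)


class TestCompareGroups:
    def test_gaussian_homoscedastic_uses_t(self):
        rng = np.random.default_rng(0)
        data = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 1, 25)])
        res = compare_groups(data, ["a"] * 25 + ["b"] * 25)
        assert res.test_name == "Student's t-test"
        assert res.parametric

    def test_heavy_tails_use_mann_whitney(self):
        rng = np.random.default_rng(1)
        data = np.concatenate(
            [rng.standard_cauchy(30), rng.standard_cauchy(30) + 1]
        )
        res = compare_groups(data, ["a"] * 30 + ["b"] * 30)
        assert res.test_name == "Mann-Whitney U"
        assert not res.parametric

    def test_three_groups_anova_tukey(self):
        rng = np.random.default_rng(2)
        data = np.concatenate([rng.normal(m, 1, 20) for m in (0, 0, 2)])
        res = compare_groups(data, ["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        assert res.test_name == "one-way ANOVA + Tukey HSD"
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_three_groups_rank_bonferroni(self):
        rng = np.random.default_rng(3)
        data = np.concatenate(
            [np.exp(rng.normal(0, 1.5, 20)) for _ in range(2)]
            + [np.exp(rng.normal(2, 1.5, 20))]
        )
        res = compare_groups(data, ["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        assert res.test_name == "pairwise Wilcoxon rank-sum + Bonferroni"
        assert np.all(res.posthoc["p_bonferroni"] >= res.posthoc["p_raw"] - 1e-12)

    def test_identical_groups_p_one(self):
        res = compare_groups(np.ones(10), ["a"] * 5 + ["b"] * 5)
        assert res.p_value == 1.0

    def test_constant_group_forces_nonparametric(self):
        rng = np.random.default_rng(4)
        data = np.concatenate([np.full(10, 3.0), rng.normal(0, 1, 10)])
        res = compare_groups(data, ["a"] * 10 + ["b"] * 10)
        assert not res.parametric

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups(np.arange(4.0), ["a", "a", "b", "b"])

    def test_power_against_clear_shift(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            data = np.concatenate([rng.normal(0, 1, 25), rng.normal(2, 1, 25)])
            if compare_groups(data, ["a"] * 25 + ["b"] * 25).p_value < 0.01:
                hits += 1
        assert hits >= 95


class TestSlabCorrelation:
    def test_identical_series_rho_one(self):
        rng = np.random.default_rng(6)
        angles = rng.random(500) * 180
        z = rng.random(500) * 50
        out = slice_dipole_correlation(angles, angles, z, slab_width=10.0)
        ok = out[out.status == "ok"]
        assert len(ok) == 5
        assert np.allclose(ok["rho"], 1.0)

    def test_single_covering_slab_equals_global(self):
        rng = np.random.default_rng(7)
        a = rng.random(300) * 180
        b = 0.5 * a + rng.random(300) * 90
        z = rng.random(300) * 9.9
        out = slice_dipole_correlation(a, b, z, slab_width=10.0, z_range=(0, 10))
        assert out.iloc[0]["rho"] == pytest.approx(spearmanr(a, b).statistic)

    def test_insufficient_data_flagged(self):
        a = np.arange(10.0)
        z = np.array([5.0] * 8 + [15.0] * 2)  # second slab has 2 < 5 frames
        out = slice_dipole_correlation(a, a, z, slab_width=10.0, z_range=(0, 20))
        assert list(out.status) == ["ok", "insufficient data"]
        assert np.isnan(out.iloc[1]["rho"])

    def test_null_series_small_rho(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(10_000) * 180, rng.random(10_000) * 180
        z = np.full(10_000, 5.0)
        out = slice_dipole_correlation(a, b, z, slab_width=10.0, z_range=(0, 10))
        assert abs(out.iloc[0]["rho"]) < 0.05


class TestReport:
    def test_empty_report_has_provenance(self):
        rep = build_report({}, provenance={"seed": 1})
        assert rep["provenance"]["seed"] == 1
        assert rep["tables"] == {}

    def test_deterministic_bytes(self, tmp_path):
        df = pd.DataFrame({"x": [1, 2], "y": [0.5, 0.25]})
        for d in ("r1", "r2"):
            write_report(build_report({"t": df}, {"seed": 3}), tmp_path / d)
        a = (tmp_path / "r1" / "report.json").read_bytes()
        b = (tmp_path / "r2" / "report.json").read_bytes()
        assert a == b

    def test_tables_schema(self, tmp_path):
        df = pd.DataFrame({"x": [1]})
        rep = build_report({"alpha": df, "beta": {"k": 1}})
        write_report(rep, tmp_path / "out")
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "alpha.csv").exists()
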