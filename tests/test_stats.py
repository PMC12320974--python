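"""Statistical layer: exact Wilcoxon, Kruskal-Wallis, summaries, study runner."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon

from flyheart.exceptions import DegenerateDataError
from flyheart.stats import (
    GroupSummary,
    kruskal_wallis,
    run_study_comparisons,
    significance_stars,
    summarize_groups,
    wilcoxon_signed_rank,
)


def enumeration_oracle_p(x, y):
    """Independent brute-force Wilcoxon oracle.

    Drops zeros, midranks |d|, then walks every sign assignment with
    itertools and counts outcomes at least as extreme (two-sided, symmetric
    null around sum(ranks)/2).
    """
    d = np.asarray(y, float) - np.asarray(x, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    extreme = 0
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            extreme += 1
    return extreme / 2 ** len(ranks)


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        """Five positive differences with distinct ranks: p = 2/2^5 = 0.0625."""
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [3, 5, 7, 9, 11])
        assert res.p == pytest.approx(0.0625, abs=1e-12)
        assert res.statistic == 15.0
        assert "exact" in res.method

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=9)
            y = x + rng.normal(0.3, 1.0, size=9)
            ours = wilcoxon_signed_rank(x, y)
            ref = scipy_wilcoxon(y, x, mode="exact", zero_method="wilcox")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(4, 10),
        seed=st.integers(0, 10_000),
    )
    def test_exact_p_equals_enumeration_with_ties(self, n, seed):
        """Property: exact p equals the brute-force oracle on tie-rich integer data."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=n).astype(float)
        y = rng.integers(0, 4, size=n).astype(float)
        if np.all(y - x == 0):
            return
        d = (y - x)[(y - x) != 0]
        if d.size < 2:
            return
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(enumeration_oracle_p(x, y), abs=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = x + rng.normal(0.5, 1.0, size=8)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        assert a.p == pytest.approx(b.p, abs=1e-12)
        total = a.n * (a.n + 1) / 2
        assert a.statistic + b.statistic == pytest.approx(total)

    def test_all_zero_differences_fail(self):
        with pytest.raises(DegenerateDataError, match="no nonzero"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_approximation_close_to_enumeration_at_cutoff(self):
        """Continuity+tie-corrected normal path tracks the exact p above cutoff."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=14)
        y = x + rng.normal(0.4, 1.0, size=14)
        exact = wilcoxon_signed_rank(x, y, exact_cutoff=16)
        approx = wilcoxon_signed_rank(x, y, exact_cutoff=5)
        assert "approximation" in approx.method
        assert approx.p == pytest.approx(exact.p, abs=0.01)

    def test_pratt_zero_handling_runs(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 4, 6, 8, 10], zero_method="pratt")
        assert 0 < res.p <= 1


class TestKruskalWallis:
    def test_three_pair_example(self):
        """Hand computation of the rank formula: H = 32/7."""
        res = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert res.statistic == pytest.approx(32 / 7)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            groups = [
                rng.integers(0, 6, size=rng.integers(3, 8)).astype(float) for _ in range(3)
            ]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            ours = kruskal_wallis(*groups)
            ref = scipy_kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.uniform(0, 1, 6), rng.uniform(0.2, 1.2, 6), rng.uniform(0.4, 1.4, 6)]
        a = kruskal_wallis(*groups)
        b = kruskal_wallis(*[np.exp(5 * g) for g in groups])
        assert b.statistic == pytest.approx(a.statistic, abs=1e-10)

    def test_all_identical_values_fail(self):
        with pytest.raises(DegenerateDataError, match="no variation"):
            kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])


class TestSummaries:
    def test_mean_and_sem(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"], "v": [1.0, 2.0, 3.0, 5.0]})
        out = {s.label: s for s in summarize_groups(df, "v", "g")}
        assert out["a"].mean == pytest.approx(2.0)
        assert out["a"].sem == pytest.approx(1.0 / np.sqrt(3))
        assert out["b"].n == 1 and not out["b"].sem_defined

    def test_constant_group_sem_zero(self):
        df = pd.DataFrame({"g": ["a"] * 4, "v": [2.0] * 4})
        (s,) = summarize_groups(df, "v", "g")
        assert s.sem == pytest.approx(0.0)

    def test_stars_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"

    def test_stars_monotone_in_p(self):
        ps = np.linspace(1e-6, 0.9, 200)
        order = {"****": 4, "***": 3, "**": 2, "*": 1, "ns": 0}
        stars = [order[significance_stars(p)] for p in ps]
        assert all(a >= b for a, b in zip(stars, stars[1:]))


class TestStudyRunner:
    @staticmethod
    def _cohort(seed=0, n=12):
        from flyheart.synth import five_strain_design, generate_cohort

        return generate_cohort(five_strain_design(n_per_group=n, seed=seed)).table

    def test_dysfunction_flags_follow_direction_rule(self):
        tables = run_study_comparisons(self._cohort(seed=5, n=15))
        paired = tables["paired"].set_index(["strain", "endpoint"])
        # HR falls significantly in all strains -> flagged
        assert paired.loc[("WT", "HR"), "dysfunction"]
        assert paired.loc[("N210K", "AI"), "dysfunction"]
        # sign convention: dysfunction requires the deleterious direction
        sig_hr = paired.xs("HR", level="endpoint")
        assert all(sig_hr.loc[sig_hr.dysfunction, "mean_delta"] < 0)

    def test_between_strain_kruskal_present(self):
        tables = run_study_comparisons(self._cohort(seed=6))
        between = tables["between"]
        assert set(between["condition"]) == {"BTP", "ATP"}
        assert {"HR", "AI", "FS"} <= set(between["endpoint"])

    def test_single_strain_skips_kruskal_keeps_wilcoxon(self):
        from flyheart.synth import generate_cohort, null_design

        table = generate_cohort(null_design(n_per_group=10, seed=1)).table
        tables = run_study_comparisons(table)
        assert not tables["paired"].empty
        assert tables["between"].empty

    def test_missing_pair_member_excluded(self, caplog):
        table = self._cohort(seed=7, n=5)
        table = table[
            ~((table.animal_id == "WT_none_a00") & (table.condition == "ATP"))
        ]
        with caplog.at_level("WARNING"):
            tables = run_study_comparisons(table)
        wt = tables["paired"].query("strain == 'WT' and endpoint == 'HR'")
        assert int(wt["n_pairs"].iloc[0]) == 4

    def test_holm_adjustment_is_monotone(self):
        tables = run_study_comparisons(self._cohort(seed=8), holm=True)
        pw = tables["pairwise"]
        assert (pw["p_adj"] >= pw["p"] - 1e-12).all()
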