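"""Poisson-Tweedie testing, BH correction, enrichment, t-tests, clustering."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import comb

from coabnet import (
    bh_adjust,
    fisher_enrichment,
    fit_pt_moments,
    hierarchical_cluster,
    hub_ttest,
    pt_two_sample_test,
    run_pairwise_da,
    sample_pt_counts,
)

from conftest import make_taxon_matrix, unit_factors


class TestPtFit:
    def test_constant_counts_collapse_to_poisson(self):
        fit = fit_pt_moments([5, 5, 5, 5])
        assert fit.mu == pytest.approx(5.0)
        assert fit.phi == 1.0
        assert fit.a == 1.0

    def test_nb_simulation_recovers_parameters_and_shape(self):
        x = sample_pt_counts(10.0, 4.0, 0.0, 10_000, seed=21)
        fit = fit_pt_moments(x)
        assert fit.mu == pytest.approx(10.0, rel=0.02)
        assert fit.phi == pytest.approx(4.0, rel=0.10)
        assert fit.a == 0.0

    def test_pig_simulation_recovers_shape(self):
        x = sample_pt_counts(10.0, 6.0, 0.5, 10_000, seed=22)
        fit = fit_pt_moments(x)
        assert fit.a == 0.5

    def test_rescaling_cancels_in_dispersion(self):
        x = sample_pt_counts(20.0, 3.0, 0.0, 50_000, seed=23)
        f1 = fit_pt_moments(x)
        f2 = fit_pt_moments(x * 5.0, norm_factors=np.full(x.size, 5.0))
        assert f2.mu == pytest.approx(f1.mu)
        assert f2.phi == pytest.approx(f1.phi)
        assert f2.a == f1.a

    def test_all_zero_vector_flagged(self):
        fit = fit_pt_moments([0, 0, 0, 0])
        assert fit.all_zero and fit.a is None


class TestPtTwoSampleTest:
    def test_identical_groups_give_null_result(self):
        z, p = pt_two_sample_test([4, 7, 5, 9], [4, 7, 5, 9])
        assert z == 0.0 and p == 1.0

    def test_swapping_groups_negates_z(self):
        a, b = [3, 8, 6, 5], [12, 15, 20, 11]
        z1, p1 = pt_two_sample_test(a, b)
        z2, p2 = pt_two_sample_test(b, a)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_all_zero_both_groups(self):
        z, p = pt_two_sample_test([0, 0, 0, 0], [0, 0, 0, 0])
        assert (z, p) == (0.0, 1.0)

    def test_one_zero_group_still_tested(self):
        z, p = pt_two_sample_test([0, 0, 0, 0], [9, 12, 10, 8])
        assert math.isfinite(z) and 0 < p < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pt_two_sample_test([5], [4, 6])

    def test_null_calibration_small(self):
        """Type-I error of the Gaussian approximation at n=4 (reduced run)."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            a = sample_pt_counts(20.0, 3.0, 0.0, 4, seed=rng)
            b = sample_pt_counts(20.0, 3.0, 0.0, 4, seed=rng)
            _, p = pt_two_sample_test(a, b)
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.09


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_permutation_invariance(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        perm = np.random.default_rng(0).permutation(p.size)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        # independent step-up evaluation: q_(i) = min_{j>=i} m p_(j)/j
        order = np.argsort(p)
        m = p.size
        q_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(q_sorted, None, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected)


class TestRunPairwiseDa:
    def test_six_comparisons_for_four_groups(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, size=(8, 16))
        tcm = make_taxon_matrix(counts, ["CKD", "CKDRS", "HRS", "H"], 4)
        table, comp = run_pairwise_da(tcm, unit_factors(tcm))
        assert len(comp.comparisons) == 6
        assert set(table["comparison"]) == set(comp.comparisons)
        assert len(table) == 6 * 8

    def test_q_dominates_p_within_comparisons(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(15, size=(10, 16))
        tcm = make_taxon_matrix(counts, ["CKD", "CKDRS", "HRS", "H"], 4)
        table, _ = run_pairwise_da(tcm, unit_factors(tcm))
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert ((table["q"] < 0.05) == table["significant"]).all()

    def test_missing_group_rejected(self):
        counts = np.random.default_rng(0).poisson(20, size=(5, 5))
        tcm = make_taxon_matrix(counts, ["A", "B", "C", "D", "E"], 1)
        with pytest.raises(ValueError, match="< 2 samples"):
            run_pairwise_da(tcm, unit_factors(tcm))

    def test_planted_effect_recovered_in_its_comparison(self):
        rng = np.random.default_rng(9)
        n_taxa, fc = 50, 4.0
        counts = np.empty((n_taxa, 16), dtype=int)
        for i in range(n_taxa):
            mu = np.full(16, 50.0)
            if i < 10:
                mu[:4] *= fc  # effect in the first group
            counts[i] = sample_pt_counts(mu, 2.0, 0.0, 16, seed=rng)
        tcm = make_taxon_matrix(counts, ["CKD", "CKDRS", "HRS", "H"], 4)
        table, comp = run_pairwise_da(tcm, unit_factors(tcm))
        sub = table[(table["comparison"] == "CKD_vs_H") & table["significant"]]
        planted = {f"T{i:03d}" for i in range(10)}
        assert len(planted & set(sub["taxon"])) >= 6
        assert planted <= comp.union_da


class TestFisherEnrichment:
    def test_hypergeometric_tail_oracle(self):
        background = [f"b{i}" for i in range(100)]
        da = background[:10]
        term = background[:5] + background[50:55]  # 5 of 10 DA, 10 of 100 bg
        table = fisher_enrichment(da, background, {"T": term})
        expected = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert table.loc[0, "p"] == pytest.approx(expected, rel=1e-10)
        assert table.loc[0, "enriched"]

    def test_term_covering_background_is_null(self):
        background = [f"b{i}" for i in range(30)]
        table = fisher_enrichment(background[:5], background, {"all": background})
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_da_set_finds_nothing(self):
        background = [f"b{i}" for i in range(20)]
        table = fisher_enrichment([], background, {"T": background[:5]})
        assert not table["enriched"].any()

    def test_da_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["x"], ["a", "b"], {})

    def test_empty_term_skipped_with_warning(self):
        background = ["a", "b", "c"]
        with pytest.warns(UserWarning, match="no background"):
            table = fisher_enrichment(["a"], background, {"ghost": ["z"]})
        assert len(table) == 0


class TestHubTtest:
    def test_identical_groups_give_p_one(self):
        counts = np.tile([5, 6, 7, 8], (1, 4))
        tcm = make_taxon_matrix(counts, ["CKD", "CKDRS", "HRS", "H"], 4)
        table = hub_ttest(tcm, ["T000"])
        assert np.allclose(table["p"], 1.0)

    def test_welch_closed_form_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([5.0, 6.0, 7.0, 8.0])
        counts = np.concatenate([a, b, b, b]).reshape(1, 16)
        tcm = make_taxon_matrix(counts.astype(float), ["CKD", "CKDRS", "HRS", "H"], 4)
        row = hub_ttest(tcm, ["T000"]).iloc[0]  # CKD vs CKDRS
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        t_exp = (a.mean() - b.mean()) / se
        df = se**4 / (
            (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 4) ** 2 / 3
        )
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        assert row["t"] == pytest.approx(t_exp)
        assert row["p"] == pytest.approx(p_exp)

    def test_label_exchange_preserves_p(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(20, size=(1, 16))
        tcm1 = make_taxon_matrix(counts, ["CKD", "CKDRS", "HRS", "H"], 4)
        swapped = np.concatenate([counts[:, 4:8], counts[:, :4], counts[:, 8:]], axis=1)
        tcm2 = make_taxon_matrix(swapped, ["CKD", "CKDRS", "HRS", "H"], 4)
        p1 = hub_ttest(tcm1, ["T000"]).set_index("comparison")["p"]
        p2 = hub_ttest(tcm2, ["T000"]).set_index("comparison")["p"]
        assert p1["CKD_vs_CKDRS"] == pytest.approx(p2["CKD_vs_CKDRS"])

    def test_unknown_hub_rejected(self):
        counts = np.ones((1, 16), dtype=int)
        tcm = make_taxon_matrix(counts, ["CKD", "CKDRS", "HRS", "H"], 4)
        with pytest.raises(KeyError):
            hub_ttest(tcm, ["nope"])


class TestHierarchicalCluster:
    def _two_group_matrix(self, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        left = rng.normal(0.0, 1.0, size=(20, 4))
        right = rng.normal(8.0, 1.0, size=(20, 4))
        data = np.concatenate([left, right], axis=1)
        return pd.DataFrame(
            data, index=[f"f{i}" for i in range(20)],
            columns=[f"L{i}" for i in range(4)] + [f"R{i}" for i in range(4)],
        )

    def test_duplicate_sample_merges_at_height_zero(self):
        m = self._two_group_matrix(0)
        m["L0b"] = m["L0"]
        res = hierarchical_cluster(m, axis="samples", k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_strong_separation_recovers_groups(self, seed):
        m = self._two_group_matrix(seed)
        res = hierarchical_cluster(m, axis="samples", k=2)
        left = {res.labels[c] for c in m.columns if c.startswith("L")}
        right = {res.labels[c] for c in m.columns if c.startswith("R")}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_column_order_invariance(self):
        m = self._two_group_matrix(1)
        perm = m[list(np.random.default_rng(2).permutation(m.columns))]
        r1 = hierarchical_cluster(m, axis="samples", k=2)
        r2 = hierarchical_cluster(perm, axis="samples", k=2)
        pd.testing.assert_series_equal(r1.labels, r2.labels)

    def test_constant_row_dropped_with_warning(self):
        m = self._two_group_matrix(3)
        m.loc["f0"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = hierarchical_cluster(m, axis="samples", k=2)
        assert res.dropped_rows == ["f0"]
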