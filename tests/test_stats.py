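"""Statistical procedures: elementary oracles, FDR, ICC, cohort screens."""

import numpy as np
import pytest
from scipy import stats as sps

import oracles
from conftest import small_cohort_config
from strucnet.stats import (
    DegenerateInputError,
    bh_fdr,
    bonferroni_alpha,
    compare_edges,
    compare_global_metrics,
    compare_nodes,
    correlate_with_cognition,
    icc_absolute_agreement,
    pearson_r,
    two_sample_t,
    zattention,
    _vectorized_pearson,
    _vectorized_pooled_t,
)
from strucnet.synthetic import Cohort, generate_cohort


class TestZAttention:
    def test_reference_cohort_composite(self):
        # mean of a reference cohort's test z-scores, -0.145, prints as -0.14
        assert zattention(-0.43, 0.14) == pytest.approx(-0.145)
        assert round(zattention(-0.43, 0.14), 2) == -0.14

    @pytest.mark.parametrize("zp,zs,expected", [(0, 0, 0), (1, -1, 0), (2, 1, 1.5)])
    def test_arithmetic_mean(self, zp, zs, expected):
        assert zattention(zp, zs) == pytest.approx(expected)

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            zattention(float("nan"), 0.2)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t1, p1 = two_sample_t(x, y)
        t2, p2 = two_sample_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_pooled_variance_closed_form(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        sp2 = (2 * x.var(ddof=1) + 2 * y.var(ddof=1)) / 4
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * sps.t.sf(abs(t_expected), 4)
        t, p = two_sample_t(x, y)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(p_expected)

    def test_constant_equal_samples(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestBonferroni:
    def test_six_metric_family_prints_0008(self):
        assert bonferroni_alpha(0.05, 6) == pytest.approx(0.05 / 6)
        assert bonferroni_alpha(0.05, 6, decimals=3) == 0.008

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (10, 0.005)])
    def test_division(self, m, expected):
        assert bonferroni_alpha(0.05, m) == pytest.approx(expected)

    def test_zero_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestBhFdr:
    def test_stepup_arithmetic(self):
        adj, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        np.testing.assert_allclose(adj, 0.04)
        assert reject.all()

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.3])
        assert adj[0] == pytest.approx(0.3)

    def test_all_ones_nothing_rejected(self):
        adj, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_definition_and_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=25)
        adj, _ = bh_fdr(p)
        np.testing.assert_allclose(adj, oracles.bh_stepup(p), atol=1e-12)
        perm = rng.permutation(p.size)
        adj_perm, _ = bh_fdr(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=40)
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x = np.array([0.2, 1.4, 0.9, 2.5, 1.8])
        y = np.array([1.0, 0.4, 1.9, 2.2, 0.6])
        r_expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(r_expected)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestIcc:
    def test_identical_sessions_unity(self):
        v = np.array([0.2, 0.5, 0.9, 0.4])
        assert icc_absolute_agreement(v, v).estimate == pytest.approx(1.0)

    def test_constant_shift_penalized(self):
        v = np.array([0.2, 0.5, 0.9, 0.4, 0.7])
        res = icc_absolute_agreement(v, v + 0.1)
        assert res.estimate < 1.0

    def test_session_exchange_invariance(self, rng):
        a = rng.uniform(size=30)
        b = a + rng.normal(0, 0.05, size=30)
        assert icc_absolute_agreement(a, b).estimate == pytest.approx(
            icc_absolute_agreement(b, a).estimate
        )

    def test_toy_layout_matches_anova_mean_squares(self):
        """6-item two-session layout vs a from-scratch two-way ANOVA."""
        s1 = np.array([0.30, 0.52, 0.45, 0.61, 0.28, 0.49])
        s2 = np.array([0.35, 0.50, 0.40, 0.66, 0.30, 0.51])
        data = np.column_stack([s1, s2])
        n, k = data.shape
        gm = data.mean()
        msr = k * ((data.mean(axis=1) - gm) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - gm) ** 2).sum() / (k - 1)
        mse = (
            ((data - gm) ** 2).sum()
            - msr * (n - 1) - msc * (k - 1)
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + mse + (k / n) * (msc - mse))
        res = icc_absolute_agreement(s1, s2)
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.variant == "two-way absolute agreement, single measure"
        assert res.n_items == 6

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(17)
        a = rng.uniform(0.2, 0.8, size=40)
        b = a + rng.normal(0, 0.05, size=40) + 0.02
        long = pd.DataFrame({
            "targets": np.tile(np.arange(40), 2),
            "raters": np.repeat(["s1", "s2"], 40),
            "scores": np.concatenate([a, b]),
        })
        table = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        ref = table.loc[label, "ICC"]
        assert icc_absolute_agreement(a, b).estimate == pytest.approx(
            float(ref), abs=1e-9
        )

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            icc_absolute_agreement([0.5, 0.5], [0.5, 0.5])


class TestVectorizedScreens:
    def test_pooled_t_matches_scipy_columnwise(self, rng):
        x = rng.normal(size=(9, 12))
        y = rng.normal(size=(7, 12))
        t, p = _vectorized_pooled_t(x, y)
        for j in range(12):
            tj, pj = sps.ttest_ind(x[:, j], y[:, j], equal_var=True)
            assert t[j] == pytest.approx(tj)
            assert p[j] == pytest.approx(pj)

    def test_pearson_matches_scipy_columnwise(self, rng):
        s = rng.normal(size=15)
        v = rng.normal(size=(15, 8))
        r, p = _vectorized_pearson(s, v)
        for j in range(8):
            rj, pj = sps.pearsonr(s, v[:, j])
            assert r[j] == pytest.approx(rj)
            assert p[j] == pytest.approx(pj)

    def test_zero_variance_columns(self):
        x = np.ones((4, 2))
        y = np.ones((5, 2))
        y[:, 1] = 2.0
        t, p = _vectorized_pooled_t(x, y)
        assert t[0] == 0.0 and p[0] == 1.0
        assert np.isinf(t[1]) and p[1] == 0.0


class TestCohortScreens:
    def test_global_table_has_six_rows(self, small_cohort):
        table = compare_global_metrics(small_cohort[0])
        assert len(table) == 6
        assert set(table.element) == {
            "strength", "transitivity", "global_efficiency",
            "assortativity", "path_length", "betweenness",
        }

    def test_strong_global_effect_direction(self):
        """A large widespread FA reduction lowers efficiency and raises path
        length in the patient group, both flagged at the Bonferroni level."""
        cfg = small_cohort_config(
            seed=21, n_edges_decreased=60, delta_decrease=0.15,
            subject_noise_sd=0.02,
        )
        table = compare_global_metrics(generate_cohort(cfg)[0]).set_index("element")
        eff = table.loc["global_efficiency"]
        pl = table.loc["path_length"]
        assert eff.statistic < 0 and eff.significant
        assert pl.statistic > 0 and pl.significant

    def test_global_metrics_null_calibration(self):
        """With zero simulated effects, the Bonferroni-guarded whole-brain
        family rejects in at most its nominal ~5% of replicates (99.9%
        binomial bound over 20 replicates at reduced scale)."""
        any_significant = 0
        reps = 20
        for seed in range(reps):
            cfg = small_cohort_config(
                seed=1000 + seed, n_edges_decreased=0, n_edges_increased=0,
                delta_decrease=0.0, delta_increase=0.0, coupling_strength=0.0,
            )
            table = compare_global_metrics(generate_cohort(cfg)[0])
            any_significant += bool(table.significant.any())
        assert any_significant <= sps.binom.ppf(0.999, reps, 0.05)

    def test_node_table_covers_all_nodes(self, small_cohort):
        table = compare_nodes(small_cohort[0])
        assert len(table) == 20
        assert (table.q >= table.p - 1e-15).all()

    def test_edge_table_covers_all_pairs(self, small_cohort):
        table = compare_edges(small_cohort[0])
        assert len(table) == 20 * 19 // 2

    def test_planted_node_effect_recovered(self):
        """Strength effects planted on designated nodes are recovered by the
        FDR screen with the correct (decreased) sign."""
        cfg = small_cohort_config(
            seed=33, n_edges_decreased=0, n_edges_increased=0,
            delta_decrease=0.0, delta_increase=0.0, n_hv=15, n_ms=18,
        )
        cohort, _ = generate_cohort(cfg)
        target_nodes = [1, 5, 9, 13, 17]
        for s in cohort.group("MS"):
            w = s.matrix.weights
            for v in target_nodes:
                mask = w[v] > 0
                w[v, mask] = np.clip(w[v, mask] - 0.12, 0.0, 1.0)
                w[mask, v] = w[v, mask]
        table = compare_nodes(cohort)
        hits = table[(table.direction < 0) & table.significant].element
        assert set(target_nodes) <= set(hits)

    def test_circuit_edges_dominate_cognition_screen(self):
        """With a tight circuit and little cognitive noise, the significant
        positive correlations concentrate on the circuit edges."""
        cfg = small_cohort_config(
            seed=55, n_ms=60, n_circuit_edges=2, coupling_strength=1.0,
            cognition_noise_sd=0.02,
        )
        cohort, truth = generate_cohort(cfg)
        _, edge_table = correlate_with_cognition(cohort, "zPASAT")
        sig_pos = {
            tuple(e) for e, s, d in zip(
                edge_table.element, edge_table.significant, edge_table.direction
            ) if s and d > 0
        }
        assert truth.circuit_edges <= sig_pos
        # circuit edges dominate: any extras are chance discoveries
        assert len(sig_pos & truth.circuit_edges) > len(sig_pos) / 2

    def test_constant_score_degenerate(self, small_cohort):
        cohort, _ = small_cohort
        for s in cohort.group("MS"):
            s.zattention = 0.5
        with pytest.raises(DegenerateInputError):
            correlate_with_cognition(cohort, "zAttention")

    def test_missing_group_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            compare_nodes(Cohort(cohort.group("MS")))
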