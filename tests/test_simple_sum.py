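import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sscoloc import (
    DegenerateError,
    DomainError,
    LDMatrix,
    Region,
    ScenarioConfig,
    SSWeights,
    Status,
    SummaryStatDataset,
    VariantKey,
    estimate_noncentrality,
    pvalues_to_chisq,
    quadform_tail_prob,
    run_simple_sum,
    simulate_ld_matrix,
    simulate_summary_stats,
    ss_stage2_test,
    stage1_test,
)


def _identity_ld(n):
    keys = [VariantKey("1", 1000 + 10 * i, "A", "G") for i in range(n)]
    return LDMatrix(snps=keys, r=np.eye(n), signed=True)


class TestChisqTransform:
    def test_p_one_maps_to_zero(self):
        assert pvalues_to_chisq([1.0])[0] == 0.0

    @pytest.mark.parametrize("p, expected", [(0.05, 3.8415), (0.3173, 1.000)])
    def test_known_quantiles(self, p, expected):
        assert pvalues_to_chisq([p])[0] == pytest.approx(expected, abs=2e-3)

    def test_agrees_with_squared_normal_quantile(self):
        # independent route: T = z^2 with p = 2*Phi(-|z|)
        p = np.array([0.9, 0.5, 0.1, 1e-4, 1e-12])
        np.testing.assert_allclose(
            pvalues_to_chisq(p), stats.norm.isf(p / 2.0) ** 2, rtol=1e-10)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            pvalues_to_chisq(bad)


class TestQuadformTail:
    def test_two_unit_eigenvalues_closed_form(self):
        # sum of two iid chi2_1 is chi2_2: Pr(>s) = exp(-s/2)
        for s in (0.5, 2.0, 5.991, 15.0):
            assert quadform_tail_prob(s, [1.0, 1.0]) == pytest.approx(
                np.exp(-s / 2.0), abs=1e-6)

    def test_single_eigenvalue_is_chi1_tail(self):
        assert quadform_tail_prob(3.8415, [1.0]) == pytest.approx(0.05, abs=1e-4)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            lam = rng.uniform(0.1, 3.0, size=rng.integers(2, 8))
            s = float(lam.sum() * rng.uniform(0.8, 2.5))
            draws = (rng.chisquare(1, (200_000, lam.size)) * lam).sum(axis=1)
            mc = (draws > s).mean()
            se = np.sqrt(mc * (1 - mc) / draws.size)
            assert abs(quadform_tail_prob(s, lam) - mc) < 3 * se + 1e-12

    def test_far_tail_positive_and_decreasing(self):
        lam = [2.0, 1.0, 0.5]
        ps = [quadform_tail_prob(s, lam) for s in (50, 100, 200)]
        assert all(p > 0 for p in ps)
        assert ps[0] > ps[1] > ps[2]

    def test_all_zero_eigenvalues_degenerate(self):
        with pytest.raises(DegenerateError):
            quadform_tail_prob(1.0, [0.0, 0.0])


class TestStage1:
    def test_single_snp_reduces_to_chi1(self):
        p = stage1_test(np.array([3.8415]), _identity_ld(1))
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_statistics_give_p_one(self):
        assert stage1_test(np.zeros(5), _identity_ld(5)) == 1.0

    def test_uniform_under_identity_null(self):
        # iid chi2_1 evidence with R = I: stage-1 p is exactly uniform
        rng = np.random.default_rng(23)
        R = _identity_ld(30)
        ps = [stage1_test(rng.chisquare(1, 30), R) for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_dimension_mismatch(self):
        with pytest.raises(DomainError):
            stage1_test(np.ones(3), _identity_ld(2))


class TestNoncentrality:
    def test_central_case_clips_to_zero(self):
        assert estimate_noncentrality([1.0, 1.0]) == 0.0
        assert estimate_noncentrality([0.1, 0.2]) == 0.0

    def test_arithmetic(self):
        assert estimate_noncentrality([5.0, 3.0, 4.0]) == pytest.approx(3.0)

    def test_consistency_under_common_noncentrality(self):
        rng = np.random.default_rng(31)
        delta = 4.0
        z = np.sqrt(delta) + rng.standard_normal(1000)
        assert 3.5 <= estimate_noncentrality(z ** 2) <= 4.5


class TestStage2:
    def test_constant_gwas_weights_degenerate(self):
        w = SSWeights.from_pvalues(np.full(6, 0.2))
        with pytest.raises(DegenerateError):
            ss_stage2_test(np.ones(6), w, _identity_ld(6), 0.0)

    def test_null_moments_identity_ld(self):
        # R = I, delta = 0: Z_SS should be standard normal in mean/sd
        rng = np.random.default_rng(41)
        n = 50
        R = _identity_ld(n)
        w = SSWeights.from_pvalues(rng.uniform(size=n))
        zs = np.array([
            ss_stage2_test(rng.chisquare(1, n), w, R, 0.0)[0]
            for _ in range(10_000)
        ])
        assert abs(zs.mean()) < 0.05
        assert abs(zs.std() - 1.0) < 0.05

    def test_calibrated_under_common_noncentrality_null(self):
        # the model's own null: z_e ~ N(sqrt(delta) * 1, R), GWAS independent
        cfg = ScenarioConfig(seed=0)
        R = simulate_ld_matrix(cfg)
        chol = np.linalg.cholesky(R.r + 1e-12 * np.eye(cfg.n_snps))
        rng = np.random.default_rng(47)
        delta_true = 3.0
        hits = 0
        n_rep = 1500
        for _ in range(n_rep):
            z_e = np.sqrt(delta_true) + chol @ rng.standard_normal(cfg.n_snps)
            T = z_e ** 2
            p_g = 2 * stats.norm.sf(np.abs(chol @ rng.standard_normal(cfg.n_snps)))
            w = SSWeights.from_pvalues(p_g)
            _, p = ss_stage2_test(T, w, R, estimate_noncentrality(T))
            hits += p <= 0.05
        rate = hits / n_rep
        assert 0.03 <= rate <= 0.07  # 95% binomial band around 0.05 at n=1500

    def test_permutation_invariance(self):
        rng = np.random.default_rng(43)
        n = 12
        cfg = ScenarioConfig(seed=5, n_snps=n)
        R = simulate_ld_matrix(cfg)
        T = rng.chisquare(1, n)
        w = SSWeights.from_pvalues(rng.uniform(size=n))
        z0, _ = ss_stage2_test(T, w, R, 0.5)
        perm = rng.permutation(n)
        w_p = SSWeights(g=w.g[perm], c=w.c[perm])
        z1, _ = ss_stage2_test(T[perm], w_p, R.subset(perm), 0.5)
        assert z1 == pytest.approx(z0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_centering_and_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(53)
        n = 20
        T = rng.chisquare(1, n)
        g = -np.log10(rng.uniform(size=n))
        R = _identity_ld(n)
        base = SSWeights(g=g, c=g - g.mean())
        z0, _ = ss_stage2_test(T, base, R, 0.2)
        shifted = SSWeights(g=g + shift, c=(g + shift) - (g + shift).mean())
        z1, _ = ss_stage2_test(T, shifted, R, 0.2)
        scaled = SSWeights(g=base.g, c=base.c * scale)
        z2, _ = ss_stage2_test(T, scaled, R, 0.2)
        assert z1 == pytest.approx(z0, rel=1e-9)
        assert z2 == pytest.approx(z0, rel=1e-9)

    def test_monotone_in_T_at_max_weight_snp(self):
        rng = np.random.default_rng(59)
        n = 15
        cfg = ScenarioConfig(seed=7, n_snps=n)
        R = simulate_ld_matrix(cfg)
        T = rng.chisquare(1, n)
        w = SSWeights.from_pvalues(rng.uniform(size=n))
        j = int(np.argmax(w.c))
        last = -np.inf
        for bump in (0.0, 1.0, 5.0, 20.0):
            T2 = T.copy()
            T2[j] += bump
            z, _ = ss_stage2_test(T2, w, R, 0.5)  # delta held fixed
            assert z >= last - 1e-12
            last = z


class TestRunSimpleSum:
    def _first(self, bundle):
        return next(iter(bundle.collection.entries.values()))

    def test_empty_secondary_is_no_data(self, bundle_c):
        cfg = bundle_c.config
        res = run_simple_sum(bundle_c.primary, None, bundle_c.ld, cfg.region)
        assert res.status is Status.NO_DATA
        assert res.sentinel == -1

    def test_uniform_secondary_fails_bonferroni_gate(self, bundle_a):
        cfg = bundle_a.config
        res = run_simple_sum(bundle_a.primary, self._first(bundle_a),
                             bundle_a.ld, cfg.region, m=49)
        assert res.status is Status.NOT_SIGNIFICANT
        assert res.sentinel == -2
        assert res.stage1_p > 0.05 / 49

    def test_colocalized_scenario_detected(self, bundle_c):
        cfg = bundle_c.config
        res = run_simple_sum(bundle_c.primary, self._first(bundle_c),
                             bundle_c.ld, cfg.region)
        assert res.status is Status.OK
        assert res.ss_p < 0.05
        assert res.neglog10_ss_p == pytest.approx(-np.log10(res.ss_p))

    def test_too_few_snps_fails(self, bundle_c):
        # a sub-region holding fewer than 5 of the evenly spaced SNPs
        tiny = Region("13", 25_200_000, 25_206_000)
        res = run_simple_sum(bundle_c.primary, self._first(bundle_c),
                             bundle_c.ld, tiny)
        assert res.status is Status.FAILED
        assert res.sentinel == -3
        assert 0 < res.n_snps < 5

    def test_constant_gwas_pvalues_fail(self, bundle_c):
        cfg = bundle_c.config
        flat = SummaryStatDataset(
            "flat", list(bundle_c.primary.variants),
            np.full(len(bundle_c.primary), 0.5))
        res = run_simple_sum(flat, self._first(bundle_c), bundle_c.ld, cfg.region)
        assert res.status is Status.FAILED

    def test_bonferroni_gate_flips_with_m(self):
        # secondary with constant T such that stage1_p is exactly mid-range
        n = 50
        ld = _identity_ld(n)
        s_target = stats.chi2.isf(0.01, df=n)  # stage1_p = 0.01 under R = I
        p_sec = stats.chi2.sf(np.full(n, s_target / n), df=1)
        secondary = SummaryStatDataset("sec", list(ld.snps), p_sec)
        rng = np.random.default_rng(61)
        primary = SummaryStatDataset("prim", list(ld.snps), rng.uniform(size=n))
        region = Region("1", 1, 100_000)
        ok = run_simple_sum(primary, secondary, ld, region, m=1)
        gated = run_simple_sum(primary, secondary, ld, region, m=10_000)
        assert ok.status is Status.OK
        assert ok.stage1_p == pytest.approx(0.01, abs=1e-4)
        assert gated.status is Status.NOT_SIGNIFICANT
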