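"""Dispersion estimation, the NB exact test, voom/moderated-t, and BH-FDR."""

import numpy as np
import pytest
from scipy.stats import binom, nbinom, poisson

from peakdiff.differential import (
    DispersionEstimates,
    _nb_logpmf,
    bh_adjust,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    fit_f_dist,
    moderated_t_test,
    nb_exact_test,
    run_differential,
    results_frame,
    squeeze_variances,
    voom_transform,
)
from peakdiff.normalization import OffsetModel, library_size_offsets
from peakdiff.simulate import SimConfig, simulate_count_experiment

from conftest import small_count_matrix


def exact_test_oracle(t_a, t_b, s_a, s_b, n_a, n_b, phi):
    """Brute-force conditional NB enumeration using scipy pmfs."""
    t = int(t_a + t_b)
    mu_a = t * s_a / (s_a + s_b)
    mu_b = t - mu_a
    ks = np.arange(t + 1)
    if phi == 0:
        mass = poisson.pmf(ks, mu_a) * poisson.pmf(t - ks, mu_b)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        mass = nbinom.pmf(ks, r_a, r_a / (r_a + mu_a)) * nbinom.pmf(
            t - ks, r_b, r_b / (r_b + mu_b)
        )
    mass = mass / mass.sum()
    obs = mass[int(t_a)]
    return float(mass[mass <= obs * (1 + 1e-9)].sum())


class TestNBLogPmf:
    def test_matches_scipy(self, rng):
        k = rng.integers(0, 50, 200)
        mu = rng.uniform(0.1, 40, 200)
        r = rng.uniform(0.5, 100, 200)
        expected = nbinom.logpmf(k, r, r / (r + mu))
        assert np.allclose(_nb_logpmf(k, r, mu), expected, atol=1e-10)

    def test_poisson_limit(self, rng):
        k = rng.integers(0, 30, 100)
        mu = rng.uniform(0.1, 20, 100)
        assert np.allclose(_nb_logpmf(k, np.inf, mu), poisson.logpmf(k, mu), atol=1e-12)


class TestExactTest:
    def _run(self, counts, conditions, phi, offsets=None):
        cm = small_count_matrix(counts, conditions, full_sizes=[1e6] * len(conditions))
        if offsets is None:
            offsets = OffsetModel("full_lib", np.zeros(len(conditions)))
        disp = DispersionEstimates(phi, np.full(len(counts), phi))
        return cm, nb_exact_test(cm, offsets, disp)

    def test_mode_gives_p_one(self):
        counts = np.array([[10, 10]])
        _, res = self._run(counts, "ab", 0.1)
        assert res[0].pvalue == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial(self):
        # phi = 0, equal sizes, total 20 split 15/5: conditional law is Binomial(20, 1/2)
        counts = np.array([[15, 5]])
        _, res = self._run(counts, "ab", 0.0)
        mass = binom.pmf(np.arange(21), 20, 0.5)
        expected = mass[mass <= mass[15] * (1 + 1e-9)].sum()
        assert res[0].pvalue == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        # all totals <= 50, phi = 0.2, replicated unequal-offset design
        counts = rng.integers(0, 13, (40, 4))
        log_off = np.log(np.array([1.0, 1.3, 0.8, 1.1]))
        cm = small_count_matrix(counts, "aabb")
        offsets = OffsetModel("full_lib", log_off)
        disp = DispersionEstimates(0.2, np.full(40, 0.2))
        res = nb_exact_test(cm, offsets, disp)
        s_a = np.exp(log_off[:2]).sum()
        s_b = np.exp(log_off[2:]).sum()
        for g, r in enumerate(res):
            t_a, t_b = counts[g, :2].sum(), counts[g, 2:].sum()
            if t_a + t_b == 0:
                assert r.pvalue == 1.0
                continue
            expected = exact_test_oracle(t_a, t_b, s_a, s_b, 2, 2, 0.2)
            assert abs(r.pvalue - expected) < 1e-10

    def test_zero_total_untestable(self):
        counts = np.array([[0, 0], [5, 5]])
        _, res = self._run(counts, "ab", 0.1)
        assert res[0].pvalue == 1.0
        assert res[0].log2fc == 0.0

    def test_label_swap_symmetry(self, rng):
        counts = rng.integers(0, 40, (30, 4))
        cm = small_count_matrix(counts, "aabb")
        offsets = OffsetModel("full_lib", np.zeros(4))
        disp = DispersionEstimates(0.1, np.full(30, 0.1))
        fwd = nb_exact_test(cm, offsets, disp, "a", "b")
        rev = nb_exact_test(cm, offsets, disp, "b", "a")
        for f, r in zip(fwd, rev):
            assert f.pvalue == pytest.approx(r.pvalue, rel=1e-12)
            assert f.log2fc == pytest.approx(-r.log2fc, rel=1e-9, abs=1e-12)

    def test_offset_shift_invariance(self, rng):
        counts = rng.integers(0, 60, (25, 4))
        cm = small_count_matrix(counts, "aabb")
        disp = DispersionEstimates(0.1, np.full(25, 0.1))
        base = np.log(np.array([1.0, 2.0, 1.5, 0.5]))
        p1 = [r.pvalue for r in nb_exact_test(cm, OffsetModel("x", base), disp)]
        p2 = [r.pvalue for r in nb_exact_test(cm, OffsetModel("x", base + 3.7), disp)]
        fc1 = [r.log2fc for r in nb_exact_test(cm, OffsetModel("x", base), disp)]
        fc2 = [r.log2fc for r in nb_exact_test(cm, OffsetModel("x", base + 3.7), disp)]
        assert np.allclose(p1, p2, rtol=1e-9)
        assert np.allclose(fc1, fc2, rtol=1e-9)


class TestDispersionEstimation:
    def test_recovery_at_phi_005(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=4000, seed=5)
        cm, _, _ = simulate_count_experiment(cfg)
        off = library_size_offsets(cm, "full")
        est = estimate_common_dispersion(cm, off)
        assert 0.04 <= est.common_phi <= 0.06

    def test_poisson_boundary(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=4000, dispersion=0.0, seed=5)
        cm, _, _ = simulate_count_experiment(cfg)
        est = estimate_common_dispersion(cm, library_size_offsets(cm, "full"))
        assert est.common_phi <= 0.005

    def test_constant_offset_shift_invariance(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=500, seed=5)
        cm, _, _ = simulate_count_experiment(cfg)
        off = library_size_offsets(cm, "full")
        shifted = OffsetModel("full_lib", off.sample_log_offsets + np.log(2))
        e1 = estimate_common_dispersion(cm, off).common_phi
        e2 = estimate_common_dispersion(cm, shifted).common_phi
        assert e1 == pytest.approx(e2, rel=1e-6)

    def test_no_replication_errors(self, rng):
        cm = small_count_matrix(rng.poisson(50, (20, 2)), "ab")
        with pytest.raises(ValueError, match="dispersion"):
            estimate_common_dispersion(cm, OffsetModel("x", np.zeros(2)))


class TestTagwiseDispersion:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=1500, seed=3)
        cm, _, _ = simulate_count_experiment(cfg)
        off = library_size_offsets(cm, "full")
        common = estimate_common_dispersion(cm, off)
        return cm, off, common

    def test_large_prior_recovers_common(self, setup):
        cm, off, common = setup
        tw = estimate_tagwise_dispersion(cm, off, common, prior_df=1e6)
        assert np.max(np.abs(tw.tagwise_phi - common.common_phi)) < 1e-3

    def test_small_prior_approaches_individual_ml(self, setup):
        from scipy.optimize import minimize_scalar

        from peakdiff.differential import _apl

        cm, off, common = setup
        tw = estimate_tagwise_dispersion(cm, off, common, prior_df=0.01)
        # per-region ML oracle for a handful of regions
        for g in [0, 100, 900]:
            sub = small_count_matrix(
                cm.counts[[g]], list(cm.samples["condition"]),
                full_sizes=list(cm.full_library_sizes),
            )
            res = minimize_scalar(
                lambda lp: -float(_apl(sub, off, np.exp(lp))[0]),
                bounds=(np.log(1e-6), np.log(10.0)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            assert tw.tagwise_phi[g] == pytest.approx(np.exp(res.x), rel=0.05, abs=1e-4)

    def test_shrinkage_monotone_in_prior(self, setup):
        cm, off, common = setup
        iqrs = []
        for prior in (0.5, 5.0, 50.0):
            tw = estimate_tagwise_dispersion(cm, off, common, prior_df=prior)
            q75, q25 = np.percentile(tw.tagwise_phi, [75, 25])
            iqrs.append(q75 - q25)
        assert iqrs[0] > iqrs[1] > iqrs[2]

    def test_invalid_prior(self, setup):
        cm, off, common = setup
        with pytest.raises(ValueError):
            estimate_tagwise_dispersion(cm, off, common, prior_df=0.0)


class TestVoom:
    def test_log_cpm_closed_form(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[1:] = 50
        cm = small_count_matrix(counts, "aabb", full_sizes=[999_999.0] * 4)
        vs = voom_transform(cm)
        # count 0 at N+1 = 1e6: log2(0.5/1e6 * 1e6) = -1
        assert vs.log_cpm[0, 0] == pytest.approx(-1.0)

    def test_doubling_library_size_lowers_log_cpm(self, rng):
        counts = rng.poisson(100, (50, 4)) + 1
        cm1 = small_count_matrix(counts, "aabb", full_sizes=[1e6] * 4)
        cm2 = small_count_matrix(counts, "aabb", full_sizes=[2e6, 1e6, 1e6, 1e6])
        v1 = voom_transform(cm1)
        v2 = voom_transform(cm2)
        assert np.allclose(v1.log_cpm[:, 0] - v2.log_cpm[:, 0], 1.0, atol=1e-5)

    def test_homoskedastic_fixture_flat_weights(self, rng):
        # log-normal counts with constant log-scale sd across a wide
        # abundance range: the sqrt-sd trend is flat, so weights are too
        base = rng.uniform(8, 13, 3000)
        counts = np.round(2 ** (base[:, None] + rng.normal(0, 0.3, (3000, 6)))).astype(int)
        cm = small_count_matrix(counts, "aaabbb", full_sizes=[3e6] * 6)
        vs = voom_transform(cm)
        w = vs.weights
        assert (w.max() - w.min()) / w.mean() < 0.10

    def test_weights_positive(self, rng):
        counts = rng.poisson(20, (100, 4)) + rng.integers(0, 2, (100, 4))
        cm = small_count_matrix(counts + 1, "aabb", full_sizes=[1e6] * 4)
        assert (voom_transform(cm).weights > 0).all()


class TestModeratedT:
    def test_variance_pooling_formula(self):
        # (4*0.04 + 4*0.09) / 8 = 0.065
        assert squeeze_variances(np.array([0.09]), 4, 4, 0.04)[0] == pytest.approx(0.065)

    def test_zero_prior_recovers_ordinary_t(self, rng):
        from scipy.stats import t as t_dist

        counts = rng.poisson(500, (60, 6))
        cm = small_count_matrix(counts, "aaabbb", full_sizes=[1e6] * 6)
        vs = voom_transform(cm)
        res = moderated_t_test(cm, vs, prior=(0.0, 1.0))
        # independent ordinary weighted two-sample t for one region
        g = 17
        w, x = vs.weights[g], vs.log_cpm[g]
        wa, wb = w[:3].sum(), w[3:].sum()
        ma = (w[:3] * x[:3]).sum() / wa
        mb = (w[3:] * x[3:]).sum() / wb
        s2 = ((w[:3] * (x[:3] - ma) ** 2).sum() + (w[3:] * (x[3:] - mb) ** 2).sum()) / 4
        t = (ma - mb) / np.sqrt(s2 * (1 / wa + 1 / wb))
        p = 2 * t_dist.sf(abs(t), 4)
        assert res[g].pvalue == pytest.approx(p, rel=1e-10)

    def test_null_pvalues_approximately_uniform(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=5000, seed=9)
        cm, _, _ = simulate_count_experiment(cfg)
        vs = voom_transform(cm)
        res = moderated_t_test(cm, vs)
        from scipy.stats import kstest

        p = np.array([r.pvalue for r in res])
        assert kstest(p, "uniform").statistic < 0.03

    def test_fit_f_dist_recovers_prior(self, rng):
        # s2 ~ s0^2 * F(d, d0) scaled: simulate from the model and refit
        d, d0, s02 = 4, 8.0, 0.25
        chi_num = rng.chisquare(d, 20000) / d
        chi_den = rng.chisquare(d0, 20000) / d0
        s2 = s02 * chi_num / chi_den
        d0_hat, s02_hat = fit_f_dist(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s02_hat == pytest.approx(s02, rel=0.05)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_equal(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_matches_stepup_oracle(self, rng):
        p = rng.uniform(0, 1, 97)
        got = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        assert np.allclose(got, q)
        assert np.all(got >= p)
        assert np.all(np.diff(got[order]) >= -1e-15)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestRunDifferential:
    def test_null_yields_no_signal(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=2000, seed=2)
        cm, _, _ = simulate_count_experiment(cfg)
        for method in ("edgeR_full", "voom_full"):
            df = results_frame(run_differential(cm, method))
            assert df.significant.mean() < 0.005

    def test_monotone_power_in_effect_size(self):
        nsig = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            cfg = SimConfig(
                scenario="global_gain",
                n_regions=2000,
                fraction_changed=0.3,
                effect_log2=effect,
                seed=4,
            )
            cm, _, _ = simulate_count_experiment(cfg)
            df = results_frame(run_differential(cm, "edgeR_full"))
            nsig.append(int(df.significant.sum()))
        assert nsig == sorted(nsig)
        assert nsig[-1] > nsig[0]

    def test_diffbind_requires_input(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=200, seed=2)
        cm, _, _ = simulate_count_experiment(cfg)
        with pytest.raises(ValueError, match="input"):
            run_differential(cm, "diffbind_full")

    def test_unknown_method(self):
        cfg = SimConfig(scenario="null_equal_depth", n_regions=100, seed=2)
        cm, _, _ = simulate_count_experiment(cfg)
        with pytest.raises(ValueError, match="unknown method"):
            run_differential(cm, "bogus")

    def test_diffbind_composition_matches_manual(self):
        from peakdiff.normalization import input_subtract, tmm_factors

        cfg = SimConfig(scenario="celltype_cna", n_regions=800, seed=6)
        cm, icm, _ = simulate_count_experiment(cfg)
        auto = results_frame(run_differential(cm, "diffbind_full", input_cm=icm))
        sub = input_subtract(cm, icm, floor=1)
        off = tmm_factors(sub, lib="full")
        disp = estimate_common_dispersion(sub, off)
        manual = results_frame(nb_exact_test(sub, off, disp))
        assert np.allclose(auto.pvalue, manual.pvalue)
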