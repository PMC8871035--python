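import numpy as np
import pytest
from scipy import integrate

from ierdjpc import (
    DegenerateDataError,
    EMConfig,
    IERDParams,
    JPCData,
    JPCDesign,
    TwoSampleParams,
    conditional_moments,
    direct_fit,
    em_fit,
    logpdf,
    observed_loglik,
    pooled_complete_record,
    simulate_jpc,
)
from ierdjpc.distribution import log_g, pdf, sf
from ierdjpc.em import _loglik_unchecked


def trunc_moment_quad(fn, w, theta, lam):
    """Adaptive-quadrature oracle for E[fn(U) | U > w], U ~ IERD(theta, lam)."""
    p = IERDParams(theta, lam)
    norm = float(sf(np.array([w]), p)[0])
    val, _ = integrate.quad(
        lambda u: fn(u) * pdf(u, p) / norm, w, np.inf, epsabs=1e-12, epsrel=1e-12, limit=400
    )
    return val


class TestObservedLoglik:
    def test_complete_data_equals_sum_of_logdensities(self, coating):
        tcs, bcs = coating
        rec = pooled_complete_record(tcs, bcs)
        p = TwoSampleParams(15.0, 14.0, 55.0)
        direct = float(
            np.sum(logpdf(tcs, IERDParams(p.theta1, p.lam)))
            + np.sum(logpdf(bcs, IERDParams(p.theta2, p.lam)))
        )
        assert observed_loglik(p, rec) == pytest.approx(direct, rel=1e-12)

    def test_pairwise_differences_match_product_form(self):
        # exp of log-likelihood differences must equal the ratio of the
        # product-form likelihoods evaluated term by term
        design = JPCDesign(m=4, n=4, k=5, removals=(1, 0, 1, 0, 1))
        data = simulate_jpc(design, IERDParams(3, 2), IERDParams(2, 2), 13)

        def product_likelihood(p):
            g = -np.expm1(-p.lam / data.w**2)
            dens = np.where(
                data.z == 1,
                pdf(data.w, IERDParams(p.theta1, p.lam)),
                pdf(data.w, IERDParams(p.theta2, p.lam)),
            )
            surv = g ** (p.theta1 * data.s) * g ** (p.theta2 * data.t)
            return float(np.prod(dens * surv))

        pa = TwoSampleParams(3.0, 2.0, 2.0)
        pb = TwoSampleParams(2.5, 1.5, 1.7)
        diff = observed_loglik(pa, data) - observed_loglik(pb, data)
        ratio = product_likelihood(pa) / product_likelihood(pb)
        assert np.exp(diff) == pytest.approx(ratio, rel=1e-9)

    def test_degenerate_record_raises_and_is_monotone_in_missing_shape(self):
        design = JPCDesign(m=3, n=3, k=3, removals=(1, 1, 1))
        data = JPCData(
            w=[0.5, 0.8, 1.1], s=[1, 1, 1], t=[0, 0, 0], z=[0, 0, 0], design=design
        )
        assert data.k1 == 0
        with pytest.raises(DegenerateDataError):
            observed_loglik(TwoSampleParams(1, 1, 1), data)
        # the unguarded expression is strictly decreasing in theta1
        thetas = np.linspace(0.5, 10, 40)
        vals = [
            _loglik_unchecked(TwoSampleParams(th, 1.0, 1.0), data) for th in thetas
        ]
        assert np.all(np.diff(vals) < 0)


class TestConditionalMoments:
    @pytest.mark.parametrize(
        "w, theta, lam",
        [(0.8, 3.0, 2.0), (1.5, 2.0, 2.0), (4.0, 15.5, 57.0), (0.6, 0.7, 1.3)],
    )
    def test_e_log_g_closed_form_matches_quadrature(self, w, theta, lam):
        m = conditional_moments(w, theta, lam)
        closed = float(log_g(w, lam)) - 1.0 / theta
        oracle = trunc_moment_quad(
            lambda u: np.log(-np.expm1(-lam / u**2)), w, theta, lam
        )
        assert m.e_log_g == pytest.approx(closed, rel=1e-12)
        assert m.e_log_g == pytest.approx(oracle, abs=1e-8)

    def test_e_inv_u2_theta_one_closed_form(self):
        w, lam = 1.2, 2.0
        m = conditional_moments(w, 1.0, lam)
        e = np.exp(-lam / w**2)
        closed = (1 - e - (lam / w**2) * e) / (lam * (1 - e))
        assert m.e_inv_u2 == pytest.approx(closed, rel=1e-9)

    @pytest.mark.parametrize(
        "w, theta, lam",
        [(0.8, 3.0, 2.0), (1.5, 2.0, 2.0), (4.0, 15.5, 57.0), (0.6, 0.45, 1.3)],
    )
    def test_moments_match_quadrature_oracle(self, w, theta, lam):
        m = conditional_moments(w, theta, lam)
        o_inv = trunc_moment_quad(lambda u: u**-2.0, w, theta, lam)
        o_log = trunc_moment_quad(np.log, w, theta, lam)
        assert m.e_inv_u2 == pytest.approx(o_inv, rel=1e-6)
        assert m.e_log_u == pytest.approx(o_log, rel=1e-7)

    def test_support_bound_on_inverse_moment(self):
        for w, theta, lam in [(0.5, 2.0, 2.0), (3.0, 10.0, 50.0), (0.2, 1.0, 2.0)]:
            assert 0 < conditional_moments(w, theta, lam).e_inv_u2 < w**-2

    def test_nonpositive_w_rejected(self):
        with pytest.raises(ValueError):
            conditional_moments(0.0, 1.0, 1.0)


class TestEMFit:
    def test_pooled_complete_coating_reproduces_printed_mles(self, coating):
        rec = pooled_complete_record(*coating)
        res = em_fit(rec)
        assert res.converged
        assert res.estimates.theta1 == pytest.approx(15.56, abs=0.015)
        assert res.estimates.theta2 == pytest.approx(14.87, abs=0.01)
        assert res.estimates.lam == pytest.approx(57.08, abs=0.01)

    def test_em_agrees_with_direct_optimizer_on_battery(self, truth):
        designs = [
            JPCDesign(m=25, n=20, k=30, removals="(5,0^28,10)"),
            JPCDesign(m=25, n=20, k=20, removals="(0^9,25,0^10)"),
            JPCDesign(m=20, n=25, k=20, removals="(10,0^18,15)"),
            JPCDesign(m=45, n=40, k=40, removals="(0^17,9^5,0^18)"),
        ]
        pA = IERDParams(truth.theta1, truth.lam)
        pB = IERDParams(truth.theta2, truth.lam)
        checked = 0
        seed = 0
        while checked < 20:
            d = simulate_jpc(designs[checked % len(designs)], pA, pB, seed)
            seed += 1
            if d.is_degenerate:
                continue
            em = em_fit(d, EMConfig(init=truth))
            dr = direct_fit(d)
            rel = np.abs(em.estimates.as_array() / dr.estimates.as_array() - 1.0)
            assert np.max(rel) < 1e-3, (checked, rel)
            checked += 1

    def test_em_does_not_decrease_observed_loglik(self, sim_dataset, truth):
        res = em_fit(sim_dataset, EMConfig(init=truth))
        assert res.converged
        assert res.loglik >= observed_loglik(truth, sim_dataset) - 1e-6

    def test_trace_and_convergence_contract(self, sim_dataset, truth):
        res = em_fit(sim_dataset, EMConfig(init=truth))
        assert res.trace.shape == (res.iterations + 1, 3)
        assert np.all(np.abs(res.trace[-1] - res.trace[-2]) <= 1e-4)

    def test_max_iter_flags_unconverged_without_raising(self, sim_dataset, truth):
        res = em_fit(sim_dataset, EMConfig(init=truth, max_iter=2))
        assert not res.converged
        assert res.iterations == 2

    def test_degenerate_data_raises(self):
        design = JPCDesign(m=3, n=3, k=3, removals=(1, 1, 1))
        data = JPCData(
            w=[0.5, 0.8, 1.1], s=[1, 1, 1], t=[0, 0, 0], z=[0, 0, 0], design=design
        )
        with pytest.raises(DegenerateDataError):
            em_fit(data)

    def test_default_init_recovers_reasonable_estimates(self, sim_dataset):
        res = em_fit(sim_dataset)
        assert res.converged
        assert np.all(res.estimates.as_array() > 0)


class TestDirectFit:
    def test_matches_em_on_pooled_coating(self, coating):
        rec = pooled_complete_record(*coating)
        res = direct_fit(rec)
        assert res.estimates.theta1 == pytest.approx(15.56, abs=0.015)
        assert res.estimates.theta2 == pytest.approx(14.87, abs=0.01)
        assert res.estimates.lam == pytest.approx(57.08, abs=0.01)

    def test_direct_is_at_least_as_good_a_maximizer(self, sim_dataset, truth):
        em = em_fit(sim_dataset, EMConfig(init=truth))
        dr = direct_fit(sim_dataset)
        assert dr.loglik >= em.loglik - 1e-6


class TestParameterRecovery:
    def test_mse_decreases_as_k_grows(self, truth):
        # same m, n; k = 20 vs 40: more observed failures -> better estimates
        d20 = JPCDesign(m=45, n=40, k=20, removals="(0^9,65,0^10)")
        d40 = JPCDesign(m=45, n=40, k=40, removals="(0^17,9^5,0^18)")
        pA = IERDParams(truth.theta1, truth.lam)
        pB = IERDParams(truth.theta2, truth.lam)
        mses = {}
        for tag, design in [("k20", d20), ("k40", d40)]:
            errs = []
            for seed in range(60):
                data = simulate_jpc(design, pA, pB, seed)
                if data.is_degenerate:
                    continue
                est = em_fit(data, EMConfig(init=truth)).estimates.as_array()
                errs.append((est - truth.as_array()) ** 2)
            mses[tag] = np.mean(errs, axis=0)
        # the common scale is the best-estimated parameter; its MSE must drop
        assert mses["k40"][2] < mses["k20"][2]
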