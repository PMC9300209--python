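"""Likelihood kernels: densities, integrals, mixtures and their oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from bulkfreq.likelihood import (
    ParamVector,
    bulk_sample_loglik,
    dtauw_logdensity,
    psi_beta,
    psi_gamma,
    total_negloglik,
)
from bulkfreq.model_core import DeltaPair

AUX = dict(delta_T=1.2, z=0.0016, eta=0.97, sigma_c=0.2)


def normal_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))


class TestDtauWDensity:
    def test_value_at_mode(self):
        sd = math.sqrt(2.0) * 0.2
        at_mode = dtauw_logdensity(0.0, delta_T=1.0, eta=0.97, sigma_c=0.2)
        assert at_mode == pytest.approx(math.log(1.0 / (sd * math.sqrt(2 * math.pi))))

    def test_neutral_target_content_centres_at_zero(self):
        for eta in (0.5, 0.97, 1.5):
            a = dtauw_logdensity(0.3, delta_T=1.0, eta=eta, sigma_c=0.2)
            b = normal_logpdf(0.3, 0.0, math.sqrt(2.0) * 0.2)
            assert a == pytest.approx(b)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda x: math.exp(dtauw_logdensity(x, 1.3, 0.97, 0.25)), -10, 10
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            dtauw_logdensity(0.0, 1.0, 1.0, 0.0)


class TestPsiBeta:
    def test_z_one_collapses_to_plain_normal(self):
        # with z=1 digestion removes nothing: the ratio is always 1
        val = psi_beta(0.5, 2, 4, 1.0, 1.2, z=1.0, eta=0.97, sigma_c=0.2)
        expect = math.exp(
            normal_logpdf(0.5, -math.log(1.2) / math.log1p(0.97), math.sqrt(2) * 0.2)
        )
        assert val == pytest.approx(expect, rel=1e-12)

    def test_monte_carlo_oracle(self):
        # marginal over y ~ Beta(mk, (n-m)k) by brute-force simulation
        m, n, k = 2, 4, 1.0
        rng = np.random.default_rng(11)
        y = rng.beta(m * k, (n - m) * k, size=1_000_000)
        sd = math.sqrt(2.0) * AUX["sigma_c"]
        for d in (0.0, 2.0, 5.0):
            mu = -(np.log(AUX["delta_T"]) + np.log(AUX["z"] + y * (1 - AUX["z"])))
            mu /= math.log1p(AUX["eta"])
            vals = np.exp(-0.5 * ((d - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
            mc, se = vals.mean(), vals.std(ddof=1) / 1000.0
            assert psi_beta(d, m, n, k, **AUX) == pytest.approx(mc, abs=3 * se)

    def test_is_a_density_in_dtau_d(self):
        val, _ = integrate.quad(
            lambda d: psi_beta(d, 1, 2, 0.7, **AUX), -6.0, 16.0, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("m,n,k,d", [(1, 2, 0.5, 6.0), (3, 8, 27.0, 2.0), (7, 8, 1.0, -1.0)])
    def test_fast_rule_matches_adaptive_quadrature(self, m, n, k, d):
        fast = psi_beta(d, m, n, k, **AUX, method="tanh-sinh")
        ref = psi_beta(d, m, n, k, **AUX, method="quad")
        assert fast == pytest.approx(ref, rel=1e-8)

    def test_interior_only(self):
        with pytest.raises(ValueError):
            psi_beta(1.0, 0, 4, 1.0, **AUX)
        with pytest.raises(ValueError):
            psi_beta(1.0, 4, 4, 1.0, **AUX)


class TestPsiGamma:
    @pytest.mark.parametrize("m,n,k", [(1, 2, 1.0), (2, 4, 0.5), (3, 8, 3.0)])
    def test_matches_beta_kernel(self, m, n, k):
        # ratio of independent same-scale gammas is beta: identical marginals
        for d in (0.0, 3.0):
            g = psi_gamma(d, m, n, k, **AUX)
            b = psi_beta(d, m, n, k, **AUX)
            assert g == pytest.approx(b, rel=1e-7)

    def test_scale_invariance(self):
        a = psi_gamma(2.0, 2, 4, 1.0, **AUX, theta=1.0)
        b = psi_gamma(2.0, 2, 4, 1.0, **AUX, theta=1e3)
        assert a == pytest.approx(b, rel=1e-9)

    def test_monte_carlo_oracle_exponential_yields(self):
        # m=1, n=2, k=1: both template amounts are exponential draws
        rng = np.random.default_rng(5)
        r = rng.exponential(size=1_000_000)
        s = rng.exponential(size=1_000_000)
        d = 2.0
        sd = math.sqrt(2.0) * AUX["sigma_c"]
        mu = -(np.log(AUX["delta_T"]) + np.log((r + AUX["z"] * s) / (r + s)))
        mu /= math.log1p(AUX["eta"])
        vals = np.exp(-0.5 * ((d - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        mc, se = vals.mean(), vals.std(ddof=1) / 1000.0
        assert psi_gamma(d, 1, 2, 1.0, **AUX) == pytest.approx(mc, abs=3 * se)


def make_params(p, k=1.0, fixed=frozenset()):
    return ParamVector(
        p=p, k=k, delta_T=AUX["delta_T"], sigma_c=AUX["sigma_c"],
        z=AUX["z"], eta=AUX["eta"], fixed=fixed,
    )


class TestBulkSampleLoglik:
    def test_p_zero_reduces_to_all_susceptible_branch(self):
        delta = DeltaPair(d_tau_W=-0.2, d_tau_D=9.0)
        L = math.log1p(AUX["eta"])
        sd = math.sqrt(2.0) * AUX["sigma_c"]
        expect = dtauw_logdensity(-0.2, AUX["delta_T"], AUX["eta"], AUX["sigma_c"])
        expect += normal_logpdf(9.0, -math.log(AUX["z"] * AUX["delta_T"]) / L, sd)
        got = bulk_sample_loglik(delta, n=6, params=make_params(0.0))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_p_one_reduces_to_all_resistant_branch(self):
        delta = DeltaPair(d_tau_W=-0.2, d_tau_D=-0.1)
        L = math.log1p(AUX["eta"])
        sd = math.sqrt(2.0) * AUX["sigma_c"]
        expect = dtauw_logdensity(-0.2, AUX["delta_T"], AUX["eta"], AUX["sigma_c"])
        expect += normal_logpdf(-0.1, -math.log(AUX["delta_T"]) / L, sd)
        got = bulk_sample_loglik(delta, n=6, params=make_params(1.0))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_matches_explicit_enumeration_for_n2(self):
        # n=2, p=0.3: 3-term mixture written out by hand
        p, n, k = 0.3, 2, 0.8
        delta = DeltaPair(d_tau_W=0.1, d_tau_D=3.0)
        L = math.log1p(AUX["eta"])
        sd = math.sqrt(2.0) * AUX["sigma_c"]
        w = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        branch = [
            math.exp(normal_logpdf(3.0, -math.log(AUX["z"] * AUX["delta_T"]) / L, sd)),
            psi_beta(3.0, 1, 2, k, **AUX),
            math.exp(normal_logpdf(3.0, -math.log(AUX["delta_T"]) / L, sd)),
        ]
        expect = dtauw_logdensity(0.1, AUX["delta_T"], AUX["eta"], AUX["sigma_c"])
        expect += math.log(sum(wi * bi for wi, bi in zip(w, branch)))
        got = bulk_sample_loglik(delta, n=n, params=make_params(p, k=k))
        assert got == pytest.approx(expect, rel=1e-10)

    def test_binomial_weights_enter_mixture(self):
        # for n=4, p=0.5 the m=0 weight is 1/16; push the observation into
        # the far m=0 regime and check the mixture approaches weight*branch
        L = math.log1p(AUX["eta"])
        sd = math.sqrt(2.0) * AUX["sigma_c"]
        d0 = -math.log(AUX["z"] * AUX["delta_T"]) / L  # m=0 branch centre
        delta = DeltaPair(d_tau_W=0.0, d_tau_D=d0 + 4 * sd)
        got = bulk_sample_loglik(delta, n=4, params=make_params(0.5))
        lower_bound = (
            dtauw_logdensity(0.0, AUX["delta_T"], AUX["eta"], AUX["sigma_c"])
            + math.log(0.0625)
            + normal_logpdf(delta.d_tau_D, d0, sd)
        )
        assert got >= lower_bound
        assert got == pytest.approx(lower_bound, abs=0.7)


class TestTotalNegLoglik:
    samples = [
        (DeltaPair(d_tau_W=-0.1, d_tau_D=2.0), 4),
        (DeltaPair(d_tau_W=0.2, d_tau_D=7.5), 4),
        (DeltaPair(d_tau_W=0.0, d_tau_D=0.3), 8),
    ]

    def test_matches_per_sample_sum(self):
        params = make_params(0.2)
        total = total_negloglik(self.samples, params)
        by_hand = -sum(bulk_sample_loglik(dp, n, params) for dp, n in self.samples)
        assert total == pytest.approx(by_hand, rel=1e-12)

    def test_additivity_under_duplication(self):
        params = make_params(0.2)
        once = total_negloglik(self.samples, params)
        twice = total_negloglik(self.samples * 2, params)
        assert twice == pytest.approx(2 * once, rel=1e-12)

    def test_permutation_invariance(self):
        params = make_params(0.35, k=2.0)
        a = total_negloglik(self.samples, params)
        b = total_negloglik(list(reversed(self.samples)), params)
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            total_negloglik(self.samples[:1], make_params(0.2))

    def test_smooth_in_transformed_parameters(self):
        # central differences exist and are stable at an interior point
        params = make_params(0.2)
        x0 = params.to_free()
        h = 1e-5

        def f(x):
            return total_negloglik(self.samples, params.with_free(x))

        for i in range(x0.size):
            e = np.zeros_like(x0)
            e[i] = h
            g1 = (f(x0 + e) - f(x0 - e)) / (2 * h)
            g2 = (f(x0 + 2 * e) - f(x0 - 2 * e)) / (4 * h)
            assert math.isfinite(g1)
            assert g1 == pytest.approx(g2, rel=1e-3, abs=1e-6)


class TestParamVector:
    def test_transform_round_trip(self):
        pv = make_params(0.07, k=3.0)
        back = pv.with_free(pv.to_free())
        assert back.p == pytest.approx(pv.p, rel=1e-12)
        assert back.k == pytest.approx(pv.k, rel=1e-12)

    def test_fixed_parameters_excluded_from_free_vector(self):
        pv = make_params(0.1, fixed=frozenset({"k"}))
        assert pv.free_names == ("p", "delta_T", "sigma_c")
        assert pv.to_free().size == 3

    def test_validation(self):
        with pytest.raises(ValueError):
            make_params(1.5)
        with pytest.raises(ValueError):
            ParamVector(p=0.5, k=-1.0, delta_T=1.0, sigma_c=0.2, z=0.001, eta=1.0)
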