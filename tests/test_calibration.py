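"""Known-ratio calibration: forward means, joint MLE, diagnostics."""

import math

import numpy as np
import pytest

from bulkfreq.calibration import (
    KnownRatioObservation,
    fit_known_ratio,
    linearity_diagnostics,
    make_known_ratio_dataset,
    predict_known_cq,
)

TRUTH = {
    "mean_dna": 1.256e-6,
    "delta_T": 1.170,
    "delta_B": 0.2361,
    "sigma_c": 0.2376,
    "z": 0.001564,
    "eta": 0.9712,
}


class TestPredictKnownCq:
    def test_pure_r_digestion_leaves_delta_cq_unchanged(self):
        # at ratio 1 nothing is digested away: ΔτD == ΔτW == -ln δT / L
        d_w = predict_known_cq(TRUTH, 1.0, "target", "W") - predict_known_cq(
            TRUTH, 1.0, "housekeeping", "W"
        )
        d_d = predict_known_cq(TRUTH, 1.0, "target", "D") - predict_known_cq(
            TRUTH, 1.0, "housekeeping", "D"
        )
        expect = -math.log(TRUTH["delta_T"]) / math.log1p(TRUTH["eta"])
        assert d_w == pytest.approx(expect, rel=1e-12)
        assert d_d == pytest.approx(expect, rel=1e-12)

    def test_all_susceptible_delta_cq_saturates_at_residue(self):
        params = dict(TRUTH, delta_T=1.0, delta_B=1.0)
        d_d = predict_known_cq(params, 0.0, "target", "D") - predict_known_cq(
            params, 0.0, "housekeeping", "D"
        )
        assert d_d == pytest.approx(-math.log(0.001564) / math.log(1.9712))
        assert d_d == pytest.approx(9.52, abs=0.01)

    def test_housekeeping_control_cq_level(self):
        params = dict(TRUTH, delta_T=1.0, delta_B=1.0)
        assert predict_known_cq(params, 1.0, "housekeeping", "W") == pytest.approx(
            20.02, abs=0.01
        )

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            predict_known_cq(TRUTH, 1.2, "target", "D")
        with pytest.raises(ValueError):
            predict_known_cq(TRUTH, 0.5, "intergenic", "D")


class TestFitKnownRatio:
    def test_noise_free_data_recovered_exactly(self):
        data = make_known_ratio_dataset(
            TRUTH, ratios=(0.0, 0.01, 0.1, 0.5, 1.0), n_replicates=1,
            undigested_ratios=None,
        )
        fit = fit_known_ratio(data)
        for name in ("mean_dna", "delta_T", "delta_B", "z", "eta"):
            assert fit[name].estimate == pytest.approx(TRUTH[name], rel=1e-6)
        assert fit["sigma_c"].estimate < 1e-6

    def test_unpaired_layout_recovers_generating_parameters(self, rng):
        # the typical incomplete layout: control wells only at ratio 1
        data = make_known_ratio_dataset(TRUTH, rng=rng)
        fit = fit_known_ratio(data)
        assert fit.success
        for name, tol in [
            ("mean_dna", 0.5), ("delta_T", 0.05), ("delta_B", 0.15),
            ("sigma_c", 0.2), ("z", 0.25), ("eta", 0.05),
        ]:
            assert fit[name].estimate == pytest.approx(TRUTH[name], rel=tol)
            assert fit[name].ci_lower < fit[name].ci_upper

    def test_log_scale_intervals_are_multiplicatively_symmetric(self, rng):
        fit = fit_known_ratio(make_known_ratio_dataset(TRUTH, rng=rng))
        e = fit["delta_T"]
        assert e.ci_upper / e.estimate == pytest.approx(
            e.estimate / e.ci_lower, rel=1e-9
        )

    def test_observation_order_irrelevant(self, rng):
        data = make_known_ratio_dataset(TRUTH, rng=rng)
        a = fit_known_ratio(data)
        b = fit_known_ratio(list(reversed(data)))
        assert a["z"].estimate == pytest.approx(b["z"].estimate, rel=1e-8)
        assert a.loglik == pytest.approx(b.loglik, rel=1e-10)

    def test_round_trip_prediction_reproduces_noiseless_data(self):
        data = make_known_ratio_dataset(
            TRUTH, ratios=(0.0, 0.05, 0.5, 1.0), n_replicates=2,
            undigested_ratios=None,
        )
        fit = fit_known_ratio(data)
        params = {n: e.estimate for n, e in fit.estimates.items()}
        for obs in data:
            assert predict_known_cq(
                params, obs.ratio, obs.gene, obs.condition
            ) == pytest.approx(obs.cq, abs=1e-6)

    def test_coverage_of_wald_intervals(self):
        # repeated noisy experiments: the 95% CI of each parameter should
        # cover its generating value at roughly nominal frequency
        hits = {n: 0 for n in TRUTH}
        trials, ok = 60, 0
        for s in range(trials):
            data = make_known_ratio_dataset(
                TRUTH, rng=np.random.default_rng(3_000 + s)
            )
            fit = fit_known_ratio(data)
            if not fit.success:
                continue
            ok += 1
            for n in TRUTH:
                if fit[n].ci_lower <= TRUTH[n] <= fit[n].ci_upper:
                    hits[n] += 1
        assert ok >= 55
        for n, c in hits.items():
            assert 0.80 <= c / ok <= 1.0, f"{n} coverage {c / ok}"


class TestIdentifiabilityGuards:
    def test_single_ratio_rejected(self):
        data = [o for o in make_known_ratio_dataset(TRUTH, ratios=(1.0,),
                undigested_ratios=None, n_replicates=2)]
        with pytest.raises(ValueError, match="distinct mixing ratios"):
            fit_known_ratio(data)

    def test_missing_digested_series_names_z(self):
        data = [
            o
            for o in make_known_ratio_dataset(
                TRUTH, ratios=(0.1, 1.0), undigested_ratios=None, n_replicates=2
            )
            if not (o.condition == "D" and o.gene == "target" and o.ratio < 1.0)
        ]
        with pytest.raises(ValueError, match="z"):
            fit_known_ratio(data)

    def test_missing_controls_names_delta_b(self):
        data = [
            o
            for o in make_known_ratio_dataset(TRUTH, n_replicates=2)
            if o.condition != "W"
        ]
        with pytest.raises(ValueError, match="delta_B"):
            fit_known_ratio(data)

    def test_paired_mode_requires_complete_quartets(self):
        data = make_known_ratio_dataset(TRUTH, n_replicates=2)  # mite layout
        with pytest.raises(ValueError, match="complete"):
            fit_known_ratio(data, paired=True)
        complete = make_known_ratio_dataset(
            TRUTH, n_replicates=2, undigested_ratios=None
        )
        fit = fit_known_ratio(complete, paired=True)
        assert fit.converged


class TestLinearityDiagnostics:
    def test_noise_free_data_gives_perfect_line(self):
        data = make_known_ratio_dataset(TRUTH, n_replicates=4)
        d = linearity_diagnostics(data, z=TRUTH["z"], eta=TRUTH["eta"], scale="ddcq")
        assert d.slope == pytest.approx(1.0, abs=1e-9)
        assert d.intercept == pytest.approx(0.0, abs=1e-9)
        assert d.adjusted_r2 == pytest.approx(1.0, abs=1e-12)
        assert d.bp_stat == pytest.approx(0.0, abs=1e-6)

    def test_linear_scale_heteroscedasticity_detected(self, rng):
        # homoscedastic Cq noise becomes multiplicative on the frequency
        # scale, so BP should reject far more often on the linear scale
        data = make_known_ratio_dataset(TRUTH, rng=rng)
        dd = linearity_diagnostics(data, z=TRUTH["z"], eta=TRUTH["eta"], scale="ddcq")
        lin = linearity_diagnostics(data, z=TRUTH["z"], eta=TRUTH["eta"], scale="linear")
        assert lin.bp_stat > dd.bp_stat
        assert lin.bp_pvalue < 0.05
        assert dd.adjusted_r2 > 0.98

    def test_bp_statistic_matches_reference_implementation(self, rng):
        pytest.importorskip("statsmodels")
        import statsmodels.api as sm
        from statsmodels.stats.diagnostic import het_breuschpagan

        data = make_known_ratio_dataset(TRUTH, rng=rng)
        d = linearity_diagnostics(data, z=TRUTH["z"], eta=TRUTH["eta"], scale="linear")
        # rebuild the same regression with statsmodels
        from bulkfreq.calibration import observed_ddcq_by_replicate

        triples = observed_ddcq_by_replicate(data)
        x = np.array([TRUTH["z"] + r * (1 - TRUTH["z"]) for _, r, _ in triples])
        y = np.array([(1 + TRUTH["eta"]) ** (-dd) for _, _, dd in triples])
        X = sm.add_constant(x)
        resid = sm.OLS(y, X).fit().resid
        lm_stat, lm_p, _, _ = het_breuschpagan(resid, X)
        assert d.bp_stat == pytest.approx(lm_stat, rel=1e-8)
        assert d.bp_pvalue == pytest.approx(lm_p, rel=1e-6)

    def test_too_few_points_rejected(self):
        data = make_known_ratio_dataset(
            TRUTH, ratios=(0.5, 1.0), n_replicates=1
        )
        with pytest.raises(ValueError, match="3"):
            linearity_diagnostics(data, z=TRUTH["z"], eta=TRUTH["eta"])


class TestObservationValidation:
    def test_bad_fields_rejected(self):
        with pytest.raises(ValueError):
            KnownRatioObservation(1.5, "target", "D", 1, 20.0)
        with pytest.raises(ValueError):
            KnownRatioObservation(0.5, "target", "X", 1, 20.0)
        with pytest.raises(ValueError):
            KnownRatioObservation(0.5, "target", "D", 1, math.nan)
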