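"""Inference pipeline: normalization, homotypic fit, gain algebra, orchestration."""

import math
import random

import numpy as np
import pytest

import clonecomp as cc
from clonecomp.inference import RegressionFit, _mean_homotypic_size


def _exponential_curve(r=0.04, t0=0.0, t1=72.0, dt=0.75, scale=1.0):
    t = np.arange(t0, t1 + 1e-9, dt)
    return cc.GrowthCurve("homotypic", "W", "r1", t, scale * np.exp(r * t))


class TestNormalizeCurve:
    def test_exact_exponential_normalizes_to_unit_at_24h(self):
        c = cc.normalize_curve(_exponential_curve(r=0.05))
        np.testing.assert_allclose(c.signal, np.exp(0.05 * (c.times - 24.0)), rtol=1e-9)

    def test_scale_invariance(self):
        a = cc.normalize_curve(_exponential_curve(scale=1.0))
        b = cc.normalize_curve(_exponential_curve(scale=10.0))
        np.testing.assert_allclose(a.signal, b.signal, rtol=1e-9)

    def test_noiseless_winner_value_at_45h(self, params, schedule):
        (curve, *_) = cc.generate_homotypic_timelapse(
            params, schedule, "W", cc.ExperimentDesign(), cc.NoiseConfig.noiseless()
        )
        norm = cc.normalize_curve(curve, schedule)
        i45 = np.argmin(np.abs(norm.times - 45.0))
        assert norm.signal[i45] == pytest.approx(math.exp(0.031 * 21), rel=1e-9)

    def test_too_few_segment_points_rejected(self, schedule):
        c = _exponential_curve(dt=30.0)  # only 3 frames total
        with pytest.raises(ValueError):
            cc.normalize_curve(c, schedule)


class TestFitHomotypic:
    def test_noiseless_recovery(self, noiseless_bundle, schedule):
        curves_L, curves_W, _, _ = noiseless_bundle
        nL = [cc.normalize_curve(c, schedule) for c in curves_L]
        nW = [cc.normalize_curve(c, schedule) for c in curves_W]
        est, sse, se = cc.fit_homotypic(nL, nW, schedule)
        true = dict(r_L1=0.044, r_W1=0.031, r_L2=0.073, r_W2=0.102, a=-0.004, d=-0.008)
        for k, v in true.items():
            assert est[k] == pytest.approx(v, rel=1e-3), k
        assert sse["L"] < 1e-8 and sse["W"] < 1e-8

    def test_pure_exponential_gives_vanishing_self_term(self, schedule):
        curves = [cc.normalize_curve(_exponential_curve(r=0.05), schedule)]
        est, _, _ = cc.fit_homotypic(curves, curves, schedule)
        assert abs(est["d"]) < 1e-4
        assert est["r_W1"] == pytest.approx(0.05, rel=1e-3)
        assert est["r_W2"] == pytest.approx(0.05, rel=1e-2)

    def test_noisy_monte_carlo_recovery(self, params, schedule):
        """Median relative error across seeds stays within 10% per parameter."""
        true = dict(r_L1=0.044, r_W1=0.031, r_L2=0.073, r_W2=0.102, a=-0.004, d=-0.008)
        errs = {k: [] for k in true}
        design = cc.ExperimentDesign()
        for seed in range(20):
            noise = cc.NoiseConfig(seed=seed, intensity_sd=0.05, cytometry_n=None,
                                   first_round_inflation=1.0)
            cL = cc.generate_homotypic_timelapse(params, schedule, "L", design, noise)
            cW = cc.generate_homotypic_timelapse(params, schedule, "W", design, noise)
            nL = [cc.normalize_curve(c, schedule) for c in cL]
            nW = [cc.normalize_curve(c, schedule) for c in cW]
            est, _, _ = cc.fit_homotypic(nL, nW, schedule)
            for k, v in true.items():
                errs[k].append(abs(est[k] - v) / abs(v))
        for k in true:
            assert np.median(errs[k]) < 0.10, (k, np.median(errs[k]))


class TestAdjustPhase1:
    def test_equal_rates_leave_proportion_unchanged(self, params, schedule):
        p = params.replace(r_W1=0.04, r_L1=0.04)
        s1, w1 = cc.adjust_phase1(0.5, p, schedule)
        assert (s1, w1) == (pytest.approx(0.0, abs=1e-12), pytest.approx(0.5, abs=1e-12))

    def test_reference_shift(self, params, schedule):
        s1, w1 = cc.adjust_phase1(0.5, params, schedule)
        assert s1 == pytest.approx(-0.585, abs=1e-9)
        assert w1 == pytest.approx(0.3578, abs=2e-4)

    def test_vanishing_phase1_is_identity(self, params):
        sched = cc.PhaseSchedule(t1=1e-9, t2=72.0, t_end=96.0)
        s1, w1 = cc.adjust_phase1(0.3, params, sched)
        assert w1 == pytest.approx(0.3, abs=1e-9)

    def test_printed_variant_uses_phase2_rates(self, params, schedule):
        s1, _ = cc.adjust_phase1(0.5, params, schedule, use_phase2_rates=True)
        assert s1 == pytest.approx(45 * (0.102 - 0.073), abs=1e-12)

    def test_degenerate_proportion_rejected(self, params, schedule):
        with pytest.raises(ValueError):
            cc.adjust_phase1(1.0, params, schedule)


class TestGainPoints:
    def test_end_equal_adjusted_start_gives_zero_gain(self, params, schedule):
        _, w_t1 = cc.adjust_phase1(0.4, params, schedule)
        rec = cc.CompetitionAssayRecord(2, 72.0, 0.4, w_t1, "x")
        (pt,) = cc.compute_gain_points([rec], params, schedule)
        assert pt.gain == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_gain_matches_model_mean_gain(self, params, schedule):
        """Cross-module oracle: assay-derived gain equals the model's phase-2 gain."""
        recs = cc.generate_competition_assays(
            params, schedule, cc.ExperimentDesign(w0_grid=(0.25,), replicates=1, n_rounds=1),
            cc.NoiseConfig.noiseless(),
        )
        (pt,) = cc.compute_gain_points(recs, params, schedule,
                                       exclude_first_round=False)
        _, _, gain = cc.mean_net_growth_rates(params, schedule, 0.25, (45.0, 72.0))
        assert pt.gain == pytest.approx(gain, abs=1e-6)

    def test_first_round_exclusion_flags_only(self, noiseless_bundle, params, schedule):
        _, _, a72, _ = noiseless_bundle
        on = cc.compute_gain_points(a72, params, schedule, exclude_first_round=True)
        off = cc.compute_gain_points(a72, params, schedule, exclude_first_round=False)
        assert all(not p.included for p in on if p.round_index == 1)
        assert all(p.included for p in off)
        for x, y in zip(on, off):
            assert x.gain == y.gain and x.w_t1 == y.w_t1

    def test_degenerate_records_skipped(self, params, schedule):
        recs = [cc.CompetitionAssayRecord(2, 72.0, 1.0, 0.5, "x"),
                cc.CompetitionAssayRecord(2, 72.0, 0.5, 0.6, "y")]
        pts = cc.compute_gain_points(recs, params, schedule)
        assert len(pts) == 1 and pts[0].replicate == "y"


class TestRegressGain:
    @staticmethod
    def _mk(w, g, rnd=2):
        return cc.GainPoint(w_t1=w, s_t1=0.0, gain=g, round_index=rnd,
                            replicate="r", included=True)

    def test_constant_gains_give_zero_slope(self):
        pts = [self._mk(w, 0.05) for w in (0.2, 0.5, 0.8)]
        fit = cc.regress_gain(pts)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.gain_at_1 == pytest.approx(0.05)
        assert fit.gain_at_0 == pytest.approx(0.05)

    def test_exact_line_extrapolates_exactly(self):
        pts = [self._mk(w, 0.02 - 0.05 * w) for w in (0.1, 0.4, 0.6, 0.9)]
        fit = cc.regress_gain(pts)
        assert fit.gain_at_1 == pytest.approx(-0.03, abs=1e-12)
        assert fit.gain_at_0 == pytest.approx(0.02, abs=1e-12)

    def test_identical_abscissae_rejected(self):
        pts = [self._mk(0.5, g) for g in (0.01, 0.02, 0.03)]
        with pytest.raises(ValueError):
            cc.regress_gain(pts)

    def test_noiseless_extrapolations_near_true_limit_gains(self, noiseless_fit, params, schedule):
        """Regression limits approximate the gains along homotypic trajectories.

        The w->1 limit is accurate; the w->0 limit carries the curvature bias
        of a straight-line fit to a convex gain function (about 10% on the
        default seeding grid).
        """
        fit = noiseless_fit.regression
        mean_w = _mean_homotypic_size(params.r_W2, params.d, params.r_W1, schedule)
        mean_l = _mean_homotypic_size(params.r_L2, params.a, params.r_L1, schedule)
        rdiff = params.r_W2 - params.r_L2
        true_at_1 = rdiff + (params.d - params.b) * mean_w
        true_at_0 = rdiff + (params.c - params.a) * mean_l
        assert fit.gain_at_1 == pytest.approx(true_at_1, rel=0.05)
        assert fit.gain_at_0 == pytest.approx(true_at_0, rel=0.15)


class TestInteractionInference:
    def test_infer_b_inverts_the_gain_expansion(self, params, schedule):
        mean_w = _mean_homotypic_size(params.r_W2, params.d, params.r_W1, schedule)
        gain1 = params.r_W2 - params.r_L2 + (params.d - params.b) * mean_w
        fit = RegressionFit(0, gain1, 0, 0, gain_at_1=gain1, gain_at_0=0.0,
                            se_at_1=0, se_at_0=0, nobs=3)
        assert cc.infer_b(fit, params, schedule) == pytest.approx(params.b, abs=1e-12)

    def test_zero_interaction_difference_returns_self_terms(self, params, schedule):
        rdiff = params.r_W2 - params.r_L2
        fit = RegressionFit(0, 0, 0, 0, gain_at_1=rdiff, gain_at_0=rdiff,
                            se_at_1=0, se_at_0=0, nobs=3)
        assert cc.infer_b(fit, params, schedule) == pytest.approx(params.d, abs=1e-12)
        assert cc.infer_c(fit, params, schedule) == pytest.approx(params.a, abs=1e-12)

    def test_symmetric_parameters_give_equal_b_and_c(self, schedule):
        # interchangeable types: swapping L and W flips the sign of the gain,
        # so a mirror-symmetric gain pattern must yield b = c
        p = cc.LVParams(r_L1=0.04, r_W1=0.04, r_L2=0.08, r_W2=0.08, r_W3=0.08,
                        a=-0.006, b=-0.01, c=-0.01, d=-0.006)
        fit = RegressionFit(0, 0, 0, 0, gain_at_1=0.01, gain_at_0=-0.01,
                            se_at_1=0, se_at_0=0, nobs=3)
        b = cc.infer_b(fit, p, schedule)
        c = cc.infer_c(fit, p, schedule)
        assert b == pytest.approx(c, rel=1e-12)


class TestInferRW3:
    def test_recovers_generating_rate_with_true_parameters(self, noiseless_bundle, params, schedule):
        _, _, _, a96 = noiseless_bundle
        r, sse = cc.infer_r_w3(a96, params, schedule)
        assert r == pytest.approx(0.04, abs=1e-4)
        assert sse < 1e-8

    def test_null_case_recovers_phase2_rate(self, params, schedule):
        p = params.replace(r_W3=params.r_W2)
        a96 = cc.generate_competition_assays(
            p, schedule, cc.ExperimentDesign(w0_grid=(0.1, 0.5, 0.9), replicates=1,
                                             round_duration=96.0),
            cc.NoiseConfig.noiseless(),
        )
        r, _ = cc.infer_r_w3(a96, p, schedule)
        assert r == pytest.approx(params.r_W2, abs=1e-4)

    def test_objective_has_local_minimum_at_generating_value(self, noiseless_bundle, params, schedule):
        from clonecomp.inference import infer_r_w3

        _, _, _, a96 = noiseless_bundle
        _, at_true = infer_r_w3(a96, params, schedule, bounds=(0.0399, 0.0401))
        _, below = infer_r_w3(a96, params, schedule, bounds=(0.018, 0.022))
        _, above = infer_r_w3(a96, params, schedule, bounds=(0.058, 0.062))
        assert at_true <= below and at_true <= above


class TestNetGrowthFromCurve:
    def test_exact_exponential_gives_constant_rate(self):
        est = cc.estimate_net_growth_from_curve(_exponential_curve(r=0.05))
        np.testing.assert_allclose(est.rate, 0.05, rtol=1e-9)

    def test_phase1_interior_rate(self, params, schedule):
        (curve, *_) = cc.generate_homotypic_timelapse(
            params, schedule, "W", cc.ExperimentDesign(), cc.NoiseConfig.noiseless()
        )
        est = cc.estimate_net_growth_from_curve(curve)
        interior = est[(est.time_h > 10) & (est.time_h < 40)]
        np.testing.assert_allclose(interior.rate, 0.031, rtol=1e-6)

    def test_agrees_with_model_rates_in_phase_interiors(self, params, schedule):
        (curve, *_) = cc.generate_homotypic_timelapse(
            params, schedule, "W", cc.ExperimentDesign(), cc.NoiseConfig.noiseless()
        )
        est = cc.estimate_net_growth_from_curve(curve)
        tr = cc.simulate(params, schedule, (0.0, 1.0), est.time_h.to_numpy())
        model_rate = np.where(
            tr.t < 45.0, params.r_W1, params.r_W2 + params.d * tr.W
        )
        interior = (np.abs(tr.t - 45.0) > 5.0) & (tr.t < 67.0) & (tr.t > 5.0)
        np.testing.assert_allclose(
            est.rate.to_numpy()[interior], model_rate[interior], rtol=0.02
        )

    def test_span_longer_than_curve_rejected(self):
        with pytest.raises(ValueError):
            cc.estimate_net_growth_from_curve(_exponential_curve(t1=4.0), smoothing_span=5.0)


class TestRunFullInference:
    def test_end_to_end_noiseless_recovery(self, noiseless_fit):
        p = noiseless_fit.params
        assert p.r_L1 == pytest.approx(0.044, rel=0.01)
        assert p.r_W1 == pytest.approx(0.031, rel=0.01)
        assert p.r_L2 == pytest.approx(0.073, rel=0.01)
        assert p.r_W2 == pytest.approx(0.102, rel=0.01)
        assert p.a == pytest.approx(-0.004, rel=0.02)
        assert p.d == pytest.approx(-0.008, rel=0.02)
        assert p.b == pytest.approx(-0.010, rel=0.20)
        assert abs(p.c) <= 0.001
        assert p.r_W3 == pytest.approx(0.04, rel=0.25)

    def test_missing_96h_data_requires_skip_flag(self, noiseless_bundle, schedule):
        curves_L, curves_W, a72, _ = noiseless_bundle
        with pytest.raises(ValueError):
            cc.run_full_inference(curves_L, curves_W, a72, [], schedule)
        res = cc.run_full_inference(
            curves_L, curves_W, a72, [], schedule,
            cc.InferenceOptions(skip_phase3=True),
        )
        assert math.isnan(res.params.r_W3) and not res.params.has_phase3

    def test_record_order_invariance(self, noiseless_bundle, schedule):
        curves_L, curves_W, a72, a96 = noiseless_bundle
        ref = cc.run_full_inference(curves_L, curves_W, a72, a96, schedule)
        sh72, sh96 = list(a72), list(a96)
        random.Random(0).shuffle(sh72)
        random.Random(1).shuffle(sh96)
        shuf = cc.run_full_inference(curves_L, curves_W, sh72, sh96, schedule)
        for k, v in ref.params_dict().items():
            assert shuf.params_dict()[k] == pytest.approx(v, rel=1e-9), k

    def test_summary_reports_parameters(self, noiseless_fit):
        text = noiseless_fit.summary()
        assert "r_W3" in text and "gain regression" in text
        assert "carrying capacity" in text
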