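"""TAC simulation: input function, analytic convolution vs quadrature,
framing, decay and the frame-variance noise model."""

import numpy as np
import pytest
from scipy import integrate

import tspopet as tp
from tspopet import BindingClass as BC
from tspopet._expsum import ExpSum


def _quad_conv(fn, beta, t):
    """Numerical-quadrature oracle for fn (*) exp(-beta s) at time t."""
    val, _ = integrate.quad(lambda s: fn(s) * np.exp(-beta * (t - s)), 0, t,
                            limit=200)
    return val


class TestExpSum:
    def test_eval_matches_definition(self):
        es = ExpSum.from_terms([(2.0, -1.0, -0.3), (0.5, 0.0, -2.0)])
        t = np.array([0.0, 0.7, 3.1])
        expected = (2.0 - 1.0 * t) * np.exp(-0.3 * t) + 0.5 * np.exp(-2.0 * t)
        np.testing.assert_allclose(es(t), expected, rtol=1e-14)

    @pytest.mark.parametrize("beta", [0.01, 0.25, 2.0])
    def test_convolution_matches_quadrature(self, input_fn, beta):
        conv = input_fn.plasma_expsum.convolve_exp(beta)
        for t in (0.5, 5.0, 40.0, 90.0):
            assert conv(np.array(t)) == pytest.approx(
                _quad_conv(input_fn.plasma, beta, t), rel=1e-7)

    def test_frame_means_match_quadrature(self, input_fn, schedule):
        means = input_fn.plasma_expsum.frame_means(schedule.starts, schedule.ends)
        for i in (0, 5, 12, schedule.n_frames - 1):
            val, _ = integrate.quad(input_fn.plasma, schedule.starts[i],
                                    schedule.ends[i], limit=200)
            assert means[i] == pytest.approx(
                val / schedule.durations[i], rel=1e-9)

    def test_convolution_linear_in_input(self, input_fn):
        a = input_fn.plasma_expsum
        b = a.scale(2.5)
        t = np.linspace(0.1, 90, 7)
        np.testing.assert_allclose(
            (a + b).convolve_exp(0.1)(t),
            a.convolve_exp(0.1)(t) + b.convolve_exp(0.1)(t),
            rtol=1e-12,
        )


class TestInputFunction:
    def test_default_shape(self, input_fn):
        t = np.linspace(0, 90, 5401)
        c = input_fn.plasma(t)
        assert c[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(c >= -1e-12)
        peak = int(np.argmax(c))
        assert t[peak] < 2.0
        assert np.all(np.diff(c[peak:]) <= 1e-9)  # monotone decay after peak
        assert c[-1] < 0.01 * c[peak]

    def test_zero_coefficients_zero_curve(self):
        fn = tp.synth_input((0, -4.0, 0, -0.5, 0, -0.05))
        assert np.all(fn.plasma(np.linspace(0, 90, 100)) == 0)

    def test_integral_matches_quadrature(self, input_fn):
        es = input_fn.plasma_expsum
        oracle, _ = integrate.quad(input_fn.plasma, 0, 90, limit=400)
        assert es.antiderivative(np.array(90.0)) == pytest.approx(
            oracle, rel=1e-3 * 0.1)

    def test_negative_parameterization_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tp.synth_input((-800.0, -4.0, 40.0, -0.5, 25.0, -0.05))


class TestFrameSchedule:
    def test_default_covers_90_minutes_contiguously(self, schedule):
        assert schedule.starts[0] == 0.0
        assert schedule.ends[-1] == pytest.approx(90.0)
        np.testing.assert_allclose(schedule.starts[1:], schedule.ends[:-1])

    @pytest.mark.parametrize(
        "starts, ends",
        [([0, 1], [1, 1]),      # zero-duration frame
         ([0, 2], [1, 3]),      # gap
         ([0, 0.5], [1, 1.5])], # overlap
    )
    def test_bad_schedules_rejected(self, starts, ends):
        with pytest.raises(ValueError):
            tp.FrameSchedule(np.array(starts, float), np.array(ends, float))


class TestTissueTacs:
    @pytest.fixture()
    def kp(self, records):
        return tp.predict_kinetics(records["11C-PBR28"])

    def test_zero_k1_zero_vb_is_zero(self, input_fn, schedule):
        kp = tp.KineticParameters(k1=1e-300, k2=0.1, bp_nd={c: 1.0 for c in BC})
        tac = tp.total_tissue_tac(kp, BC.HAB, input_fn, 0.0, schedule,
                                  tp.Isotope.C11)
        np.testing.assert_allclose(tac.values, 0.0, atol=1e-290)

    def test_single_exponential_input_closed_form(self):
        # e^{-lam t} (*) e^{-beta t} = (e^{-lam t} - e^{-beta t})/(beta - lam)
        lam, beta = 0.2, 0.08
        conv = ExpSum.from_terms([(1.0, 0.0, -lam)]).convolve_exp(beta)
        t = np.linspace(0.2, 90, 31)
        closed = (np.exp(-lam * t) - np.exp(-beta * t)) / (beta - lam)
        np.testing.assert_allclose(conv(t), closed, rtol=1e-3 * 0.1)

    def test_infinite_bp_approaches_trapping(self, kp, input_fn, schedule):
        huge = tp.KineticParameters(k1=kp.k1, k2=kp.k2,
                                    bp_nd={c: 1e12 for c in BC})
        tac = tp.total_tissue_tac(huge, BC.HAB, input_fn, 0.0, schedule,
                                  tp.Isotope.C11)
        # trapping limit: K1 * int_0^t C_P; oracle = exact frame means of it
        from scipy.integrate import quad

        def cum(t):
            return float(input_fn.plasma_expsum.antiderivative(np.array(t)))

        for i in (3, 10, 15, schedule.n_frames - 1):
            s, e = schedule.starts[i], schedule.ends[i]
            oracle = kp.k1 * quad(cum, s, e, limit=200)[0] / (e - s)
            assert tac.values[i] == pytest.approx(oracle, rel=1e-6)

    def test_nd_equals_total_at_zero_bp(self, kp, input_fn, schedule):
        zero = tp.KineticParameters(k1=kp.k1, k2=kp.k2,
                                    bp_nd={c: 0.0 for c in BC})
        total = tp.total_tissue_tac(zero, BC.MAB, input_fn, 0.05, schedule,
                                    tp.Isotope.C11)
        nd = tp.nd_tissue_tac(kp, input_fn, 0.05, schedule, tp.Isotope.C11)
        np.testing.assert_allclose(total.values, nd.values, rtol=1e-12)

    def test_nd_below_total_for_positive_bp(self, kp, input_fn, schedule):
        total = tp.total_tissue_tac(kp, BC.HAB, input_fn, 0.05, schedule,
                                    tp.Isotope.C11)
        nd = tp.nd_tissue_tac(kp, input_fn, 0.05, schedule, tp.Isotope.C11)
        assert np.all(total.values >= nd.values - 1e-12)

    def test_pure_blood_signal(self, input_fn, schedule):
        kp = tp.KineticParameters(k1=1e-300, k2=0.1, bp_nd={c: 0.0 for c in BC})
        nd = tp.nd_tissue_tac(kp, input_fn, 0.05, schedule, tp.Isotope.C11)
        blood = input_fn.blood_expsum.frame_means(schedule.starts, schedule.ends)
        np.testing.assert_allclose(nd.values, 0.05 * blood, rtol=1e-12)

    def test_frame_means_converge_to_pointwise(self, kp, input_fn):
        """Frame averages approach the continuous model as frames shrink."""
        conv = input_fn.plasma_expsum.convolve_exp(
            kp.k2 / (1 + kp.bp_nd[BC.HAB])).scale(0.95 * kp.k1)

        def max_rel_err(dt):
            sched = tp.FrameSchedule.from_durations([dt] * int(1.0 / dt))
            tac = tp.total_tissue_tac(kp, BC.HAB, input_fn, 0.05, sched,
                                      tp.Isotope.C11)
            pointwise = conv(sched.midpoints) + 0.05 * input_fn.whole_blood(
                sched.midpoints)
            return np.max(np.abs(tac.values - pointwise) / np.abs(pointwise))

        coarse, fine = max_rel_err(0.05), max_rel_err(0.0125)
        assert fine < coarse / 2  # shrinking frames tighten the agreement


class TestDecay:
    def test_one_half_life_factor(self, input_fn):
        sched = tp.FrameSchedule(np.array([20.4 - 1.0]), np.array([20.4 + 1.0]))
        tac = tp.TimeActivityCurve(sched, np.array([10.0]), tp.Isotope.C11)
        raw = tp.apply_decay(tac, "uncorrect")
        assert raw.values[0] == pytest.approx(5.0)
        sched_f = tp.FrameSchedule(np.array([109.77 - 1]), np.array([109.77 + 1]))
        tac_f = tp.TimeActivityCurve(sched_f, np.array([10.0]), tp.Isotope.F18)
        assert tp.apply_decay(tac_f, "uncorrect").values[0] == pytest.approx(5.0)

    def test_roundtrip_identity(self, schedule, rng):
        values = rng.uniform(0, 50, schedule.n_frames)
        tac = tp.TimeActivityCurve(schedule, values, tp.Isotope.F18)
        back = tp.apply_decay(tp.apply_decay(tac, "uncorrect"), "correct")
        np.testing.assert_allclose(back.values, values, rtol=1e-14)
        assert back.decay_corrected

    def test_direction_contract(self, schedule):
        tac = tp.TimeActivityCurve(schedule, np.ones(schedule.n_frames),
                                   tp.Isotope.C11)
        with pytest.raises(ValueError):
            tp.apply_decay(tac, "correct")  # already corrected
        with pytest.raises(ValueError):
            tp.apply_decay(tac, "sideways")

    def test_f18_decays_slower(self, records, input_fn, schedule):
        """Same kinetics: F18 raw late frames are relatively higher than C11."""
        kp = tp.predict_kinetics(records["11C-PBR28"])
        tac = tp.total_tissue_tac(kp, BC.HAB, input_fn, 0.05, schedule,
                                  tp.Isotope.C11)
        c11 = tp.apply_decay(tac, "uncorrect").values
        f18 = tp.apply_decay(
            tp.TimeActivityCurve(schedule, tac.values, tp.Isotope.F18),
            "uncorrect").values
        ratio = f18 / c11
        assert np.all(np.diff(ratio) > 0)  # grows with frame time


class TestNoise:
    @pytest.fixture()
    def raw_tac(self, records, input_fn, schedule):
        kp = tp.predict_kinetics(records["11C-PBR28"])
        tac = tp.total_tissue_tac(kp, BC.HAB, input_fn, 0.05, schedule,
                                  tp.Isotope.C11)
        return tp.apply_decay(tac, "uncorrect")

    def test_zero_scale_is_identity(self, raw_tac, rng):
        out = tp.add_noise(raw_tac, tp.NoiseModel(0.0), rng)
        np.testing.assert_array_equal(out.values, raw_tac.values)

    def test_fixed_seed_bit_identical(self, raw_tac):
        a = tp.add_noise(raw_tac, tp.NoiseModel(0.3), 77)
        b = tp.add_noise(raw_tac, tp.NoiseModel(0.3), 77)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_variance_matches_rule(self, raw_tac, rng):
        """10k realizations: per-frame variance within 5% of
        scale^2 * activity / duration."""
        model = tp.NoiseModel(0.4)
        draws = np.array([
            tp.add_noise(raw_tac, model, rng).values for _ in range(10_000)
        ])
        emp = draws.var(axis=0, ddof=1)
        expected = model.scale**2 * raw_tac.values / raw_tac.schedule.durations
        # skip the earliest frames where activity ~ 0
        sel = expected > 1e-6
        np.testing.assert_allclose(emp[sel], expected[sel], rtol=0.05)

    def test_rejects_decay_corrected_input(self, raw_tac, rng):
        corrected = tp.apply_decay(raw_tac, "correct")
        with pytest.raises(ValueError, match="non-decay-corrected"):
            tp.add_noise(corrected, tp.NoiseModel(0.1), rng)
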