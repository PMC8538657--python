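"""Pharmacokinetic core: closed-form oracles, inversion identities, bounded fits."""

import numpy as np
import pytest

from renodce import pk
from renodce.dataio import AIFCurve
from renodce.errors import (
    DomainError,
    EmptyRegionError,
    NoEnhancementError,
    ParameterError,
)
from renodce.pk import (
    ConcentrationCurve,
    PKParams,
    compute_gfr,
    concentration_to_signal,
    convolve_aif,
    fit_2cfm,
    forward_2cfm,
    mean_cortex_curve,
    signal_to_concentration,
    virf,
)

TIMES = np.arange(0, 170, 2.3)


class TestVirf:
    def test_zero_before_delay(self):
        t = np.linspace(0, 1.9, 50)
        assert np.all(virf(t, tg_s=5.0, delay_s=2.0) == 0.0)

    def test_value_at_delay(self):
        assert virf(np.array([2.0]), tg_s=5.0, delay_s=2.0)[0] == pytest.approx(1 / 5.0)

    def test_unit_integral(self):
        # dense trapezoid over [delta, delta + 50*Tg]
        tg, delta = 3.0, 2.0
        t = np.linspace(delta, delta + 50 * tg, 400_000)
        integral = np.trapezoid(virf(t, tg, delta), t)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_tg_rejected(self):
        with pytest.raises(DomainError):
            virf(TIMES, tg_s=0.0, delay_s=1.0)


class TestConvolveAif:
    def test_step_response_closed_form(self):
        """Unit step through the VIRF gives 1 - exp(-t/Tg) exactly."""
        aif = AIFCurve(TIMES, np.ones_like(TIMES))
        out = convolve_aif(aif, tg_s=5.0, delay_s=0.0)
        assert np.max(np.abs(out.concentration - (1 - np.exp(-TIMES / 5.0)))) < 1e-3

    def test_zero_aif_maps_to_zero(self):
        aif = AIFCurve(TIMES, np.zeros_like(TIMES))
        out = convolve_aif(aif, tg_s=5.0, delay_s=2.0)
        assert np.all(out.concentration == 0.0)

    def test_output_lags_by_delay(self):
        conc = np.zeros_like(TIMES)
        conc[10:] = 1.0
        aif = AIFCurve(TIMES, conc)
        out = convolve_aif(aif, tg_s=1.0, delay_s=3.0)
        # the coarse step is linearly interpolated, so the delayed input first
        # becomes nonzero at (previous sample time + delay)
        first_nonzero = TIMES[9] + 3.0
        assert np.all(out.concentration[TIMES < first_nonzero] < 1e-9)

    def test_area_conservation(self):
        """The kernel has unit mass, so the full response preserves area."""
        conc = np.exp(-0.5 * ((TIMES - 30) / 5.0) ** 2)  # bolus well inside window
        aif = AIFCurve(TIMES, conc)
        out = convolve_aif(aif, tg_s=2.0, delay_s=1.0)
        a_in = np.trapezoid(conc, TIMES)
        a_out = np.trapezoid(out.concentration, TIMES)
        assert a_out == pytest.approx(a_in, rel=5e-3)


class TestForward2CFM:
    def test_zero_aif(self):
        aif = AIFCurve(TIMES, np.zeros_like(TIMES))
        out = forward_2cfm(PKParams(0.2, 0.4, 1.5, 5.0), aif)
        assert np.all(out.concentration == 0.0)

    def test_constant_aif_closed_form(self):
        """Constant AIF c0, delta=0: analytic integral of the exponential step."""
        c0, tg, ktrans, vp = 2.0, 5.0, 0.2, 0.4
        aif = AIFCurve(TIMES, np.full_like(TIMES, c0))
        out = forward_2cfm(PKParams(ktrans, vp, 0.0, tg), aif)
        expected = (ktrans / 60.0) * c0 * (TIMES - tg * (1 - np.exp(-TIMES / tg))) + vp * c0 * (
            1 - np.exp(-TIMES / tg)
        )
        rel = np.abs(out.concentration[1:] - expected[1:]) / np.abs(expected[1:])
        assert rel.max() < 1e-3

    def test_linearity_in_ktrans(self):
        """Doubling Ktrans (vp fixed) doubles the late-time slope."""
        aif = AIFCurve(TIMES, np.full_like(TIMES, 1.0))
        lo = forward_2cfm(PKParams(0.1, 0.2, 0.0, 2.0), aif).concentration
        hi = forward_2cfm(PKParams(0.2, 0.2, 0.0, 2.0), aif).concentration
        slope = lambda c: (c[-1] - c[-10]) / (TIMES[-1] - TIMES[-10])
        assert slope(hi) == pytest.approx(2 * slope(lo), rel=1e-6)

    def test_unit_audit_seconds_vs_minutes(self):
        """Computing the constant-AIF closed form in minutes leaves Ktrans [1/min] invariant."""
        c0, tg_s, ktrans, vp = 1.5, 6.0, 0.3, 0.5
        aif = AIFCurve(TIMES, np.full_like(TIMES, c0))
        ours = forward_2cfm(PKParams(ktrans, vp, 0.0, tg_s), aif).concentration
        t_min = TIMES / 60.0
        tg_min = tg_s / 60.0
        closed_min = ktrans * c0 * (t_min - tg_min * (1 - np.exp(-t_min / tg_min))) + vp * c0 * (
            1 - np.exp(-t_min / tg_min)
        )
        assert np.max(np.abs(ours[1:] - closed_min[1:]) / np.abs(closed_min[1:])) < 1e-3


class TestSignalConcentrationConversion:
    def test_zero_concentration_gives_baseline(self):
        sig = concentration_to_signal(np.zeros(20), s0=123.0, t10_s=0.966)
        assert np.allclose(sig, 123.0)

    def test_round_trip_identity(self):
        conc = np.linspace(0.0, 5.0, 80)
        conc[:8] = 0.0
        sig = concentration_to_signal(conc, s0=100.0, t10_s=0.966)
        back = signal_to_concentration(sig, np.arange(80.0), 8, t10_s=0.966)
        assert np.max(np.abs(back.concentration - conc)) < 1e-9
        assert not back.clipped

    def test_monotone_in_concentration(self):
        conc = np.linspace(0, 3, 200)
        sig = concentration_to_signal(conc, s0=100.0, t10_s=1.0)
        assert np.all(np.diff(sig) > 0)

    def test_small_signal_linearity(self):
        """In the low-concentration regime doubling (S - S0) ~ doubles conc."""
        base = np.full(8, 100.0)
        s1 = np.concatenate([base, [100.5]])
        s2 = np.concatenate([base, [101.0]])
        t = np.arange(9.0)
        c1 = signal_to_concentration(s1, t, 8, t10_s=0.966).concentration[-1]
        c2 = signal_to_concentration(s2, t, 8, t10_s=0.966).concentration[-1]
        assert c2 == pytest.approx(2 * c1, rel=0.05)

    def test_baseline_signal_gives_zero_concentration(self):
        sig = np.full(30, 77.0)
        out = signal_to_concentration(sig, np.arange(30.0), 8, t10_s=1.4)
        assert np.allclose(out.concentration, 0.0, atol=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            concentration_to_signal(np.array([-0.1]), s0=100.0, t10_s=1.0)

    def test_saturated_signal_clipped_with_flag(self):
        sig = np.concatenate([np.full(8, 100.0), [1e4]])
        with pytest.warns(UserWarning):
            out = signal_to_concentration(sig, np.arange(9.0), 8, t10_s=1.0)
        assert out.clipped


@pytest.fixture(scope="module")
def aif():
    from renodce.phantom import AIFParams, population_aif

    t = np.arange(74) * 2.3
    return population_aif(t, AIFParams(bolus_arrival_s=18.4))


class TestFit2CFM:

    def test_noiseless_recovery(self, aif):
        true = PKParams(0.2, 0.4, 2.0, 5.0)
        measured = forward_2cfm(true, aif)
        fit = fit_2cfm(measured, aif, n_baseline=8)
        est, ref = fit.params.as_array(), true.as_array()
        assert np.all(np.abs(est - ref) / ref < 0.01)
        assert fit.converged

    def test_estimate_within_bounds_under_noise(self, aif):
        rng = np.random.default_rng(5)
        true = PKParams(0.38, 0.85, 3.2, 2.0)  # near upper corner
        clean = forward_2cfm(true, aif).concentration
        noisy = ConcentrationCurve(aif.times, clean + rng.normal(0, 0.1, clean.shape))
        fit = fit_2cfm(noisy, aif, n_baseline=8)
        assert fit.params.within_bounds()

    def test_rss_not_worse_than_any_start(self, aif):
        true = PKParams(0.1, 0.3, 1.2, 8.0)
        measured = forward_2cfm(true, aif)
        fit = fit_2cfm(measured, aif, n_baseline=8)
        assert fit.rss <= min(fit.start_rss) + 1e-12

    def test_all_zero_curve_rejected(self, aif):
        flat = ConcentrationCurve(aif.times, np.zeros_like(aif.times))
        with pytest.raises(NoEnhancementError):
            fit_2cfm(flat, aif, n_baseline=8)

    def test_too_few_samples_rejected(self, aif):
        short = ConcentrationCurve(aif.times[:12], np.ones(12))
        with pytest.raises(ParameterError):
            fit_2cfm(short, aif, n_baseline=8)


class TestRegionCurvesAndGFR:
    def test_mean_cortex_curve_single_and_identical_voxels(self, small_phantom):
        ph = small_phantom
        curve = mean_cortex_curve(ph.series, ph.labels)
        one_voxel = ph.series.data[ph.labels.data == 1][0]
        # homogeneous noiseless cortex: mean equals any single voxel
        assert np.allclose(curve, one_voxel)

    def test_mean_cortex_curve_empty_region(self, small_phantom):
        from renodce.dataio import CompartmentLabelMap

        empty = CompartmentLabelMap(np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(EmptyRegionError):
            mean_cortex_curve(small_phantom.series, empty)

    def test_gfr_arithmetic(self):
        """Ktrans 0.2/min over 300 mL of cortex filters 60 mL/min."""
        from renodce.dataio import CompartmentLabelMap

        labels = CompartmentLabelMap(np.ones((10, 10, 3), dtype=np.uint8))  # 300 voxels
        out = compute_gfr(0.2, labels, voxel_volume_ml=1.0)
        assert out.gfr_ml_min == pytest.approx(60.0)
        assert out.cortex_volume_ml == pytest.approx(300.0)

    def test_bsa_reference_identity(self):
        from renodce.dataio import CompartmentLabelMap

        labels = CompartmentLabelMap(np.ones((5, 5, 2), dtype=np.uint8))
        out = compute_gfr(0.3, labels, 1.0, body_surface_area_m2=1.73)
        assert out.gfr_ml_min_173 == pytest.approx(out.gfr_ml_min)

    def test_zero_cortex_rejected(self):
        from renodce.dataio import CompartmentLabelMap

        labels = CompartmentLabelMap(np.full((4, 4, 2), 2, dtype=np.uint8))
        with pytest.raises(EmptyRegionError):
            compute_gfr(0.2, labels, 1.0)

    def test_aif_from_roi_recovers_generating_aif(self, small_phantom):
        ph = small_phantom
        rec = pk.aif_from_roi(ph.series, ph.aorta_mask, t10_blood_s=ph.config.t10_s["blood"])
        assert np.max(np.abs(rec.concentration - ph.aif.concentration)) < 1e-9

    def test_aif_from_roi_empty_mask(self, small_phantom):
        with pytest.raises(EmptyRegionError):
            pk.aif_from_roi(small_phantom.series, np.zeros(small_phantom.series.shape[:3], bool))
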