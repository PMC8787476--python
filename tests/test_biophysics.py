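"""SEC calibration, MW/oligomer inference, MRE conversion and melt fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sixhelix import biophysics as bp
from sixhelix import synthetic_data as sd


class TestKav:
    @pytest.mark.parametrize("ve,vo,vc,kav", [(8, 8, 24, 0.0), (24, 8, 24, 1.0),
                                              (16, 8, 24, 0.5)])
    def test_values(self, ve, vo, vc, kav):
        assert bp.compute_kav(ve, vo, vc) == kav

    def test_errors(self):
        with pytest.raises(ValueError):
            bp.compute_kav(10, 24, 8)
        with pytest.raises(ValueError):
            bp.compute_kav(5, 8, 24)


class TestCalibration:
    def test_exact_line_recovered(self):
        stds = sd.make_sec_standards()
        cal = bp.fit_calibration(stds, sd.VOID_VOLUME_ML, sd.COLUMN_VOLUME_ML)
        assert cal.slope == pytest.approx(-0.33, abs=1e-12)
        assert cal.intercept == pytest.approx(1.68, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_degrades_r2_but_not_slope(self):
        slopes = []
        for seed in range(20):
            stds = sd.make_sec_standards(noise=0.01, seed=seed)
            cal = bp.fit_calibration(stds, 8.0, 24.0)
            assert cal.r_squared < 1.0
            slopes.append(cal.slope)
        assert abs(np.mean(slopes) - (-0.33)) / 0.33 < 0.05

    def test_too_few_standards(self):
        stds = sd.make_sec_standards()[:2]
        with pytest.raises(ValueError):
            bp.fit_calibration(stds, 8.0, 24.0)


class TestMwEstimate:
    @pytest.fixture
    def cal(self):
        return bp.SecCalibration(slope=-0.33, intercept=1.68, r_squared=1.0,
                                 vo=8.0, vc=24.0)

    def test_kav_at_intercept_gives_unit_mass(self, cal):
        assert bp.estimate_mw(1.68, cal) == pytest.approx(1.0)

    def test_kilodalton_point(self, cal):
        assert bp.estimate_mw(0.69, cal) == pytest.approx(1000.0)

    @given(st.floats(min_value=3.0, max_value=6.0))
    def test_forward_inverse_roundtrip(self, logmw):
        cal = bp.SecCalibration(slope=-0.33, intercept=1.68, r_squared=1.0,
                                vo=8.0, vc=24.0)
        mw = 10.0 ** logmw
        kav = cal.intercept + cal.slope * np.log10(mw)
        assert bp.estimate_mw(kav, cal) == pytest.approx(mw, rel=1e-9)

    @pytest.mark.parametrize("apparent,n", [(43000, 3), (13300, 1), (26600, 2)])
    def test_oligomer(self, apparent, n):
        assert bp.infer_oligomer(apparent, 13300)[0] == n


class TestMre:
    def test_zero_theta(self):
        assert bp.mre_convert(0.0, 2000, 21, 0.1, 1.0) == 0.0

    def test_worked_value(self):
        assert bp.mre_convert(5.0, 2000, 21, 0.1, 1.0) == pytest.approx(500.0)

    def test_linear_in_theta_and_inverse_conc(self):
        base = bp.mre_convert(5.0, 2000, 21, 0.1, 0.2)
        assert bp.mre_convert(10.0, 2000, 21, 0.1, 0.2) == pytest.approx(2 * base)
        assert bp.mre_convert(5.0, 2000, 21, 0.1, 0.4) == pytest.approx(base / 2)

    def test_paper_conditions_accepted(self):
        assert np.isfinite(bp.mre_convert(-8.0, 11500, 96, 0.1, 0.2))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bp.mre_convert(1.0, 2000, 1, 0.1, 1.0)
        with pytest.raises(ValueError):
            bp.mre_convert(1.0, 2000, 21, 0.0, 1.0)


class TestNormalize:
    def test_affine_map(self):
        curve = bp.MeltCurve(np.arange(15, 96, 5.0), np.linspace(-10, -2, 17))
        norm = bp.normalize_melt(curve)
        # baseline-averaged map: endpoints within half a grid step of 0/1
        assert norm.signal[0] == pytest.approx(0.0, abs=0.05)
        assert norm.signal[-1] == pytest.approx(1.0, abs=0.05)
        assert np.all(np.diff(norm.signal) > 0)

    def test_constant_signal_error(self):
        curve = bp.MeltCurve(np.arange(15, 96, 5.0), np.full(17, -5.0))
        with pytest.raises(ValueError):
            bp.normalize_melt(curve)

    def test_idempotent(self):
        curve = sd.make_melt([70.0])
        once = bp.normalize_melt(curve)
        twice = bp.normalize_melt(once)
        assert np.allclose(once.signal, twice.signal)

    def test_decreasing_raw_signal_flipped(self):
        curve = sd.make_melt([70.0])
        flipped = bp.MeltCurve(curve.temperatures, -curve.signal)
        norm = bp.normalize_melt(flipped)
        assert norm.signal[0] < 0.2 and norm.signal[-1] > 0.8


class TestFitMelt:
    def test_single_phase_recovery(self):
        for seed in range(5):
            curve = sd.make_melt([78.0], noise=0.02, seed=seed)
            fit = bp.fit_melt(bp.normalize_melt(curve), phases=2)
            tm = fit.tm[int(np.argmax(fit.amplitudes))]
            assert abs(tm - 78.0) <= 0.5

    def test_biphasic_recovery(self):
        curve = sd.make_melt([50.0, 80.0], amplitudes=[0.4, 0.6],
                             noise=0.01, seed=8)
        fit = bp.fit_melt(bp.normalize_melt(curve), phases=2)
        assert fit.n_phases == 2
        assert fit.tm[0] == pytest.approx(50.0, abs=1.0)
        assert fit.tm[1] == pytest.approx(80.0, abs=1.0)
        assert sum(fit.amplitudes) == pytest.approx(1.0)

    def test_single_phase_data_reduces(self):
        curve = sd.make_melt([78.0], noise=0.02, seed=2)
        fit = bp.fit_melt(bp.normalize_melt(curve), phases=2)
        assert fit.n_phases == 1

    def test_flat_curve_error(self):
        flat = bp.MeltCurve(np.arange(15, 96, 5.0), np.full(17, 0.5))
        with pytest.raises(ValueError):
            bp.fit_melt(flat)

    def test_too_few_points(self):
        curve = bp.MeltCurve(np.linspace(15, 95, 6), np.linspace(0, 1, 6))
        with pytest.raises(ValueError):
            bp.fit_melt(curve)


class TestTmVsPh:
    def _fits(self, tms, phs, seed0=0):
        fits = []
        for i, (tm, ph) in enumerate(zip(tms, phs)):
            curve = sd.make_melt([tm], noise=0.02, seed=seed0 + i, ph=ph)
            fits.append(bp.fit_melt(bp.normalize_melt(curve), phases=1))
        return fits

    def test_flat_tm_spread_near_zero(self):
        phs = list(np.arange(4.5, 8.0, 0.5))
        table = bp.tm_vs_ph(self._fits([78.0] * 7, phs))
        assert table.attrs["tm_spread"] < 1.5

    def test_monotone_tm_in_ph(self):
        phs = [5.0, 6.0, 7.0]
        table = bp.tm_vs_ph(self._fits([60.0, 70.0, 80.0], phs, seed0=30))
        assert table["tm"].is_monotonic_increasing

    def test_single_ph_errors(self):
        with pytest.raises(ValueError):
            bp.tm_vs_ph(self._fits([78.0], [7.0]))
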