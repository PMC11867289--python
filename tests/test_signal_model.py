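"""Signal conversion, AIF shifting and the tracer-kinetic forward model."""

import numpy as np
import pytest
from scipy.integrate import quad

import dscbezier as dz


def make_signal(values, dt=1.65, baseline=4):
    values = np.asarray(values, dtype=float)
    return dz.SignalTimeSeries(np.arange(values.size) * dt, values, baseline_count=baseline)


class TestSignalToConcentration:
    def test_constant_signal_gives_zero(self, acq):
        sig = make_signal(np.full(20, 123.0), baseline=5)
        conc = dz.signal_to_concentration(sig, acq)
        np.testing.assert_allclose(conc.values, 0.0, atol=1e-14)
        np.testing.assert_array_equal(conc.times, sig.times)

    def test_log_identity(self):
        # te * r2star = 1 and S = S0/e  ->  C = 1 exactly
        acq = dz.AcquisitionConfig(te=1.0, r2star=1.0, n_frames=10, n_baseline=4)
        vals = np.full(10, 50.0)
        vals[4:] = 50.0 * np.exp(-1.0)
        conc = dz.signal_to_concentration(make_signal(vals), acq)
        np.testing.assert_allclose(conc.values[4:], 1.0, rtol=1e-14)

    def test_hand_computed_value(self):
        # S0=100, S=70, te=0.054 s, r2star=87: C = -ln(0.70)/(0.054*87)
        acq = dz.AcquisitionConfig(te=0.054, r2star=87.0, n_frames=10, n_baseline=4)
        vals = np.full(10, 100.0)
        vals[4:] = 70.0
        conc = dz.signal_to_concentration(make_signal(vals), acq)
        np.testing.assert_allclose(conc.values[4:], 0.0759205925795514, rtol=1e-12)

    def test_nonpositive_signal_names_frame(self):
        vals = np.full(10, 100.0)
        vals[7] = -1.0
        with pytest.raises(ValueError, match="frame 7"):
            make_signal(vals)

    def test_roundtrip_with_inverse(self, acq, rng):
        conc = dz.ConcentrationTimeSeries(acq.times, rng.uniform(0, 5, acq.n_frames))
        sig = dz.concentration_to_signal(conc, acq, s0=250.0)
        back = dz.signal_to_concentration(sig, acq)
        # baseline frames of conc are nonzero here, so S0 != 250; rebuild with
        # zero baseline for an exact round trip
        conc0 = dz.ConcentrationTimeSeries(acq.times, np.where(np.arange(acq.n_frames) < acq.n_baseline, 0.0, conc.values))
        sig0 = dz.concentration_to_signal(conc0, acq, s0=250.0)
        back0 = dz.signal_to_concentration(sig0, acq)
        np.testing.assert_allclose(back0.values, conc0.values, atol=1e-12)


class TestShiftAif:
    def test_zero_delay_is_identity(self, aif):
        out = dz.shift_aif(aif, 0.0)
        np.testing.assert_array_equal(out.values, aif.values)

    def test_whole_frame_shift(self, aif, acq):
        out = dz.shift_aif(aif, acq.dt)
        assert out.values[0] == 0.0
        np.testing.assert_allclose(out.values[1:], aif.values[:-1], rtol=1e-12)

    def test_half_frame_shift_on_triangle(self):
        t = np.arange(8) * 1.0
        vals = np.array([0, 0, 1, 2, 1, 0, 0, 0], dtype=float)
        aif = dz.ConcentrationTimeSeries(t, vals, role="arterial")
        out = dz.shift_aif(aif, 0.5)
        expected = np.concatenate([[vals[0] / 2], (vals[1:] + vals[:-1]) / 2])
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)
        # dense-grid interpolation oracle
        dense_t = np.linspace(0, 7, 7001)
        dense = np.interp(dense_t, t, vals)
        oracle = np.interp(t - 0.5, dense_t, dense, left=0.0)
        np.testing.assert_allclose(out.values, oracle, atol=1e-9)

    def test_negative_delay_rejected(self, aif):
        with pytest.raises(ValueError):
            dz.shift_aif(aif, -0.1)


class TestForwardModel:
    def test_zero_cbf_gives_zero(self, aif, acq, truth_residue):
        out = dz.forward_model(truth_residue, 0.0, 0.5, aif, acq)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_impulse_aif_returns_residue(self, acq):
        vals = np.zeros(acq.n_frames)
        vals[0] = 1.0 / acq.dt
        impulse = dz.ConcentrationTimeSeries(acq.times, vals, role="arterial")
        residue = dz.BezierResidue.linear(6.0)
        out = dz.forward_model(residue, 2.0, 0.0, impulse, acq)
        np.testing.assert_allclose(out.values, 2.0 * residue.evaluate(acq.times), rtol=1e-12)

    def test_boxcar_residue_exponential_aif_closed_form(self):
        # R boxcar of width T convolved with A*exp(-t/b): the integral of the
        # exponential over a sliding window, known in closed form
        dt = 0.02
        n = 4000
        t = np.arange(n) * dt
        acq = dz.AcquisitionConfig(dt=dt, n_frames=n, n_baseline=1)
        A, bscale, T = 3.0, 2.0, 4.0
        aif = dz.ConcentrationTimeSeries(t, A * np.exp(-t / bscale), role="arterial")
        grid = np.arange(0.0, 80.0 + dt / 2, dt / 4)
        residue = dz.GriddedResidue(grid, np.where(grid < T, 1.0, 0.0))
        out = dz.forward_model(residue, 1.0, 0.0, aif, acq)
        exact = A * bscale * (1 - np.exp(-np.minimum(t, T) / bscale)) * np.exp(-np.maximum(t - T, 0) / bscale)
        assert np.max(np.abs(out.values - exact)) < 0.05 * np.max(exact)

    def test_linear_in_cbf_and_aif(self, aif, acq, truth_residue):
        base = dz.forward_model(truth_residue, 0.05, 0.5, aif, acq)
        double_cbf = dz.forward_model(truth_residue, 0.10, 0.5, aif, acq)
        np.testing.assert_allclose(double_cbf.values, 2 * base.values, rtol=1e-12)
        aif2 = dz.ConcentrationTimeSeries(aif.times, 3.0 * aif.values, role="arterial")
        scaled_aif = dz.forward_model(truth_residue, 0.05, 0.5, aif2, acq)
        np.testing.assert_allclose(scaled_aif.values, 3 * base.values, rtol=1e-12)

    def test_discretization_converges_first_order(self):
        # rectangle-rule convolution vs adaptive quadrature of the continuous
        # convolution, on two grid refinements
        residue = dz.BezierResidue.linear(5.0)

        def ca(t):
            return np.where(t > 0, t**2 * np.exp(-t / 1.5), 0.0)

        def exact_at(tq):
            val, _ = quad(lambda u: residue.evaluate(u)[0] * ca(tq - u), 0.0, min(5.0, tq), limit=200)
            return val

        errs = []
        for dt in (0.4, 0.2):
            n = int(30 / dt)
            t = np.arange(n) * dt
            acq = dz.AcquisitionConfig(dt=dt, n_frames=n, n_baseline=1)
            aif = dz.ConcentrationTimeSeries(t, ca(t), role="arterial")
            out = dz.forward_model(residue, 1.0, 0.0, aif, acq)
            probes = [10.0, 15.0, 20.0]
            idx = [int(round(p / dt)) for p in probes]
            errs.append(max(abs(out.values[i] - exact_at(t[i])) for i in idx))
        assert errs[1] < 0.65 * errs[0]  # ~first order in dt


class TestIO:
    def test_csv_roundtrip(self, aif, tmp_path):
        path = tmp_path / "aif.csv"
        dz.write_timeseries_csv(aif, path)
        back = dz.read_timeseries_csv(path, role="arterial")
        np.testing.assert_allclose(back.values, aif.values, rtol=1e-12)
        np.testing.assert_allclose(back.times, aif.times, rtol=1e-12)

    def test_acquisition_from_yaml(self, tmp_path):
        path = tmp_path / "acq.yaml"
        path.write_text(
            "acquisition:\n  te_s: 0.054\n  dt_s: 1.65\n  n_frames: 46\n"
            "  n_baseline: 11\n  r2star: 1.0\n  k_h: 0.73\n"
        )
        acq = dz.AcquisitionConfig.from_yaml(path)
        assert acq.k_h == 0.73
        assert acq.n_frames == 46

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            dz.AcquisitionConfig(n_baseline=0)
        with pytest.raises(ValueError):
            dz.AcquisitionConfig(n_baseline=46, n_frames=46)
        with pytest.raises(ValueError):
            dz.AcquisitionConfig(te=-1)
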