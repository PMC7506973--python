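import dataclasses

import numpy as np
import pytest

from scrkit.deconv import (
    convolve_driver,
    count_bursts_by_segment,
    deconvolve,
    detect_bursts,
    extract_scr_driver,
    make_kernel,
    phasic_residue,
    scr_atom,
    split_tonic_phasic,
)
from scrkit.io import EDASignal
from scrkit.preprocess import preprocess
from scrkit.synth import SyntheticConfig, render_bumps, simulate_session


@pytest.fixture(scope="module")
def irf():
    return make_kernel(tau_rise=0.75, tau_decay=2.0, fs=8.0)


class TestKernel:
    def test_peak_time_matches_closed_form(self, irf):
        # argmax of exp(-t/td) - exp(-t/tr) is ln(td/tr) tr td / (td - tr)
        expected = np.log(2.0 / 0.75) * 0.75 * 2.0 / (2.0 - 0.75)
        assert expected == pytest.approx(1.18, abs=0.01)
        k = irf.kernel
        assert abs(np.argmax(k) / irf.fs - expected) <= 1.0 / irf.fs

    def test_unit_area(self, irf):
        assert irf.kernel.sum() / irf.fs == pytest.approx(1.0, abs=1e-9)

    def test_starts_at_zero_and_nonnegative(self, irf):
        assert irf.kernel[0] == 0.0
        assert irf.kernel.min() >= 0.0

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            make_kernel(tau_rise=2.0, tau_decay=0.75, fs=8.0)


class TestConvolve:
    def test_zero_driver(self, irf):
        assert np.all(convolve_driver(np.zeros(100), irf) == 0.0)

    def test_impulse_reproduces_kernel(self, irf):
        d = np.zeros(400)
        d[50] = 8.0  # unit area at fs = 8: one sample of height fs
        out = convolve_driver(d, irf)
        np.testing.assert_allclose(out[50 : 50 + 150], irf.kernel[:150], atol=1e-12)

    def test_superposition(self, irf):
        fs = 8.0
        d1, d2 = np.zeros(800), np.zeros(800)
        d1[100], d2[100 + int(5 * fs)] = 3.0, 2.0
        both = convolve_driver(d1 + d2, irf)
        np.testing.assert_allclose(
            both, convolve_driver(d1, irf) + convolve_driver(d2, irf), atol=1e-10
        )

    def test_constant_driver_steady_state(self, irf):
        out = convolve_driver(np.full(400, 3.0), irf)
        np.testing.assert_allclose(out, 3.0, atol=1e-9)

    def test_fs_mismatch_rejected(self, irf):
        with pytest.raises(ValueError):
            convolve_driver(np.ones(10), irf, fs=4.0)


class TestDeconvolve:
    def test_constant_signal_recovers_constant_driver(self, irf):
        d = deconvolve(EDASignal(np.full(961, 2.5), fs=8.0), irf, reg=1e-8)
        np.testing.assert_allclose(d, 2.5, atol=1e-6)

    def test_round_trip_on_quiet_margin_driver(self, irf, rng):
        fs, dur = 8.0, 120.0
        n = int(dur * fs) + 1
        times = rng.uniform(45.0, dur - 45.0, 10)
        amps = rng.lognormal(np.log(0.5), 0.3, 10)
        d = 4.0 + render_bumps(n, fs, times, amps, 0.7)
        y = convolve_driver(d, irf)
        rec = deconvolve(y, irf, reg=1e-8)
        assert np.abs(rec - d).max() < 1e-6

    def test_stronger_regularisation_smooths_more(self, irf, rng):
        y = rng.normal(0, 1, 961)
        v_small = np.var(deconvolve(y, irf, reg=1e-8))
        v_large = np.var(deconvolve(y, irf, reg=0.1))
        assert v_large < v_small

    def test_all_zero_kernel_rejected(self, irf):
        bad = dataclasses.replace(irf, kernel=np.zeros_like(irf.kernel))
        with pytest.raises(ValueError):
            deconvolve(np.ones(100), bad)


class TestSplit:
    def test_constant_total_gives_zero_phasic(self):
        scl, scr = split_tonic_phasic(np.full(961, 1.5), fs=8.0)
        np.testing.assert_allclose(scl, 1.5, atol=1e-9)
        np.testing.assert_allclose(scr, 0.0, atol=1e-9)

    def test_additivity_and_nonnegativity(self, rng):
        total = rng.normal(2.0, 0.5, 961)
        scl, scr = split_tonic_phasic(total, fs=8.0)
        np.testing.assert_allclose(scl + scr, total, atol=1e-12)
        assert scr.min() >= 0.0

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_tonic_phasic(np.ones(100), fs=8.0, window_s=5.0)

    def test_long_window_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            split_tonic_phasic(np.ones(80), fs=8.0, window_s=30.0)


class TestExtract:
    def test_too_short_signal_rejected(self, irf):
        with pytest.raises(ValueError, match="short"):
            extract_scr_driver(EDASignal(np.ones(10), fs=8.0), irf)

    def test_result_invariants(self, session, irf):
        res = extract_scr_driver(preprocess(session.signal), irf)
        res.validate()
        assert res.residual_rmse >= 0.0

    def test_offset_robustness(self, session, irf):
        """Adding a constant to the signal moves only the tonic driver."""
        clean = preprocess(session.signal)
        shifted = EDASignal(clean.samples + 1.0, clean.fs)
        r0 = extract_scr_driver(clean, irf)
        r1 = extract_scr_driver(shifted, irf)
        interior = slice(80, -80)
        np.testing.assert_allclose(
            r1.scr_driver[interior], r0.scr_driver[interior], atol=1e-3
        )
        assert np.median(r1.scl_driver - r0.scl_driver) == pytest.approx(1.0, abs=0.01)


class TestBurstDetection:
    def test_recovers_clean_sparse_train(self, irf):
        fs = 8.0
        n = int(90 * fs)
        times = np.array([20.0, 31.5, 47.0, 63.2])
        amps = np.array([0.5, 0.8, 0.4, 0.6])
        driver = 3.0 + render_bumps(n, fs, times, amps, 0.3)
        y = convolve_driver(driver, irf)
        sig = preprocess(EDASignal(y, fs=fs))
        res = extract_scr_driver(sig, irf)
        residue = phasic_residue(sig, res, irf)
        det = detect_bursts(residue, fs, scr_atom(irf), mass_threshold=0.12)
        assert det.times.size == 4
        assert np.abs(np.sort(det.times) - times).max() < 0.5
        np.testing.assert_allclose(np.sort(det.masses), np.sort(amps), rtol=0.25)

    def test_counts_per_segment_on_noisy_session(self, small_config):
        cfg = dataclasses.replace(small_config, amp_gain_sigma=0.0)
        s = simulate_session(cfg, "P01", np.random.default_rng(3))
        irf = cfg.make_irf()
        clean = preprocess(s.signal)
        res = extract_scr_driver(clean, irf)
        counts = count_bursts_by_segment(clean, res, irf, s.events)
        ok = 0
        music = [ev for ev in s.events if ev.label != "neutral"]
        for ev in music:
            nt = len(s.truth.segment_truth(ev.label).times)
            ok += abs(counts[ev.label] - nt) <= max(1, 0.1 * nt)
        assert ok >= len(music) - 1
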