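import dataclasses

import numpy as np
import pytest
from scipy import stats as spstats

from scrkit.deconv import convolve_driver
from scrkit.synth import (
    SyntheticConfig,
    draw_burst_times,
    random_smooth_driver,
    simulate_cohort,
    simulate_driver,
    simulate_session,
)


class TestBurstProcess:
    def test_zero_rate_yields_no_events(self, rng):
        assert draw_burst_times(0.0, 60.0, 1.5, rng).size == 0

    def test_rate_preserved_despite_dead_time(self):
        counts = [
            draw_burst_times(16.0, 60.0, 1.5, np.random.default_rng(s)).size
            for s in range(500)
        ]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 16.0) < 3 * se + 0.3

    def test_refractory_gap_enforced(self, rng):
        times = draw_burst_times(16.0, 600.0, 1.5, rng)
        assert np.diff(times).min() >= 1.5

    def test_incompatible_dead_time_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_burst_times(60.0, 60.0, 1.5, rng)

    def test_determinism(self):
        a = draw_burst_times(10.0, 60.0, 1.5, np.random.default_rng(42))
        b = draw_burst_times(10.0, 60.0, 1.5, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)


class TestDriver:
    def test_zero_arousal_zero_base_rate(self, rng):
        cfg = SyntheticConfig(scr_rate_base=0.0, scr_rate_slope=12.0)
        driver, times, amps = simulate_driver(0.0, 60.0, 8.0, rng, cfg)
        assert times.size == 0 and np.all(driver == 0.0)

    def test_nonnegative_and_sparse(self, rng):
        driver, times, _ = simulate_driver(0.5, 60.0, 8.0, rng)
        assert driver.min() >= 0.0
        assert (driver < 1e-6).mean() > 0.3  # mostly quiet between bursts

    def test_invalid_duration(self, rng):
        with pytest.raises(ValueError):
            simulate_driver(0.5, -1.0, 8.0, rng)


class TestSession:
    def test_schedule_arithmetic(self, session, small_config):
        cfg = small_config
        expected = (cfg.baseline_duration + 8 * cfg.segment_duration) * cfg.fs + 1
        assert abs(len(session.signal) - expected) <= 1

    def test_events_tile_without_overlap(self, session):
        labels = [e.label for e in session.events]
        assert len(labels) == 9 and labels[0] == "neutral"
        for a, b in zip(session.events, session.events[1:]):
            assert b.onset >= a.onset + a.duration - 1e-9

    def test_neutral_segment_matches_music_duration(self, session, small_config):
        neutral = session.events[0]
        assert neutral.duration == small_config.segment_duration

    def test_sam_one_per_music_segment(self, session):
        assert len(session.sam) == 8
        assert all(1 <= r.arousal <= 9 for r in session.sam)

    def test_forward_model_exactness(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0, artifact_rate=0.0)
        s = simulate_session(cfg, "P01", np.random.default_rng(0))
        recon = convolve_driver(s.truth.total_driver, cfg.make_irf())
        np.testing.assert_allclose(s.signal.samples, recon, atol=1e-10)

    def test_degenerate_config_constant_signal(self):
        cfg = SyntheticConfig(
            noise_sd=0.0, artifact_rate=0.0, tonic_drift_sd=0.0,
            scr_rate_base=0.0, scr_rate_slope=0.0, arousal_sd=0.0,
        )
        s = simulate_session(cfg, "P01", np.random.default_rng(0))
        assert np.ptp(s.signal.samples) == pytest.approx(0.0, abs=1e-9)

    def test_artifacts_add_spikes(self):
        base = SyntheticConfig(seed=5)
        spiky = dataclasses.replace(base, artifact_rate=30.0)
        a = simulate_session(base, "P01", np.random.default_rng(5))
        b = simulate_session(spiky, "P01", np.random.default_rng(5))
        assert np.abs(np.diff(b.signal.samples)).max() > np.abs(np.diff(a.signal.samples)).max()

    def test_invalid_config_lists_fields(self):
        cfg = SyntheticConfig(noise_sd=-1.0, segment_duration=-5.0)
        with pytest.raises(ValueError) as exc:
            cfg.validate()
        assert "noise_sd" in str(exc.value) and "segment_duration" in str(exc.value)

    def test_truth_times_inside_recording(self, session):
        for seg in session.truth.segments:
            if seg.times.size:
                assert seg.times.min() >= seg.onset - 1e-9
                assert seg.times.max() < seg.onset + seg.duration


class TestCohort:
    def test_reproducible_from_master_seed(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.signal.samples, s2.signal.samples)
            assert s1.sam == s2.sam

    def test_participants_differ(self, small_cohort):
        assert not np.array_equal(
            small_cohort[0].signal.samples, small_cohort[1].signal.samples
        )

    def test_tonic_levels_span(self):
        cfg = SyntheticConfig(n_participants=40, seed=3)
        sessions = simulate_cohort(cfg)
        levels = [s.truth.tonic_driver[0] for s in sessions]
        assert max(levels) - min(levels) >= 2.0

    def test_arousal_physiology_coupling_monotone(self):
        """Higher latent arousal must mean stochastically more bursts."""
        cfg = SyntheticConfig(n_participants=10, seed=9)
        a, counts = [], []
        for s in simulate_cohort(cfg):
            for seg in s.truth.segments:
                a.append(seg.arousal)
                counts.append(seg.times.size)
        rho = spstats.spearmanr(a, counts).statistic
        assert rho > 0.4

    def test_high_arousal_elevates_driver_mean(self):
        """Phasic driver mean is larger in high-arousal than neutral windows
        in nearly every simulated session."""
        wins = 0
        reps = 20
        for rep in range(reps):
            cfg = SyntheticConfig(
                n_participants=1, seed=100 + rep,
                genre_arousal={g: 1.0 for g in ("flamenco", "cuban", "spanish_folklore", "rock_jazz")},
            )
            s = simulate_cohort(cfg)[0]
            fs = cfg.fs
            means = {}
            for ev in s.events:
                i0, i1 = int(ev.onset * fs), int(ev.end * fs)
                means[ev.label] = s.truth.phasic_driver[i0:i1].mean()
            music = np.mean([v for k, v in means.items() if k != "neutral"])
            wins += music > means["neutral"]
        assert wins >= reps - 2


class TestSmoothDriver:
    def test_quiet_margins(self, rng):
        d = random_smooth_driver(rng)
        fs = 8.0
        assert np.ptp(d[: int(30 * fs)]) < 1e-9  # flat inside the margin
        assert np.ptp(d[-int(30 * fs):]) < 1e-9
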