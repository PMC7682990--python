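"""Synthetic-data generator: PMD schedules, button traces, tagged EEG."""

import numpy as np
import pytest
from scipy import stats

from pfitag import BehaviorParams, EEGParams, ModulationProfile, StimulusConfig
from pfitag.simulate import (
    default_topographies,
    event_gain_profile,
    generate_button_traces,
    generate_eeg,
    generate_pmd_schedule,
    pink_noise,
    simulate_participant,
    synthetic_montage,
)
from pfitag.types import ReportEvent


class TestStimulusConfig:
    def test_default_frequencies_are_commensurate(self):
        cfg = StimulusConfig()
        assert cfg.im == 5.0
        assert cfg.n_frames == 3600

    def test_invalid_frequency_order_rejected(self):
        with pytest.raises(ValueError):
            StimulusConfig(f1=20.0, f2=15.0)

    def test_noncommensurate_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            StimulusConfig(f1=14.0, f2=20.0)  # 60/14 is not an integer; 6 Hz im


class TestPmdSchedule:
    def test_bulk_draw_respects_bounds(self):
        """10,000 draws: durations in [3.5, 5], onsets >= 10 s, removal
        inside the trial."""
        cfg = StimulusConfig(n_trials=10_000)
        pmds = generate_pmd_schedule(cfg, 1)
        durations = np.array([p.duration for p in pmds])
        onsets = np.array([p.onset for p in pmds])
        assert durations.min() >= 3.5 and durations.max() <= 5.0
        assert onsets.min() >= 10.0
        assert (onsets + durations).max() <= cfg.trial_duration
        sizes = np.array([len(p.removed_targets) for p in pmds])
        assert set(sizes) == {1, 2, 3, 4}

    def test_duration_distribution_is_uniform(self):
        """KS test of durations against Uniform(3.5, 5) is not rejected at
        alpha = 0.01."""
        cfg = StimulusConfig(n_trials=10_000)
        pmds = generate_pmd_schedule(cfg, 2)
        durations = [p.duration for p in pmds]
        _, p = stats.kstest(durations, "uniform", args=(3.5, 1.5))
        assert p > 0.01

    def test_same_seed_identical_schedules(self):
        cfg = StimulusConfig(n_trials=20)
        assert generate_pmd_schedule(cfg, 9) == generate_pmd_schedule(cfg, 9)

    def test_short_trial_rejected(self):
        with pytest.raises(ValueError):
            generate_pmd_schedule(StimulusConfig(trial_duration=12.0), 0)


class TestButtonTraces:
    def test_responder_with_no_pfi_presses_only_in_pmd_windows(self):
        cfg = StimulusConfig(n_trials=6)
        beh = BehaviorParams(
            pfi_onset_rate=0.0, responder=True, report_lag_sd=0.05,
            rate_heterogeneity=0.0, duration_heterogeneity=0.0,
        )
        pmds = generate_pmd_schedule(cfg, 3)
        traces, truth = generate_button_traces(cfg, beh, pmds, 3)
        for trace, pmd in zip(traces, pmds):
            pressed_frames = np.flatnonzero(trace.pressed.any(axis=0))
            if pressed_frames.size == 0:
                continue
            times = pressed_frames / cfg.frame_rate
            # lag-shifted window (lag mean 0.7, sd 0.05 -> generous margin)
            assert times.min() >= pmd.onset
            assert times.max() <= pmd.offset + 1.5
        assert all(len(evts) == 0 for evts in truth.pfi_events)

    def test_full_coupling_recruits_all_targets(self):
        cfg = StimulusConfig(n_trials=4)
        beh = BehaviorParams(
            coupling=1.0, responder=False,
            rate_heterogeneity=0.0, duration_heterogeneity=0.0,
        )
        pmds = generate_pmd_schedule(cfg, 4)
        _, truth = generate_button_traces(cfg, beh, pmds, 4)
        checked = 0
        for trial_events, pmd in zip(truth.pfi_events, pmds):
            onsets = {}
            for ev in trial_events:
                onsets.setdefault(round(ev.onset, 9), set()).add(ev.target)
            for onset, members in onsets.items():
                # events near the PMD window can be truncated away at
                # removed targets; skip those onsets
                if pmd.onset - 15.0 <= onset <= pmd.offset:
                    continue
                assert members == {0, 1, 2, 3}
                checked += 1
        assert checked > 0

    def test_zero_coupling_matches_independence_prediction(self):
        """With coupling 0 the fraction of frames with all four targets
        reported invisible approaches the product of per-target press
        probabilities."""
        cfg = StimulusConfig(n_trials=60)
        beh = BehaviorParams(
            coupling=0.0, responder=False,
            rate_heterogeneity=0.0, duration_heterogeneity=0.0,
        )
        pmds = generate_pmd_schedule(cfg, 8)
        traces, _ = generate_button_traces(cfg, beh, pmds, 8)
        pressed = np.concatenate([t.pressed for t in traces], axis=1).astype(float)
        per_target = pressed.mean(axis=1)
        all_four = (pressed.sum(axis=0) == 4).mean()
        expected = per_target.prod()
        assert all_four == pytest.approx(expected, abs=3e-3)

    def test_truth_and_trace_are_consistent(self, small_participant):
        """Every true PFI event produces a press covering its lagged span."""
        _, traces, truth, _ = small_participant
        for trace, events in zip(traces, truth.pfi_events):
            for ev in events:
                # the report lag is truncated at 0, so by the event midpoint
                # (duration >= ~2 s) the button must be down
                mid = (ev.onset + min(ev.offset, ev.onset + 2.5)) / 2
                frame = int(np.ceil((mid + 1.6) * trace.frame_rate))
                if frame < trace.n_frames and ev.offset - ev.onset > 2.0:
                    assert trace.pressed[ev.target, frame] == 1


class TestGainProfile:
    def test_transient_bump_half_rise_at_latency_plus_half_ramp(self):
        prof = ModulationProfile(0.5, -0.4, 0.0, 0.0, rise_time=0.3, span=1.0)
        t = np.arange(0, 20, 0.001)
        press = ReportEvent(kind="disappearance", target=0, time=10.0, frame=600, source="pfi")
        m = event_gain_profile(t, [press], prof, "pfi")
        half_idx = np.argmax(m >= 0.5)
        assert t[half_idx] == pytest.approx(10.0 - 0.4 + 0.15, abs=0.002)
        # plateau reached after the ramp, decays after span + ramp
        assert m[np.searchsorted(t, 10.0)] == pytest.approx(1.0, abs=1e-9)
        assert m[np.searchsorted(t, 12.0)] == pytest.approx(0.0, abs=1e-9)

    def test_release_subtracts_bump(self):
        prof = ModulationProfile(0.5, 0.0, 0.0, 0.0)
        t = np.arange(0, 20, 0.01)
        release = ReportEvent(kind="reappearance", target=0, time=10.0, frame=600, source="pfi")
        m = event_gain_profile(t, [release], prof, "pfi")
        assert m.min() == pytest.approx(-1.0, abs=1e-9)
        assert m.max() <= 1e-9


class TestEEG:
    def test_zero_noise_single_component_is_spectrally_pure(self):
        cfg = StimulusConfig(n_trials=1, trial_duration=20.0)
        beh = BehaviorParams(pfi_onset_rate=0.0, responder=False,
                             rate_heterogeneity=0.0, duration_heterogeneity=0.0)
        pmds = generate_pmd_schedule(cfg, 0)
        traces, truth = generate_button_traces(cfg, beh, pmds, 0)
        topo = {"f1": np.ones(2)}
        eeg = EEGParams(
            n_channels=2, noise_scale=0.0, nonlinearity_gain=0.0,
            source_topographies=topo, latency_jitter_sd=0.0, depth_jitter_sd=0.0,
        )
        recs = generate_eeg(cfg, eeg, traces, truth, 0)
        sig = recs[0].samples[0]
        spec = np.abs(np.fft.rfft(sig)) ** 2
        freqs = np.fft.rfftfreq(sig.size, 1 / 250.0)
        peak = spec[np.argmin(np.abs(freqs - 15.0))]
        others = spec[np.abs(freqs - 15.0) > 0.5]
        assert 10 * np.log10(others.max() / peak) < -100

    def test_nonlinearity_creates_intermodulation_line(self):
        """The rectified two-tone sum must produce a 5 Hz line that is
        absent without the nonlinearity."""
        cfg = StimulusConfig(n_trials=1, trial_duration=20.0)
        beh = BehaviorParams(pfi_onset_rate=0.0, responder=False,
                             rate_heterogeneity=0.0, duration_heterogeneity=0.0)
        pmds = generate_pmd_schedule(cfg, 0)
        traces, truth = generate_button_traces(cfg, beh, pmds, 0)
        topo = {"f1": np.ones(2), "f2": np.ones(2), "im": np.ones(2)}

        def im_power(gain):
            eeg = EEGParams(
                n_channels=2, noise_scale=0.0, nonlinearity_gain=gain,
                source_topographies=topo, latency_jitter_sd=0.0, depth_jitter_sd=0.0,
            )
            recs = generate_eeg(cfg, eeg, traces, truth, 0)
            sig = recs[0].samples[0]
            spec = np.abs(np.fft.rfft(sig)) ** 2
            freqs = np.fft.rfftfreq(sig.size, 1 / 250.0)
            return spec[np.argmin(np.abs(freqs - 5.0))]

        with_nl = im_power(0.4)
        without_nl = im_power(0.0)
        assert with_nl > 1e6 * max(without_nl, 1e-30)

    def test_same_seed_bit_identical(self, small_config):
        beh = BehaviorParams()
        eeg = EEGParams(n_channels=8)
        _, _, _, recs1 = simulate_participant(small_config, beh, eeg, 77)
        _, _, _, recs2 = simulate_participant(small_config, beh, eeg, 77)
        for r1, r2 in zip(recs1, recs2):
            np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_mismatched_traces_and_truth_rejected(self, small_participant):
        pmds, traces, truth, _ = small_participant
        eeg = EEGParams(n_channels=4)
        from pfitag.types import GroundTruth

        bad_truth = GroundTruth(
            pfi_events=truth.pfi_events[:-1],
            report_events=truth.report_events[:-1],
        )
        with pytest.raises(ValueError):
            generate_eeg(StimulusConfig(n_trials=4, trial_duration=30.0), eeg, traces, bad_truth, 0)


class TestMontageAndNoise:
    def test_montage_is_deterministic_and_inside_unit_disc(self):
        coords = synthetic_montage(64)
        np.testing.assert_array_equal(coords, synthetic_montage(64))
        assert np.all(np.linalg.norm(coords, axis=1) <= 1.0 + 1e-9)

    def test_topographies_have_expected_layout(self):
        topos = default_topographies(64)
        assert set(topos) == {"f1", "f2", "im", "alpha", "noise"}
        coords = synthetic_montage(64)
        # visual components peak posterior (y < 0)
        for name in ("f1", "f2", "im"):
            assert coords[np.argmax(topos[name]), 1] < 0

    def test_pink_noise_slope_near_one_over_f(self, rng):
        x = pink_noise(rng, 2**16, 250.0, exponent=1.0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / 250.0)
        band = (freqs > 1) & (freqs < 50)
        slope = np.polyfit(np.log10(freqs[band]), np.log10(spec[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)
        assert x.std() == pytest.approx(1.0, abs=1e-9)
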