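"""Synthetic behavior and EEG with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: per-target filling-in reports with optional cross-target grouping,
one physical-removal (PMD) catch event per trial, and multichannel EEG whose
f1/f2 tag components, rectification-born intermodulation component, and
alpha rhythm are amplitude-modulated time-locked to the report events, on
top of 1/f noise.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .types import (
    BehaviorParams,
    ModulationProfile,
    ButtonTrace,
    EEGParams,
    GroundTruth,
    PFIEvent,
    PMDSchedule,
    ReportEvent,
    StimulusConfig,
    TrialRecording,
)

__all__ = [
    "generate_pmd_schedule",
    "generate_button_traces",
    "generate_eeg",
    "simulate_participant",
    "synthetic_montage",
    "default_topographies",
    "event_gain_profile",
    "pink_noise",
]

PMD_DURATION_RANGE = (3.5, 5.0)
PMD_EARLIEST_ONSET = 10.0


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def generate_pmd_schedule(
    config: StimulusConfig, seed: int | np.random.Generator
) -> list[PMDSchedule]:
    """Draw one physical-removal event per trial.

    Durations are uniform on [3.5, 5] s, onsets uniform on [10, T - duration]
    (removal never in the first 10 s), the removed-target count uniform on
    {1..n_targets} and the identity uniform over subsets of that size.
    """
    lo, hi = PMD_DURATION_RANGE
    if config.trial_duration < PMD_EARLIEST_ONSET + hi:
        raise ValueError(
            f"trial_duration {config.trial_duration} too short to place a "
            f"PMD of up to {hi} s after {PMD_EARLIEST_ONSET} s"
        )
    rng = np.random.default_rng(seed)
    schedules = []
    for trial in range(config.n_trials):
        duration = rng.uniform(lo, hi)
        onset = rng.uniform(PMD_EARLIEST_ONSET, config.trial_duration - duration)
        n_removed = int(rng.integers(1, config.n_targets + 1))
        removed = tuple(
            int(t) for t in sorted(rng.choice(config.n_targets, size=n_removed, replace=False))
        )
        schedules.append(
            PMDSchedule(
                onset=onset,
                duration=duration,
                removed_targets=removed,
                trial_index=trial,
            )
        )
    return schedules


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of a log-normal with the given moments."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncated_lag(rng: np.random.Generator, mean: float, sd: float, size: int):
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def generate_button_traces(
    config: StimulusConfig,
    behavior: BehaviorParams,
    pmds: list[PMDSchedule],
    seed: int | np.random.Generator,
) -> tuple[list[ButtonTrace], GroundTruth]:
    """Simulate button reports for every trial.

    True filling-in onsets are a Poisson process per target with log-normal
    durations; with probability ``coupling`` each other target joins an
    onset (shared onset, own duration), implementing perceptual grouping.
    A filling-in event that would overlap the PMD window at a removed target
    is truncated at PMD onset.  Reports lag true events by a truncated
    Gaussian delay; responders additionally report the physical removals.
    """
    if len(pmds) != config.n_trials:
        raise ValueError("need one PMDSchedule per trial")
    rng = np.random.default_rng(seed)
    T = config.trial_duration
    fr = config.frame_rate
    n_frames = config.n_frames
    mu, sigma = (
        _lognormal_params(behavior.pfi_duration_mean, behavior.pfi_duration_sd)
        if behavior.pfi_duration_mean > 0 and behavior.pfi_duration_sd > 0
        else (None, None)
    )

    traces: list[ButtonTrace] = []
    all_true: list[list[PFIEvent]] = []
    all_reports: list[list[ReportEvent]] = []

    for trial, pmd in enumerate(pmds):
        # --- true PFI events -------------------------------------------------
        events: list[PFIEvent] = []
        for target in range(config.n_targets):
            n_onsets = rng.poisson(behavior.pfi_onset_rate * T)
            onsets = np.sort(rng.uniform(0.0, T, size=n_onsets))
            for onset in onsets:
                members = [target]
                for other in range(config.n_targets):
                    if other != target and rng.random() < behavior.coupling:
                        members.append(other)
                for m in members:
                    if mu is None:
                        dur = behavior.pfi_duration_mean
                    else:
                        dur = float(rng.lognormal(mu, sigma))
                    offset = min(onset + dur, T)
                    if m in pmd.removed_targets and onset < pmd.offset and offset > pmd.onset:
                        # attribute presses inside PMD windows to the PMD
                        offset = min(offset, pmd.onset)
                        if offset <= onset:
                            continue
                    events.append(PFIEvent(target=m, onset=onset, offset=offset))
        events.sort(key=lambda e: (e.target, e.onset))

        # --- reports ---------------------------------------------------------
        pressed = np.zeros((config.n_targets, n_frames), dtype=np.uint8)

        def mark(target: int, start: float, stop: float) -> None:
            i0 = int(np.ceil(start * fr - 1e-9))
            i1 = int(np.ceil(stop * fr - 1e-9))
            i0 = max(i0, 0)
            i1 = min(i1, n_frames)
            if i1 > i0:
                pressed[target, i0:i1] = 1

        for ev in events:
            lag_on, lag_off = _truncated_lag(
                rng, behavior.report_lag_mean, behavior.report_lag_sd, 2
            )
            mark(ev.target, ev.onset + lag_on, ev.offset + lag_off)

        if behavior.responder:
            for target in pmd.removed_targets:
                lag_on, lag_off = _truncated_lag(
                    rng, behavior.report_lag_mean, behavior.report_lag_sd, 2
                )
                mark(target, pmd.onset + lag_on, pmd.offset + lag_off)

        trace = ButtonTrace(pressed=pressed, frame_rate=fr, trial_index=trial)
        traces.append(trace)
        all_true.append(events)

        from .events import classify_and_filter_events, detect_report_events

        reports = detect_report_events(trace)
        reports = classify_and_filter_events(reports, pmd)
        all_reports.append(reports)

    truth = GroundTruth(pfi_events=all_true, report_events=all_reports)
    return traces, truth


# ---------------------------------------------------------------------------
# montage and topographies
# ---------------------------------------------------------------------------

def synthetic_montage(n_channels: int) -> np.ndarray:
    """Deterministic 2-D sensor layout (sunflower spiral on the unit disc).

    x is rightward, y anterior; posterior sensors have y < 0.  No real
    electrode geometry is modeled, only enough spatial structure for
    topographies and neighborhood adjacency.
    """
    i = np.arange(n_channels)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt((i + 0.5) / n_channels)
    theta = i * golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _bump(coords: np.ndarray, center: tuple[float, float], width: float) -> np.ndarray:
    d2 = ((coords - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def default_topographies(n_channels: int) -> dict[str, np.ndarray]:
    """Posterior bumps for the visual tag components, a centro-parietal bump
    for alpha, and a broad pattern for the shared noise source."""
    coords = synthetic_montage(n_channels)
    return {
        "f1": _bump(coords, (-0.15, -0.75), 0.45),
        "f2": _bump(coords, (0.15, -0.75), 0.45),
        "im": _bump(coords, (0.0, -0.60), 0.45),
        "alpha": _bump(coords, (0.0, -0.15), 0.55),
        "noise": _bump(coords, (0.0, 0.3), 1.2),
    }


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _raised_cosine_step(t: np.ndarray, t0: float, rise: float) -> np.ndarray:
    """0 before t0, 1 after t0 + rise, half-cosine ramp in between."""
    if rise <= 0:
        return (t >= t0).astype(float)
    x = np.clip((t - t0) / rise, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _transient_bump(t: np.ndarray, t0: float, rise: float, span: float) -> np.ndarray:
    """Raised-cosine plateau: ramps 0->1 from t0 over ``rise``, holds for
    ``span``, decays back over another ``rise``."""
    return _raised_cosine_step(t, t0, rise) - _raised_cosine_step(
        t, t0 + rise + span, rise
    )


def event_gain_profile(
    t: np.ndarray,
    reports: list[ReportEvent],
    profile,
    kind_source: str,
) -> np.ndarray:
    """Event-locked modulation drive m(t) for one source label.

    Every press adds a transient bump starting at ``press + latency`` and
    every release subtracts one starting at ``release + latency``, so the
    drive is positive around disappearance reports, negative around
    reappearances, and zero in between.  Contributions from simultaneous
    events add unless the profile is saturating (clip to [-1, 1]).
    """
    latency = profile.latency_pfi if kind_source == "pfi" else profile.latency_pmd
    m = np.zeros_like(t)
    for ev in reports:
        if ev.source != kind_source:
            continue
        sign = 1.0 if ev.kind == "disappearance" else -1.0
        m += sign * _transient_bump(
            t, ev.time + latency, profile.rise_time, profile.span
        )
    if profile.saturating:
        m = np.clip(m, -1.0, 1.0)
    return m


def pink_noise(
    rng: np.random.Generator, n_samples: int, sample_rate: float, exponent: float = 1.0
) -> np.ndarray:
    """Unit-variance noise with power spectral density proportional to 1/f^exponent,
    made by spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _component_gain(
    t: np.ndarray, reports: list[ReportEvent], profile
) -> np.ndarray:
    """Multiplicative gain combining PFI- and PMD-locked modulation."""
    g = (
        1.0
        + profile.depth_pfi * event_gain_profile(t, reports, profile, "pfi")
        + profile.depth_pmd * event_gain_profile(t, reports, profile, "pmd")
    )
    return np.clip(g, 0.0, None)


def generate_eeg(
    config: StimulusConfig,
    eeg: EEGParams,
    traces: list[ButtonTrace],
    truth: GroundTruth,
    seed: int | np.random.Generator,
) -> list[TrialRecording]:
    """Render multichannel EEG for every trial.

    Each channel is the topography-weighted sum of the modulated f1/f2
    sinusoids, the rectified two-tone intermodulation signal, the alpha
    rhythm, a shared 1/f noise source, plus independent 1/f sensor noise.
    """
    if len(traces) != len(truth.report_events):
        raise ValueError("traces and ground truth describe different trials")
    eeg.validate_rate(config)
    rng = np.random.default_rng(seed)
    fs = eeg.sample_rate
    n_samples = int(round(config.trial_duration * fs))
    t = np.arange(n_samples) / fs
    topos = (
        eeg.source_topographies
        if eeg.source_topographies is not None
        else default_topographies(eeg.n_channels)
    )
    labels = [f"ch{i:02d}" for i in range(eeg.n_channels)]
    profiles = eeg.modulation_profiles

    truth.modulation_latencies = {
        name: prof.latency_pfi for name, prof in profiles.items()
    }
    if "alpha" in profiles:
        truth.alpha_suppression_depth = abs(profiles["alpha"].depth_pfi)

    recordings: list[TrialRecording] = []
    for trial, trace in enumerate(traces):
        reports = truth.report_events[trial]
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)

        g1 = _component_gain(t, reports, profiles["f1"])
        g2 = _component_gain(t, reports, profiles["f2"])
        drive1 = g1 * np.sin(2.0 * np.pi * config.f1 * t + phases[0])
        drive2 = g2 * np.sin(2.0 * np.pi * config.f2 * t + phases[1])

        data = np.zeros((eeg.n_channels, n_samples))
        if "f1" in topos:
            data += np.outer(topos["f1"], drive1)
        if "f2" in topos:
            data += np.outer(topos["f2"], drive2)

        if eeg.nonlinearity_gain != 0 and "im" in topos and "im" in profiles:
            rect = np.clip(drive1 + drive2, 0.0, None)
            rect = rect - rect.mean()
            gim = _component_gain(t, reports, profiles["im"])
            data += np.outer(topos["im"], eeg.nonlinearity_gain * gim * rect)

        if "alpha" in topos and "alpha" in profiles:
            ga = _component_gain(t, reports, profiles["alpha"])
            alpha_sig = eeg.alpha_amplitude * ga * np.sin(
                2.0 * np.pi * 10.0 * t + phases[2]
            )
            data += np.outer(topos["alpha"], alpha_sig)

        if eeg.noise_scale > 0:
            shared = pink_noise(rng, n_samples, fs, eeg.noise_exponent)
            noise_topo = topos.get("noise", np.ones(eeg.n_channels))
            data += eeg.noise_scale * np.outer(noise_topo, shared)
            for ch in range(eeg.n_channels):
                data[ch] += eeg.noise_scale * pink_noise(
                    rng, n_samples, fs, eeg.noise_exponent
                )

        recordings.append(
            TrialRecording(
                samples=data, sample_rate=fs, channel_labels=labels, trial_index=trial
            )
        )
    return recordings


def simulate_participant(
    config: StimulusConfig,
    behavior: BehaviorParams,
    eeg: EEGParams | None,
    seed: int | np.random.SeedSequence,
):
    """Convenience wrapper: PMD schedule + button traces (+ EEG if requested).

    Returns ``(pmds, traces, truth, recordings)``; ``recordings`` is None
    when ``eeg`` is None.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pmd, s_beh, s_eeg, s_jit, s_jit2 = ss.spawn(5)
    pmds = generate_pmd_schedule(config, np.random.default_rng(s_pmd))
    behavior_p = individualize_behavior_params(
        behavior, np.random.default_rng(s_jit)
    )
    traces, truth = generate_button_traces(
        config, behavior_p, pmds, np.random.default_rng(s_beh)
    )
    recordings = None
    if eeg is not None:
        eeg_p = individualize_eeg_params(eeg, np.random.default_rng(s_jit2))
        recordings = generate_eeg(
            config, eeg_p, traces, truth, np.random.default_rng(s_eeg)
        )
    return pmds, traces, truth, recordings


def individualize_behavior_params(
    behavior: BehaviorParams, rng: np.random.Generator
) -> BehaviorParams:
    """Per-participant scaling of the filling-in rate and duration mean by
    log-normal factors, emulating individual differences in the amount of
    PFI.  Returns a new BehaviorParams; with zero heterogeneity the input
    is returned as is."""
    if behavior.rate_heterogeneity == 0 and behavior.duration_heterogeneity == 0:
        return behavior
    rate_f = float(np.exp(rng.normal(0.0, behavior.rate_heterogeneity)))
    dur_f = float(np.exp(rng.normal(0.0, behavior.duration_heterogeneity)))
    return dataclasses.replace(
        behavior,
        pfi_onset_rate=behavior.pfi_onset_rate * rate_f,
        pfi_duration_mean=behavior.pfi_duration_mean * dur_f,
    )


def individualize_eeg_params(
    eeg: EEGParams, rng: np.random.Generator
) -> EEGParams:
    """Per-participant perturbation of the modulation profiles.

    Onset latencies are jittered by a Gaussian of SD ``latency_jitter_sd``
    and depths scaled by ``1 + N(0, depth_jitter_sd)`` (sign preserved),
    emulating the between-participant spread of event-locked responses.
    Returns a new EEGParams; with both SDs zero the input is returned as is.
    """
    if eeg.latency_jitter_sd == 0 and eeg.depth_jitter_sd == 0:
        return eeg
    profiles = {}
    for name, p in eeg.modulation_profiles.items():
        lat_j = rng.normal(0.0, eeg.latency_jitter_sd, size=2)
        dep_j = np.clip(1.0 + rng.normal(0.0, eeg.depth_jitter_sd, size=2), 0.1, None)
        profiles[name] = ModulationProfile(
            depth_pfi=p.depth_pfi * dep_j[0],
            latency_pfi=p.latency_pfi + lat_j[0],
            depth_pmd=p.depth_pmd * dep_j[1],
            latency_pmd=p.latency_pmd + lat_j[1],
            rise_time=p.rise_time,
            saturating=p.saturating,
        )
    return dataclasses.replace(eeg, modulation_profiles=profiles)
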