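"""Ground-truth recovery checks on controlled synthetic scenarios.

Each helper builds a scenario in which one injected quantity is well
defined and isolated (homogeneous cohorts, sparse long events, silenced
interfering components), runs the package's own analysis path on generated
EEG/behavior, and returns the recovered quantity next to the truth.  The
scenarios deliberately differ from the busy default conditions: a recovery
check is only meaningful where "the" injected value exists (for example,
per-participant latency jitter makes a single true latency lead undefined)
and where neighboring-event transients do not overlap the analysis window.
"""

from __future__ import annotations

import numpy as np

from . import behavior as beh
from .alpha import AlphaParams, alpha_envelope, baseline_normalize, suppression_depth
from .events import epoch_signal, pfi_events
from .latency import jackknife_latencies
from .simulate import default_topographies, simulate_participant
from .spectral import snr_timecourse
from .types import BehaviorParams, EEGParams, ModulationProfile, StimulusConfig

__all__ = [
    "recover_latency_lead",
    "recover_alpha_suppression",
    "screen_synthetic_pair",
]


def recover_latency_lead(
    lead: float,
    seed: int,
    n_participants: int = 8,
    n_trials: int = 10,
    epoch_half_width: float = 4.0,
) -> float | None:
    """Inject a surround-leads-target onset offset and re-estimate it.

    The surround (f2) modulation onset is set ``lead`` seconds before the
    target (f1) onset; both frequencies' disappearance-vs-reappearance SNR
    contrasts are built per participant from single-channel moving-window
    log-SNR, and the jackknifed median first-significant-timepoints are
    differenced.  Events are sparse and long (rate 0.02 /s/target, duration
    8 +- 1 s, no coupling) so neighboring transients stay clear of the
    epochs; the IM and alpha modulations are silenced so their rectified
    15/20 Hz content cannot shift either onset; the cohort is homogeneous
    so the injected lead is single-valued.  Returns the recovered lead
    (f1 onset minus f2 onset) or None when either onset is undefined.
    """
    cfg = StimulusConfig(n_trials=n_trials, trial_duration=60.0)
    behavior = BehaviorParams(
        pfi_onset_rate=0.02,
        pfi_duration_mean=8.0,
        pfi_duration_sd=1.0,
        coupling=0.0,
        rate_heterogeneity=0.2,
        duration_heterogeneity=0.1,
    )
    profiles = {
        "f1": ModulationProfile(0.5, -0.3, -0.24, -0.52),
        "f2": ModulationProfile(0.5, -0.3 - lead, 0.5, -0.10),
        "im": ModulationProfile(0.0, -0.83, 0.0, 0.73),
        "alpha": ModulationProfile(0.0, -0.14, 0.0, 0.35, saturating=True),
    }
    n_channels = 12
    topo = default_topographies(n_channels)
    window = (-epoch_half_width, epoch_half_width)

    courses: dict[float, dict[str, list]] = {
        cfg.f1: {"dis": [], "rea": []},
        cfg.f2: {"dis": [], "rea": []},
    }
    times = None
    root = np.random.SeedSequence(seed)
    for pss in root.spawn(n_participants):
        eeg = EEGParams(
            n_channels=n_channels,
            modulation_profiles=dict(profiles),
            latency_jitter_sd=0.0,
            depth_jitter_sd=0.0,
        )
        _, _, truth, recordings = simulate_participant(cfg, behavior, eeg, pss)
        for freq, name in ((cfg.f1, "f1"), (cfg.f2, "f2")):
            channel = int(np.argmax(topo[name]))
            dis, rea = [], []
            for rec, events in zip(recordings, truth.report_events):
                for ev in pfi_events(events):
                    try:
                        seg = epoch_signal(
                            rec.samples[channel], ev.time, window, rec.sample_rate
                        )
                    except ValueError:
                        continue
                    if seg is None:
                        continue
                    (dis if ev.kind == "disappearance" else rea).append(seg[0])
            for label, segs in (("dis", dis), ("rea", rea)):
                tc = snr_timecourse(
                    np.stack(segs),
                    eeg.sample_rate,
                    freq,
                    epoch_start=window[0],
                )
                courses[freq][label].append(tc.log_snr)
                times = tc.times

    onsets = {}
    for freq in (cfg.f1, cfg.f2):
        est = jackknife_latencies(
            np.stack(courses[freq]["dis"]),
            np.stack(courses[freq]["rea"]),
            times,
            frequency=freq,
        )
        onsets[freq] = est.median
    if onsets[cfg.f1] is None or onsets[cfg.f2] is None:
        return None
    return onsets[cfg.f1] - onsets[cfg.f2]


def recover_alpha_suppression(
    depth: float,
    seed: int,
    n_trials: int = 70,
) -> tuple[float, int]:
    """Inject an event-locked alpha suppression and read it back.

    Sparse, long, uncoupled events keep the -2.5..-1.5 s baseline window of
    each epoch free of other events; the suppression is measured on the
    plateau (0.3-1.2 s after the report, inside the modulation span) of the
    baseline-normalized Hilbert envelope at the alpha-dominant channel.
    Returns (recovered depth, number of events used).
    """
    cfg = StimulusConfig(n_trials=n_trials, trial_duration=60.0)
    behavior = BehaviorParams(
        pfi_onset_rate=0.012,
        pfi_duration_mean=5.0,
        pfi_duration_sd=1.0,
        coupling=0.0,
        rate_heterogeneity=0.0,
        duration_heterogeneity=0.0,
    )
    profiles = {
        "f1": ModulationProfile(0.5, -0.43, -0.24, -0.52),
        "f2": ModulationProfile(0.5, -1.22, 0.5, -0.10),
        "im": ModulationProfile(0.5, -0.83, 0.5, 0.73),
        "alpha": ModulationProfile(
            -depth, -0.14, -0.1, 0.35, span=2.0, saturating=True
        ),
    }
    n_channels = 8
    eeg = EEGParams(
        n_channels=n_channels,
        modulation_profiles=profiles,
        latency_jitter_sd=0.0,
        depth_jitter_sd=0.0,
    )
    _, _, truth, recordings = simulate_participant(cfg, behavior, eeg, seed)
    topo = default_topographies(n_channels)
    channel = int(np.argmax(topo["alpha"]))
    params = AlphaParams()

    envelopes = []
    for rec, events in zip(recordings, truth.report_events):
        for ev in pfi_events(events):
            if ev.kind != "disappearance":
                continue
            if any(abs(o.time - ev.time) < 3.0 and o is not ev for o in events):
                continue  # isolation: keep the baseline window clean
            try:
                seg = epoch_signal(
                    rec.samples[channel], ev.time, params.epoch_window, rec.sample_rate
                )
            except ValueError:
                continue
            if seg is None:
                continue
            envelopes.append(alpha_envelope(seg[0], rec.sample_rate, params))
    envelopes = np.stack(envelopes)
    rel = params.epoch_window[0] + np.arange(envelopes.shape[-1]) / eeg.sample_rate
    normalized = baseline_normalize(envelopes, rel, params)
    return suppression_depth(normalized, rel, window=(0.3, 1.2)), len(envelopes)


def screen_synthetic_pair(seed: int, n_boot: int = 200) -> tuple[bool, bool]:
    """Run the PMD screening analysis on one responder and one
    non-responder observer.

    Uses a moderate filling-in rate (0.02 /s/target, heterogeneity off)
    where the bootstrap-CI reaction-time procedure has full power; at very
    heavy PFI rates a non-responder's spontaneous presses become genuinely
    indistinguishable from removal reports.  Returns
    (responder retained, non-responder excluded).
    """
    cfg = StimulusConfig(n_trials=24, trial_duration=60.0)
    reaction_times = {}
    for label, responder in (("responder", True), ("non_responder", False)):
        behavior = BehaviorParams(
            responder=responder,
            pfi_onset_rate=0.02,
            rate_heterogeneity=0.0,
            duration_heterogeneity=0.0,
        )
        pmds, traces, _, _ = simulate_participant(
            cfg, behavior, None, seed * 2 + int(responder)
        )
        null = beh.bootstrap_pmd_null(traces, pmds, n_boot=n_boot, seed=seed)
        rel, observed = beh.observed_pmd_timecourse(traces, pmds)
        reaction_times[label] = beh.pmd_reaction_time(rel, observed, null)
    retained, _ = beh.exclude_participants(reaction_times)
    return "responder" in retained, "non_responder" not in retained
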