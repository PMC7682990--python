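"""Core data types shared by all analysis stages.

The experiment these types describe: four peripheral flickering targets are
superimposed on a dynamic texture background.  The texture inside each target
refreshes at ``f1`` (15 Hz), the surround at ``f2`` (20 Hz), so targets and
surround each drive a steady-state visually evoked potential (SSVEP) at their
own frequency, with a possible intermodulation (IM) component at ``f2 - f1``
(5 Hz) produced by nonlinear interaction.  Participants hold down one of four
buttons for as long as the corresponding target is perceptually filled in
(PFI, subjectively invisible).  Each trial also embeds one catch event in
which one to four targets are physically removed from the screen (a
phenomenally matched disappearance, PMD) used to validate report behavior and
as a control condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusConfig",
    "BehaviorParams",
    "ModulationProfile",
    "EEGParams",
    "PMDSchedule",
    "PFIEvent",
    "ReportEvent",
    "GroundTruth",
    "ButtonTrace",
    "TrialRecording",
    "EventEpoch",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus and session layout.

    ``f1`` tags the targets, ``f2`` the surround; the intermodulation
    frequency is ``f2 - f1`` by construction.  The frame grid on which button
    reports live must be commensurate with all tag frequencies.
    """

    n_targets: int = 4
    trial_duration: float = 60.0
    n_trials: int = 48
    frame_rate: float = 60.0
    f1: float = 15.0
    f2: float = 20.0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not self.f1 < self.f2:
            raise ValueError(f"f1 ({self.f1}) must be below f2 ({self.f2})")
        for f in (self.f1, self.f2, self.im):
            ratio = self.frame_rate / f
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"frame_rate {self.frame_rate} not divisible by {f} Hz"
                )
        n_frames = self.trial_duration * self.frame_rate
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("trial_duration * frame_rate must be an integer")

    @property
    def im(self) -> float:
        """Intermodulation (difference) frequency in Hz."""
        return self.f2 - self.f1

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the simulated observer.

    pfi_onset_rate
        Rate of spontaneous filling-in onsets, events per second per target
        (Poisson).
    pfi_duration_mean, pfi_duration_sd
        Mean and SD (seconds) of the log-normal invisibility durations.
    coupling
        Probability in [0, 1] that a filling-in onset recruits each other
        target, emulating the grouping in which targets disappear together
        more often than independence predicts.
    report_lag_mean, report_lag_sd
        Gaussian report latency (seconds), truncated at zero; applied to both
        filling-in and physical-removal reports.
    responder
        Whether the simulated observer reports physical removals at all.
        Non-responders model participants who cannot track four targets and
        should be caught by the PMD screening analysis.
    """

    pfi_onset_rate: float = 0.05
    pfi_duration_mean: float = 4.0
    pfi_duration_sd: float = 1.0
    coupling: float = 0.35
    report_lag_mean: float = 0.7
    report_lag_sd: float = 0.2
    responder: bool = True
    #: between-participant spread (SD of a log-normal scale factor) of the
    #: onset rate and of the duration mean, reflecting the large individual
    #: differences in the amount of filling-in real cohorts show
    rate_heterogeneity: float = 0.4
    duration_heterogeneity: float = 0.3

    def __post_init__(self) -> None:
        if self.pfi_onset_rate < 0:
            raise ValueError("pfi_onset_rate must be nonnegative")
        if self.pfi_duration_mean < 0 or self.pfi_duration_sd < 0:
            raise ValueError("durations must be nonnegative")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.report_lag_sd < 0:
            raise ValueError("report_lag_sd must be nonnegative")


@dataclass(frozen=True)
class ModulationProfile:
    """Transient event-locked amplitude modulation of one spectral component.

    Each report transition triggers a transient gain excursion: a press
    adds a raised-cosine bump of ``depth`` (fractional change), a release
    subtracts one, so the component's gain rises (or falls) around
    disappearance reports and moves oppositely around reappearances before
    returning to baseline.  ``latency_*`` is the excursion onset in seconds
    relative to the report (negative = the neural change precedes the
    report); the bump ramps over ``rise_time`` s, holds for ``span`` s and
    decays over another ``rise_time``.  Contributions from simultaneously
    invisible targets add, except for saturating components (the alpha
    rhythm, whose suppression does not stack) where the summed drive is
    clipped to [-1, 1].
    """

    depth_pfi: float
    latency_pfi: float
    depth_pmd: float
    latency_pmd: float
    rise_time: float = 0.3
    span: float = 1.0
    saturating: bool = False


def _default_profiles() -> dict[str, ModulationProfile]:
    # Signs and latencies follow the empirical pattern the analyses are
    # designed to detect: during PFI the surround (f2) response rises well
    # before the report and the target (f1) response rises shortly before it;
    # during physical removal the order reverses and the target response
    # falls instead.  Alpha shows event-locked suppression.
    return {
        "f1": ModulationProfile(0.5, -0.43, -0.24, -0.52),
        "f2": ModulationProfile(0.5, -1.22, 0.5, -0.10),
        "im": ModulationProfile(0.5, -0.83, 0.5, 0.73),
        "alpha": ModulationProfile(-0.20, -0.14, -0.10, 0.35, saturating=True),
    }


@dataclass
class EEGParams:
    """Forward model of the synthetic EEG.

    Each spectral component (f1, f2, im, alpha, plus a broadband noise
    source) projects to the sensors through a fixed topography; its amplitude
    is modulated around report events per :class:`ModulationProfile`.  The IM
    component is not an injected sinusoid: it is produced by a static
    half-wave rectification of the summed f1 + f2 drives (scaled by
    ``nonlinearity_gain``), which provably creates energy at ``f2 - f1``.
    """

    n_channels: int = 64
    sample_rate: float = 250.0
    source_topographies: dict[str, np.ndarray] | None = None
    modulation_profiles: dict[str, ModulationProfile] = field(
        default_factory=_default_profiles
    )
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    nonlinearity_gain: float = 0.4
    alpha_amplitude: float = 2.0
    #: between-participant variability of modulation onset latencies (s) and
    #: fractional variability of modulation depths, mirroring the spread of
    #: onset estimates across real participants
    latency_jitter_sd: float = 0.15
    depth_jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.source_topographies is not None:
            for name, topo in self.source_topographies.items():
                if np.asarray(topo).shape != (self.n_channels,):
                    raise ValueError(
                        f"topography {name!r} must have {self.n_channels} entries"
                    )

    def validate_rate(self, config: StimulusConfig) -> None:
        if self.sample_rate <= 2 * config.f2:
            raise ValueError("sample_rate must exceed 2 * f2")


@dataclass(frozen=True)
class PMDSchedule:
    """One physical-removal catch event.

    ``onset`` is the removal time S in trial seconds; ``removed_targets``
    indexes the targets taken off the screen (0-based).
    """

    onset: float
    duration: float
    removed_targets: tuple[int, ...]
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be nonnegative")
        if len(set(self.removed_targets)) != len(self.removed_targets):
            raise ValueError("removed_targets must be unique")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class PFIEvent:
    """A true (ground-truth) invisibility interval of one target."""

    target: int
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError("offset must be >= onset")


@dataclass(frozen=True)
class ReportEvent:
    """A button transition: press = reported disappearance, release =
    reported reappearance.  ``source`` is filled in by classification
    against the PMD schedule ('pfi' or 'pmd'); ``excluded`` flags PFI events
    whose guarded window touches a PMD period."""

    kind: str  # 'disappearance' | 'reappearance'
    target: int
    time: float
    frame: int
    trial_index: int = 0
    source: str | None = None
    excluded: bool = False


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests.

    ``pfi_events[trial]`` lists the true invisibility intervals;
    ``report_events[trial]`` the lagged button transitions with their source
    labels; modulation latencies and the alpha suppression depth echo the
    EEG parameters used.
    """

    pfi_events: list[list[PFIEvent]]
    report_events: list[list[ReportEvent]]
    modulation_latencies: dict[str, float] = field(default_factory=dict)
    alpha_suppression_depth: float = 0.0


@dataclass
class ButtonTrace:
    """Per-trial binary visibility report on the stimulus frame grid.

    ``pressed[target, frame] == 1`` means the target was reported invisible
    during that frame.
    """

    pressed: np.ndarray
    frame_rate: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.pressed = np.asarray(self.pressed)
        if self.pressed.ndim != 2:
            raise ValueError("pressed must be targets x frames")
        if not np.isin(self.pressed, (0, 1)).all():
            raise ValueError("pressed must be binary")
        self.pressed = self.pressed.astype(np.uint8)

    @property
    def n_targets(self) -> int:
        return self.pressed.shape[0]

    @property
    def n_frames(self) -> int:
        return self.pressed.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class TrialRecording:
    """Continuous multichannel EEG of one trial (channels x samples)."""

    samples: np.ndarray
    sample_rate: float
    channel_labels: Sequence[str]
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EventEpoch:
    """An analysis epoch around one report event.

    ``n_pfi`` counts simultaneously invisible targets at the alignment frame;
    ``amount`` is the duration-weighted button count over the 3 s window
    (the "amount of PFI", 0-4).
    """

    kind: str  # pfi_disappearance | pfi_reappearance | pmd_onset | pmd_offset
    align_time: float
    window: tuple[float, float]
    target: int | None = None
    n_pfi: int = 0
    amount: float | None = None
    trial_index: int = 0
    participant: int | str | None = None

    def __post_init__(self) -> None:
        if self.amount is not None and not 0.0 <= self.amount <= 4.0 + 1e-9:
            raise ValueError("amount must lie in [0, 4]")
        if not 0 <= self.n_pfi <= 4:
            raise ValueError("n_pfi must lie in [0, 4]")
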