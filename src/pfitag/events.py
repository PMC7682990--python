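"""Report-event extraction, PMD classification, and signal epoching.

Time conventions: trial time is 0-based seconds; a report event is
attributed to the first frame of the new state (press = first pressed
frame); epochs are half-open sample windows [start, end) with the alignment
time mapped to the nearest sample at or after the event.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ButtonTrace, EventEpoch, PMDSchedule, ReportEvent, TrialRecording

__all__ = [
    "detect_report_events",
    "classify_and_filter_events",
    "pfi_events",
    "pmd_events",
    "epoch_signal",
    "ress_training_windows",
]

logger = logging.getLogger(__name__)

#: Default guard (s) around a PMD period inside which an event cannot be
#: treated as PFI; equals the 3 s epoch half-width so no PFI epoch contains
#: PMD-contaminated samples.
DEFAULT_PMD_GUARD = 3.0


def detect_report_events(trace: ButtonTrace) -> list[ReportEvent]:
    """Extract button transitions from a binary visibility trace.

    A 0->1 transition is a reported disappearance, 1->0 a reported
    reappearance.  A press already held at trial start yields no
    disappearance event; one held through trial end yields no reappearance.
    """
    if not np.isin(trace.pressed, (0, 1)).all():
        raise ValueError("trace must be binary")
    events: list[ReportEvent] = []
    for target in range(trace.n_targets):
        row = trace.pressed[target].astype(np.int8)
        d = np.diff(row)
        for frame in np.flatnonzero(d == 1) + 1:
            events.append(
                ReportEvent(
                    kind="disappearance",
                    target=target,
                    time=float(frame) / trace.frame_rate,
                    frame=int(frame),
                    trial_index=trace.trial_index,
                )
            )
        for frame in np.flatnonzero(d == -1) + 1:
            events.append(
                ReportEvent(
                    kind="reappearance",
                    target=target,
                    time=float(frame) / trace.frame_rate,
                    frame=int(frame),
                    trial_index=trace.trial_index,
                )
            )
    events.sort(key=lambda e: (e.time, e.target))
    return events


def classify_and_filter_events(
    events: list[ReportEvent],
    pmd: PMDSchedule,
    guard: float = DEFAULT_PMD_GUARD,
) -> list[ReportEvent]:
    """Label events as PMD-evoked or PFI, avoiding PMD periods.

    An event at a removed target whose time falls inside
    ``[S - guard, S + duration + guard]`` is PMD-evoked.  Any other event is
    PFI; PFI events inside the guarded interval (at non-removed targets) are
    flagged ``excluded`` so PFI analyses can drop them.
    """
    lo = pmd.onset - guard
    hi = pmd.offset + guard
    out: list[ReportEvent] = []
    for ev in events:
        inside = bool(lo <= ev.time <= hi)
        if inside and ev.target in pmd.removed_targets:
            source, excluded = "pmd", False
        else:
            source, excluded = "pfi", inside
        out.append(
            ReportEvent(
                kind=ev.kind,
                target=ev.target,
                time=ev.time,
                frame=ev.frame,
                trial_index=ev.trial_index,
                source=source,
                excluded=excluded,
            )
        )
    return out


def pfi_events(events: list[ReportEvent]) -> list[ReportEvent]:
    """PFI-labeled events that survived PMD exclusion."""
    return [e for e in events if e.source == "pfi" and not e.excluded]


def pmd_events(events: list[ReportEvent]) -> list[ReportEvent]:
    return [e for e in events if e.source == "pmd"]


def epoch_signal(
    recording: TrialRecording | np.ndarray,
    align_time: float,
    window: tuple[float, float],
    sample_rate: float | None = None,
) -> np.ndarray | None:
    """Cut a channels x time segment around an alignment time.

    The sample at relative time 0 is the recording's sample at (or just
    after) ``align_time``; the window is half-open in samples.  Returns None
    (with a logged reason) when the window spills over a trial edge, and
    raises when it lies entirely outside the trial.
    """
    if isinstance(recording, TrialRecording):
        data = recording.samples
        fs = recording.sample_rate
    else:
        data = np.atleast_2d(np.asarray(recording))
        if sample_rate is None:
            raise ValueError("sample_rate required for bare arrays")
        fs = sample_rate
    n = data.shape[-1]
    w0, w1 = window
    if not w0 < w1:
        raise ValueError("window start must precede window end")
    align = int(np.ceil(align_time * fs - 1e-9))
    start = align + int(round(w0 * fs))
    stop = align + int(round(w1 * fs))
    if stop <= 0 or start >= n:
        raise ValueError("epoch window lies entirely outside the trial")
    if start < 0 or stop > n:
        logger.info(
            "dropping epoch at %.3f s: window [%g, %g] exceeds trial bounds",
            align_time,
            w0,
            w1,
        )
        return None
    return data[..., start:stop]


def ress_training_windows(
    recording: TrialRecording,
    events: list[ReportEvent],
    inner: float = 0.1,
    outer: float = 3.0,
) -> list[np.ndarray]:
    """Epochs used to train RESS filters: [-outer, -inner] and [inner, outer]
    around every press/release, PMD periods avoided (only non-excluded PFI
    events are used), pooled without condition labels."""
    segments: list[np.ndarray] = []
    for ev in pfi_events(events):
        for win in ((-outer, -inner), (inner, outer)):
            try:
                seg = epoch_signal(recording, ev.time, win)
            except ValueError:
                continue
            if seg is not None:
                segments.append(seg)
    return segments


def n_pfi_at(trace: ButtonTrace, time: float) -> int:
    """Number of simultaneously invisible (pressed) targets at a time point."""
    frame = min(int(np.ceil(time * trace.frame_rate - 1e-9)), trace.n_frames - 1)
    return int(trace.pressed[:, frame].sum())
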