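"""Readers and writers for the package's portable file formats.

Events and PMD schedules travel as TSV tables, EEG as an HDF5 array
container (trials x channels x samples) with a JSON sidecar, ground truth as
JSON.  Optional readers for BrainVision and EDF interchange formats are thin
wrappers over :mod:`mne` and only require it when called.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    ButtonTrace,
    GroundTruth,
    PFIEvent,
    PMDSchedule,
    ReportEvent,
    TrialRecording,
)

__all__ = [
    "report_intervals",
    "write_events_tsv",
    "read_events_tsv",
    "write_pmd_tsv",
    "read_pmd_tsv",
    "write_eeg_h5",
    "read_eeg_h5",
    "write_ground_truth_json",
    "read_raw_brainvision",
    "read_raw_edf",
]


def report_intervals(trace: ButtonTrace) -> pd.DataFrame:
    """Press/release intervals of one trial as a table.

    Columns: trial, target, press_onset_s, press_offset_s.  An interval held
    through trial end gets offset NaN.
    """
    rows = []
    for target in range(trace.n_targets):
        row = trace.pressed[target].astype(np.int8)
        padded = np.concatenate([[0], row])
        d = np.diff(padded)
        onsets = np.flatnonzero(d == 1)
        offsets = np.flatnonzero(d == -1)
        for i, on in enumerate(onsets):
            off = offsets[i] if i < len(offsets) else None
            rows.append(
                {
                    "trial": trace.trial_index,
                    "target": target,
                    "press_onset_s": on / trace.frame_rate,
                    "press_offset_s": (
                        off / trace.frame_rate if off is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["trial", "target", "press_onset_s", "press_offset_s"])


def write_events_tsv(events: list[ReportEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "trial": e.trial_index,
                "target": e.target,
                "kind": e.kind,
                "time_s": e.time,
                "frame": e.frame,
                "source": e.source if e.source is not None else "",
                "excluded": int(e.excluded),
            }
            for e in events
        ],
        columns=["trial", "target", "kind", "time_s", "frame", "source", "excluded"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events_tsv(path: str | Path) -> list[ReportEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    return [
        ReportEvent(
            kind=str(r.kind),
            target=int(r.target),
            time=float(r.time_s),
            frame=int(r.frame),
            trial_index=int(r.trial),
            source=str(r.source) or None,
            excluded=bool(int(r.excluded)),
        )
        for r in df.itertuples()
    ]


def write_pmd_tsv(pmds: list[PMDSchedule], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "trial": p.trial_index,
                "onset_s": p.onset,
                "duration_s": p.duration,
                "removed_targets": ";".join(str(t) for t in p.removed_targets),
            }
            for p in pmds
        ],
        columns=["trial", "onset_s", "duration_s", "removed_targets"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pmd_tsv(path: str | Path) -> list[PMDSchedule]:
    df = pd.read_csv(
        path, sep="\t", dtype={"removed_targets": str}, float_precision="round_trip"
    )
    return [
        PMDSchedule(
            onset=float(r.onset_s),
            duration=float(r.duration_s),
            removed_targets=tuple(int(t) for t in str(r.removed_targets).split(";")),
            trial_index=int(r.trial),
        )
        for r in df.itertuples()
    ]


def write_eeg_h5(
    recordings: list[TrialRecording],
    path: str | Path,
    config_echo: dict | None = None,
) -> None:
    """Store trials x channels x samples plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.stack([r.samples for r in recordings])
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=data)
        f.attrs["sample_rate"] = recordings[0].sample_rate
    sidecar = {
        "sample_rate": recordings[0].sample_rate,
        "channel_labels": list(recordings[0].channel_labels),
        "n_trials": len(recordings),
        "config": config_echo or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_eeg_h5(path: str | Path) -> list[TrialRecording]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        data = f["eeg"][()]
        fs = float(f.attrs["sample_rate"])
    return [
        TrialRecording(
            samples=data[i],
            sample_rate=fs,
            channel_labels=sidecar["channel_labels"],
            trial_index=i,
        )
        for i in range(data.shape[0])
    ]


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "pfi_events": [
            [dataclasses.asdict(e) for e in trial] for trial in truth.pfi_events
        ],
        "report_events": [
            [dataclasses.asdict(e) for e in trial] for trial in truth.report_events
        ],
        "modulation_latencies": truth.modulation_latencies,
        "alpha_suppression_depth": truth.alpha_suppression_depth,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        pfi_events=[
            [PFIEvent(**e) for e in trial] for trial in payload["pfi_events"]
        ],
        report_events=[
            [ReportEvent(**e) for e in trial] for trial in payload["report_events"]
        ],
        modulation_latencies=payload["modulation_latencies"],
        alpha_suppression_depth=payload["alpha_suppression_depth"],
    )


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading interchange EEG formats requires the optional 'mne' "
            "dependency (pip install pfitag[eeg-io])"
        ) from exc
    return mne


def read_raw_brainvision(vhdr_path: str | Path):
    """Continuous BrainVision recording (+ annotations) via mne."""
    mne = _require_mne()
    return mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")


def read_raw_edf(edf_path: str | Path):
    """Continuous EDF recording (+ annotations) via mne."""
    mne = _require_mne()
    return mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
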