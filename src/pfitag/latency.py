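"""Onset-latency estimation for SNR time-course contrasts.

The onset of a condition difference is the first time point of a
temporally contiguous run of pointwise-significant paired t-tests lasting
at least 500 ms, computed after linearly interpolating the participant
time courses from the spectrogram step grid (250 ms) to a 1 ms grid.
Reliability is assessed by leave-one-participant-out jackknifing: the
onset is recomputed on every subsample and the distribution of estimates
(median, SD, and the jackknife-inflated SE) is reported.  Peak-based
latency criteria are deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cluster import running_paired_t

__all__ = [
    "interpolate_timecourse",
    "first_significant_timepoint",
    "LatencyEstimate",
    "jackknife_latencies",
    "compare_latency_distributions",
]


def interpolate_timecourse(
    times: np.ndarray,
    values: np.ndarray,
    target_step: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a dense grid spanning the original range.

    ``values`` may be 1-D or participants x time; endpoints are preserved
    exactly and original grid points are reproduced where the dense grid
    hits them.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    n_dense = int(round((times[-1] - times[0]) / target_step)) + 1
    dense = times[0] + target_step * np.arange(n_dense)
    dense[-1] = times[-1]  # guard against rounding drift at the far end
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        out = np.interp(dense, times, values)
    else:
        out = np.vstack([np.interp(dense, times, row) for row in values])
    return dense, out


def first_significant_timepoint(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    min_duration: float = 0.5,
    p_thresh: float = 0.05,
    target_step: float | None = 0.001,
) -> float | None:
    """Earliest start of a contiguous significant run of >= min_duration.

    Running paired two-tailed t-tests at each (interpolated) time point;
    pointwise uncorrected p < ``p_thresh`` defines significance.  Each
    participant's time course is interpolated individually before testing
    (``target_step=None`` disables interpolation).  Returns None when no
    qualifying run exists.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    times = np.asarray(times, dtype=float)
    if target_step is not None:
        dense, a = interpolate_timecourse(times, a, target_step)
        _, b = interpolate_timecourse(times, b, target_step)
        times = dense
    _, p = running_paired_t(a, b)
    sig = p < p_thresh
    dt = float(np.median(np.diff(times)))
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return None
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        if run.size * dt >= min_duration - 1e-12:
            return float(times[run[0]])
    return None


@dataclass
class LatencyEstimate:
    """Leave-one-out onset estimates for one frequency/condition contrast.

    ``estimates[i]`` is the onset with participant i left out (None when no
    qualifying run survived).  ``sd`` is the raw SD over defined subsample
    estimates; ``jackknife_se`` applies the (N-1)/N variance inflation
    appropriate for leave-one-out statistics.  Both are reported because
    plain subsample SDs understate jackknife variability.
    """

    estimates: list[float | None]
    median: float | None
    sd: float | None
    jackknife_se: float | None
    frequency: float | None = None
    condition: str = ""

    @property
    def n_undefined(self) -> int:
        return sum(e is None for e in self.estimates)

    @property
    def fraction_undefined(self) -> float:
        return self.n_undefined / len(self.estimates)


def jackknife_latencies(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    min_duration: float = 0.5,
    p_thresh: float = 0.05,
    target_step: float | None = 0.001,
    frequency: float | None = None,
    condition: str = "",
) -> LatencyEstimate:
    """Recompute the first significant time point on every leave-one-out
    subsample of participants."""
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least three participants to jackknife")
    estimates: list[float | None] = []
    for leave in range(n):
        keep = np.arange(n) != leave
        estimates.append(
            first_significant_timepoint(
                a[keep], b[keep], times, min_duration, p_thresh, target_step
            )
        )
    defined = np.array([e for e in estimates if e is not None], dtype=float)
    if defined.size:
        median = float(np.median(defined))
        sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
        m = defined.size
        jackknife_se = float(
            np.sqrt((m - 1) / m * ((defined - defined.mean()) ** 2).sum())
        )
    else:
        median = sd = jackknife_se = None
    return LatencyEstimate(
        estimates=estimates,
        median=median,
        sd=sd,
        jackknife_se=jackknife_se,
        frequency=frequency,
        condition=condition,
    )


def compare_latency_distributions(
    estimates_a: LatencyEstimate, estimates_b: LatencyEstimate
) -> dict:
    """Paired t-test and Wilcoxon signed-rank test over matched subsamples.

    Subsamples where either estimate is undefined are dropped, with the
    count reported.
    """
    if len(estimates_a.estimates) != len(estimates_b.estimates):
        raise ValueError("estimates must come from matched subsamples")
    pairs = [
        (x, y)
        for x, y in zip(estimates_a.estimates, estimates_b.estimates)
        if x is not None and y is not None
    ]
    n_dropped = len(estimates_a.estimates) - len(pairs)
    if len(pairs) < 3:
        raise ValueError("fewer than three defined subsample pairs")
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    diffs = xs - ys
    if np.allclose(diffs, 0.0):
        t_stat, t_p = 0.0, 1.0
        w_stat, w_p = np.nan, 1.0
    else:
        t_stat, t_p = stats.ttest_rel(xs, ys)
        try:
            w_stat, w_p = stats.wilcoxon(xs, ys)
        except ValueError:
            w_stat, w_p = np.nan, 1.0
    return {
        "n_pairs": len(pairs),
        "n_dropped": n_dropped,
        "t": float(t_stat),
        "t_p": float(t_p),
        "wilcoxon": float(w_stat),
        "wilcoxon_p": float(w_p),
        "mean_difference": float(diffs.mean()),
    }
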