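"""Behavioral statistics around the button-report data.

Two null-distribution constructions anchor this module.  The PMD bootstrap
null estimates each participant's baseline press likelihood by epoching
[S-2, S+4] s of button data at the removed-target locations from randomly
redrawn trials (T' may equal T), repeated per bootstrap set; the reaction
time to a physical removal is the first post-onset time at which the
observed median press time course exceeds the logit-based 95% CI of that
null, and participants with no such crossing within 2 s are excluded.  The
location-shuffling null destroys temporal correlation between target
locations by rebuilding trials from per-location traces drawn from random
trials, against which the quadratic trend of PFI characteristics over the
number of simultaneously invisible targets (nPFI) is tested.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .types import ButtonTrace, PMDSchedule, ReportEvent

__all__ = [
    "BootstrapNull",
    "bootstrap_pmd_null",
    "observed_pmd_timecourse",
    "pmd_reaction_time",
    "exclude_participants",
    "reject_failed_pmd_trials",
    "shuffle_locations",
    "npfi_duration_profile",
    "shuffled_npfi_profiles",
    "ShuffleResult",
    "quadratic_null_test",
    "amount_of_pfi",
    "sort_and_resample",
    "bin_by_amount",
]

logger = logging.getLogger(__name__)

PMD_EPOCH_WINDOW = (-2.0, 4.0)


def _relative_frames(frame_rate: float, window=PMD_EPOCH_WINDOW) -> np.ndarray:
    return np.arange(
        int(round(window[0] * frame_rate)), int(round(window[1] * frame_rate))
    )


def _pmd_epoch_matrix(
    traces: list[ButtonTrace], pmds: list[PMDSchedule], window=PMD_EPOCH_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """E[p, t'] = press likelihood time course when PMD p's epoch window and
    removed-target locations are read out of trial t'.

    Samples outside the trial are NaN and ignored by later averaging.
    Returns (E, relative_times) with E of shape (n_pmd, n_trials, n_rel).
    """
    fr = traces[0].frame_rate
    n_frames = traces[0].n_frames
    rel = _relative_frames(fr, window)
    pressed = np.stack([t.pressed for t in traces]).astype(float)
    E = np.full((len(pmds), len(traces), rel.size), np.nan)
    for p, pmd in enumerate(pmds):
        onset_frame = int(np.ceil(pmd.onset * fr - 1e-9))
        frames = onset_frame + rel
        valid = (frames >= 0) & (frames < n_frames)
        rows = list(pmd.removed_targets)
        E[p][:, valid] = pressed[:, rows][:, :, frames[valid]].mean(axis=1)
    return E, rel / fr


@dataclass
class BootstrapNull:
    """Bootstrap null of press likelihood around PMD onset.

    ``mean_timecourse`` is the null-average press likelihood on the
    relative-time grid; the CI bounds come from z = +-1.96 on the
    logit-transformed null set means, back-transformed.
    """

    rel_times: np.ndarray
    mean_timecourse: np.ndarray
    upper_ci: np.ndarray
    lower_ci: np.ndarray
    n_boot: int
    null: np.ndarray = field(repr=False, default=None)


def bootstrap_pmd_null(
    traces: list[ButtonTrace],
    pmds: list[PMDSchedule],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    window: tuple[float, float] = PMD_EPOCH_WINDOW,
    method: str = "bootstrap",
    max_exhaustive: int = 100_000,
) -> BootstrapNull:
    """Baseline press-likelihood null for PMD-response screening.

    One bootstrap set draws, for every real PMD, a random trial T' (with
    replacement; T' = T allowed) and epochs its button data at the removed
    target locations; the mean time course of each of ``n_boot`` sets forms
    the null.  ``method='exhaustive'`` enumerates every possible draw
    combination instead (only feasible for toy problems) and is the oracle
    the bootstrap converges to.
    """
    if len(traces) < 2:
        raise ValueError("need at least two trials")
    E, rel_times = _pmd_epoch_matrix(traces, pmds, window)
    n_pmd, n_trials, n_rel = E.shape

    if method == "exhaustive":
        if n_trials**n_pmd > max_exhaustive:
            raise ValueError("exhaustive enumeration infeasible at this size")
        combos = np.array(
            list(itertools.product(range(n_trials), repeat=n_pmd)), dtype=int
        )
        null = np.stack(
            [np.nanmean(E[np.arange(n_pmd), c], axis=0) for c in combos]
        )
    elif method == "bootstrap":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        null = np.empty((n_boot, n_rel))
        for b in range(n_boot):
            draws = rng.integers(0, n_trials, size=n_pmd)
            null[b] = np.nanmean(E[np.arange(n_pmd), draws], axis=0)
    else:
        raise ValueError("method must be 'bootstrap' or 'exhaustive'")

    # logit CI; clip against degenerate all-zero / all-one likelihoods
    eps = 1.0 / (2.0 * n_pmd)
    trans = logit(np.clip(null, eps, 1.0 - eps))
    mu = trans.mean(axis=0)
    sd = trans.std(axis=0, ddof=0)
    upper = expit(mu + 1.96 * sd)
    lower = expit(mu - 1.96 * sd)
    return BootstrapNull(
        rel_times=rel_times,
        mean_timecourse=null.mean(axis=0),
        upper_ci=upper,
        lower_ci=lower,
        n_boot=null.shape[0],
        null=null,
    )


def observed_pmd_timecourse(
    traces: list[ButtonTrace],
    pmds: list[PMDSchedule],
    window: tuple[float, float] = PMD_EPOCH_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Median across PMD events of each event's own press time course
    (per-event mean over its removed targets)."""
    E, rel_times = _pmd_epoch_matrix(traces, pmds, window)
    own = E[np.arange(len(pmds)), [p.trial_index for p in pmds]]
    return rel_times, np.nanmedian(own, axis=0)


def pmd_reaction_time(
    rel_times: np.ndarray,
    observed: np.ndarray,
    null: BootstrapNull,
) -> float | None:
    """First relative time after PMD onset at which the observed median
    press likelihood exceeds the null's upper CI; None if it never does."""
    rel_times = np.asarray(rel_times)
    observed = np.asarray(observed)
    if rel_times.shape != null.rel_times.shape or not np.allclose(
        rel_times, null.rel_times
    ):
        raise ValueError("observed and null are on different relative-time grids")
    after = rel_times > 0
    exceed = after & (observed > null.upper_ci)
    idx = np.flatnonzero(exceed)
    return float(rel_times[idx[0]]) if idx.size else None


def exclude_participants(
    reaction_times: dict, criterion: float = 2.0
) -> tuple[list, list[dict]]:
    """Drop participants with no PMD reaction time within the criterion.

    The boundary is inclusive: RT exactly equal to the criterion is
    retained.  Returns (retained ids, audit log).
    """
    retained, audit = [], []
    for pid, rt in reaction_times.items():
        keep = rt is not None and rt <= criterion
        audit.append(
            {
                "participant": pid,
                "reaction_time": rt,
                "excluded": not keep,
                "criterion_s": criterion,
            }
        )
        if keep:
            retained.append(pid)
    return retained, audit


def reject_failed_pmd_trials(
    traces: list[ButtonTrace],
    pmds: list[PMDSchedule],
    threshold: float = 0.5,
) -> tuple[list[int], list[int]]:
    """Reject trials whose PMD was not adequately reported.

    For each removed target, the fraction of the PMD window during which
    its button was held is computed; the trial fails if ANY removed
    target's fraction is below the threshold (inclusive boundary: exactly
    50% passes).  Returns (retained trial indices, rejected).
    """
    retained, rejected = [], []
    for trace, pmd in zip(traces, pmds):
        fr = trace.frame_rate
        i0 = max(int(np.ceil(pmd.onset * fr - 1e-9)), 0)
        i1 = min(int(np.ceil(pmd.offset * fr - 1e-9)), trace.n_frames)
        ok = True
        for target in pmd.removed_targets:
            frac = trace.pressed[target, i0:i1].mean() if i1 > i0 else 0.0
            if frac < threshold:
                ok = False
                break
        (retained if ok else rejected).append(trace.trial_index)
    return retained, rejected


# ---------------------------------------------------------------------------
# location shuffling and the quadratic nPFI test
# ---------------------------------------------------------------------------

def shuffle_locations(
    traces: list[ButtonTrace],
    n_shuffle: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw indices for location-shuffled trial sets.

    Each shuffled trial takes, independently per target location, that
    location's press time course from a uniformly random real trial (with
    replacement).  Returns an (n_shuffle, n_trials, n_targets) index array
    into the trial dimension; the traces themselves are materialized lazily
    by :func:`shuffled_npfi_profiles`.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n_trials = len(traces)
    n_targets = traces[0].n_targets
    return rng.integers(0, n_trials, size=(n_shuffle, n_trials, n_targets))


def npfi_duration_profile(pressed: np.ndarray, frame_rate: float) -> np.ndarray:
    """Total duration (s) spent at each simultaneity level nPFI = 0..n_targets.

    ``pressed`` is (n_trials, n_targets, n_frames) binary.
    """
    pressed = np.asarray(pressed)
    n_targets = pressed.shape[1]
    counts = pressed.sum(axis=1).ravel().astype(int)
    return np.bincount(counts, minlength=n_targets + 1) / frame_rate


def shuffled_npfi_profiles(
    traces: list[ButtonTrace], shuffle_idx: np.ndarray
) -> np.ndarray:
    """nPFI duration profiles of every shuffled set, (n_shuffle, n_levels)."""
    pressed = np.stack([t.pressed for t in traces])
    fr = traces[0].frame_rate
    n_trials, n_targets, _ = pressed.shape
    cols = np.arange(n_targets)
    out = np.empty((shuffle_idx.shape[0], n_targets + 1))
    for s in range(shuffle_idx.shape[0]):
        shuffled = pressed[shuffle_idx[s], cols[None, :], :]
        out[s] = npfi_duration_profile(shuffled, fr)
    return out


@dataclass
class ShuffleResult:
    """Observed vs location-shuffled quadratic trend over nPFI levels."""

    observed_stat: np.ndarray
    null_stats: np.ndarray
    observed_beta: float
    null_betas: np.ndarray
    p: float
    significant: bool
    p_report: str = ""


def quadratic_null_test(
    observed_values: np.ndarray,
    null_values: np.ndarray,
    levels: np.ndarray | None = None,
) -> ShuffleResult:
    """Permutation test on the quadratic coefficient over nPFI levels.

    A 2nd-order polynomial is least-squares fit to value vs nPFI; the
    quadratic coefficient beta of the observed data is compared against the
    distribution of betas from the shuffled sets.  The add-one convention
    p = (r + 1) / (n + 1) is used, and the effect is significant when the
    observed beta exceeds the null's 95th percentile.  The nPFI axis is
    centered before fitting for conditioning; the quadratic coefficient is
    unchanged by that shift.
    """
    observed = np.asarray(observed_values, dtype=float)
    null = np.atleast_2d(np.asarray(null_values, dtype=float))
    if levels is None:
        levels = np.arange(observed.size, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need at least three distinct nPFI levels for a quadratic fit")
    x = levels - levels.mean()
    beta_obs = float(np.polyfit(x, observed, 2)[0])
    null_betas = np.polyfit(x, null.T, 2)[0]
    r = int((null_betas >= beta_obs - 1e-12).sum())
    n = null_betas.size
    p = (r + 1) / (n + 1)
    significant = beta_obs > np.percentile(null_betas, 95)
    p_report = f"p < {1 / n:g}" if r == 0 else f"p = {p:g}"
    return ShuffleResult(
        observed_stat=observed,
        null_stats=null,
        observed_beta=beta_obs,
        null_betas=np.asarray(null_betas),
        p=p,
        significant=significant,
        p_report=p_report,
    )


# ---------------------------------------------------------------------------
# amount of PFI
# ---------------------------------------------------------------------------

AMOUNT_WINDOW = 3.0


def amount_of_pfi(trace: ButtonTrace, event: ReportEvent) -> float | None:
    """Duration-weighted number of buttons pressed over the 3 s window.

    The window is [0, +3] s after a press (disappearance) and [-3, 0] s
    before a release (reappearance); the amount is the mean over the window
    of the instantaneous pressed-button count (range 0 to n_targets).
    Events whose window leaves the trial are dropped (None).
    """
    fr = trace.frame_rate
    nw = int(round(AMOUNT_WINDOW * fr))
    if event.kind == "disappearance":
        i0, i1 = event.frame, event.frame + nw
    elif event.kind == "reappearance":
        i0, i1 = event.frame - nw, event.frame
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    if i0 < 0 or i1 > trace.n_frames:
        logger.info("dropping event at %.3f s: amount window leaves trial", event.time)
        return None
    return float(trace.pressed[:, i0:i1].sum() / nw)


def sort_and_resample(
    amounts: np.ndarray,
    companion: np.ndarray | None = None,
    target_count: int = 100,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Sort events by descending amount and resample to a fixed row count.

    The event axis is linearly interpolated along the sorted index so every
    participant contributes exactly ``target_count`` rows; companion signals
    (e.g. per-event SNR time courses) are reordered by the same sort and
    resampled identically along the event axis.
    """
    amounts = np.asarray(amounts, dtype=float)
    if amounts.size == 0:
        raise ValueError("no events to resample")
    order = np.argsort(-amounts, kind="stable")
    sorted_amounts = amounts[order]
    n = sorted_amounts.size
    xp = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    x = np.linspace(0.0, 1.0, target_count)
    if n == 1:
        resampled = np.full(target_count, sorted_amounts[0])
    else:
        resampled = np.interp(x, xp, sorted_amounts)
    resampled_companion = None
    if companion is not None:
        companion = np.asarray(companion, dtype=float)[order]
        if n == 1:
            resampled_companion = np.repeat(companion, target_count, axis=0)
        else:
            resampled_companion = np.column_stack(
                [np.interp(x, xp, companion[:, j]) for j in range(companion.shape[1])]
            )
    return resampled, resampled_companion


AMOUNT_BIN_EDGES = (0.0, 1.0, 2.0, 3.0, 4.0)


def bin_by_amount(amounts: np.ndarray) -> list[np.ndarray]:
    """Partition events into the four amount-of-PFI groups
    (0,1], (1,2], (2,3], (3,4]; zero-amount events are excluded."""
    amounts = np.asarray(amounts, dtype=float)
    n_zero = int((amounts <= 0).sum())
    if n_zero:
        logger.info("excluding %d zero-amount events from binning", n_zero)
    groups = []
    for lo, hi in zip(AMOUNT_BIN_EDGES[:-1], AMOUNT_BIN_EDGES[1:]):
        groups.append(np.flatnonzero((amounts > lo) & (amounts <= hi)))
    return groups
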