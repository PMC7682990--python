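"""Behavioral statistics: PMD bootstrap null, screening rules, location
shuffling, the quadratic nPFI test, and amount-of-PFI machinery."""

import numpy as np
import pytest

from pfitag import behavior as beh
from pfitag.types import ButtonTrace, PMDSchedule, ReportEvent


def trace_from(rows, frame_rate=2.0, trial_index=0):
    return ButtonTrace(
        pressed=np.asarray(rows, dtype=np.uint8),
        frame_rate=frame_rate,
        trial_index=trial_index,
    )


class TestBootstrapNull:
    def test_constant_press_probability_recovered(self, rng):
        """With exchangeable Bernoulli(p) traces the null mean is ~p at
        every relative time."""
        p = 0.3
        fr = 10.0
        traces = [
            ButtonTrace(rng.random((2, 200)) < p, frame_rate=fr, trial_index=i)
            for i in range(6)
        ]
        pmds = [
            PMDSchedule(onset=8.0, duration=4.0, removed_targets=(0, 1), trial_index=i)
            for i in range(6)
        ]
        null = beh.bootstrap_pmd_null(traces, pmds, n_boot=400, seed=1)
        # exchangeability: the expected null mean at relative time r is the
        # cross-trial mean of the traces at the onset-shifted frame, which is
        # itself ~p; compare against that exact expectation
        rel = np.arange(int(-2 * fr), int(4 * fr))
        pressed = np.stack([t.pressed for t in traces]).astype(float)
        expected = pressed[:, :, int(8.0 * fr) + rel].mean(axis=(0, 1))
        np.testing.assert_allclose(null.mean_timecourse, expected, atol=0.06)
        assert abs(null.mean_timecourse.mean() - p) < 0.05
        assert np.all(null.upper_ci >= null.mean_timecourse - 1e-9)

    def test_same_seed_reproducible(self, rng):
        traces = [
            ButtonTrace(rng.random((2, 100)) < 0.5, frame_rate=10.0, trial_index=i)
            for i in range(4)
        ]
        pmds = [
            PMDSchedule(onset=5.0, duration=3.5, removed_targets=(0,), trial_index=i)
            for i in range(4)
        ]
        n1 = beh.bootstrap_pmd_null(traces, pmds, n_boot=50, seed=7)
        n2 = beh.bootstrap_pmd_null(traces, pmds, n_boot=50, seed=7)
        np.testing.assert_array_equal(n1.null, n2.null)

    def test_two_trial_toy_matches_exhaustive_enumeration(self):
        """On a 2-trial toy problem the bootstrap null mean converges to the
        exhaustive enumeration over all trial draws, and the exhaustive mode
        reproduces the hand enumeration exactly."""
        fr = 2.0  # window [-2, 4] s -> frames -4..7
        t0 = trace_from([[0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1]])
        t1 = trace_from([[1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0]], trial_index=1)
        pmds = [
            PMDSchedule(onset=2.0, duration=1.0, removed_targets=(0,), trial_index=0),
            PMDSchedule(onset=3.0, duration=1.0, removed_targets=(0,), trial_index=1),
        ]
        exhaustive = beh.bootstrap_pmd_null([t0, t1], pmds, method="exhaustive")
        # hand enumeration: 2 PMDs x 2 candidate trials = 4 epoch rows;
        # the null mean is the average over all (draw0, draw1) assignments,
        # i.e. the mean of the four epoch rows.
        rel = np.arange(-4, 8)
        rows = []
        for pmd in pmds:
            for tr in (t0, t1):
                frames = int(np.ceil(pmd.onset * fr)) + rel
                row = np.full(rel.size, np.nan)
                ok = (frames >= 0) & (frames < 16)
                row[ok] = tr.pressed[0, frames[ok]]
                rows.append(row)
        expected = np.nanmean(rows, axis=0)
        np.testing.assert_allclose(exhaustive.mean_timecourse, expected, atol=1e-12)
        boot = beh.bootstrap_pmd_null([t0, t1], pmds, n_boot=4000, seed=3)
        np.testing.assert_allclose(boot.mean_timecourse, expected, atol=0.05)

    def test_requires_two_trials(self):
        t = trace_from([[0, 1]])
        with pytest.raises(ValueError):
            beh.bootstrap_pmd_null([t], [PMDSchedule(0.5, 0.5, (0,))])


class TestReactionTimeAndExclusion:
    def test_observed_below_ci_gives_none(self):
        null = beh.BootstrapNull(
            rel_times=np.linspace(-2, 4, 13),
            mean_timecourse=np.full(13, 0.5),
            upper_ci=np.full(13, 0.9),
            lower_ci=np.full(13, 0.1),
            n_boot=10,
        )
        rt = beh.pmd_reaction_time(null.rel_times, np.full(13, 0.2), null)
        assert rt is None

    def test_first_crossing_after_onset_returned(self):
        rel = np.linspace(-2, 4, 25)
        null = beh.BootstrapNull(
            rel_times=rel,
            mean_timecourse=np.full(25, 0.1),
            upper_ci=np.full(25, 0.5),
            lower_ci=np.full(25, 0.0),
            n_boot=10,
        )
        observed = np.where(rel >= 0.75, 1.0, 0.6)  # above CI only from 0.75
        observed[rel <= 0] = 0.9  # pre-onset exceedance must be ignored
        rt = beh.pmd_reaction_time(rel, observed, null)
        assert rt == pytest.approx(0.25)  # first positive time, 0.9 > 0.5

    def test_grid_mismatch_rejected(self):
        null = beh.BootstrapNull(
            rel_times=np.linspace(-2, 4, 13),
            mean_timecourse=np.zeros(13),
            upper_ci=np.ones(13),
            lower_ci=np.zeros(13),
            n_boot=1,
        )
        with pytest.raises(ValueError):
            beh.pmd_reaction_time(np.linspace(-2, 4, 14), np.zeros(14), null)

    def test_exclusion_rules_and_inclusive_boundary(self):
        rts = {"p1": 0.68, "p2": None, "p3": 2.0, "p4": 2.5}
        retained, audit = beh.exclude_participants(rts, criterion=2.0)
        assert retained == ["p1", "p3"]
        excluded = {a["participant"] for a in audit if a["excluded"]}
        assert excluded == {"p2", "p4"}


class TestTrialRejection:
    def make(self, frac, fr=10.0):
        """Trace pressing the button for `frac` of a 2 s PMD at t=4."""
        pressed = np.zeros((1, 100), dtype=np.uint8)
        n = int(round(frac * 20))
        pressed[0, 40 : 40 + n] = 1
        trace = ButtonTrace(pressed, frame_rate=fr)
        pmd = PMDSchedule(onset=4.0, duration=2.0, removed_targets=(0,))
        return trace, pmd

    @pytest.mark.parametrize(
        "frac,kept", [(1.0, True), (0.4, False), (0.5, True)]
    )
    def test_threshold_with_inclusive_boundary(self, frac, kept):
        trace, pmd = self.make(frac)
        retained, rejected = beh.reject_failed_pmd_trials([trace], [pmd])
        assert (0 in retained) == kept

    def test_any_failed_button_rejects_multi_target_trial(self):
        pressed = np.zeros((2, 100), dtype=np.uint8)
        pressed[0, 40:60] = 1  # full window
        pressed[1, 40:45] = 1  # 25% only
        trace = ButtonTrace(pressed, frame_rate=10.0)
        pmd = PMDSchedule(onset=4.0, duration=2.0, removed_targets=(0, 1))
        retained, rejected = beh.reject_failed_pmd_trials([trace], [pmd])
        assert rejected == [0]


class TestShuffleLocations:
    def test_single_trial_shuffles_reproduce_observed(self, rng):
        t = ButtonTrace(rng.random((4, 50)) < 0.4, frame_rate=10.0)
        idx = beh.shuffle_locations([t], n_shuffle=20, seed=0)
        profiles = beh.shuffled_npfi_profiles([t], idx)
        observed = beh.npfi_duration_profile(t.pressed[None], 10.0)
        for row in profiles:
            np.testing.assert_allclose(row, observed)

    def test_press_time_conserved_in_expectation(self, rng):
        traces = [
            ButtonTrace(rng.random((4, 100)) < 0.3, frame_rate=10.0, trial_index=i)
            for i in range(6)
        ]
        idx = beh.shuffle_locations(traces, n_shuffle=500, seed=1)
        pressed = np.stack([t.pressed for t in traces]).astype(float)
        observed_per_loc = pressed.sum(axis=(0, 2))
        cols = np.arange(4)
        tot = np.zeros(4)
        for s in range(idx.shape[0]):
            tot += pressed[idx[s], cols[None, :], :].sum(axis=(0, 2))
        np.testing.assert_allclose(tot / idx.shape[0], observed_per_loc, rtol=0.1)

    def test_coupled_simultaneity_exceeds_shuffled_null(self):
        """With full coupling the observed 4-target simultaneity beats the
        95th percentile of the location-shuffled null."""
        from pfitag import BehaviorParams, StimulusConfig
        from pfitag.simulate import generate_button_traces, generate_pmd_schedule

        cfg = StimulusConfig(n_trials=12, trial_duration=30.0)
        pmds = generate_pmd_schedule(cfg, 5)
        traces, _ = generate_button_traces(
            cfg,
            BehaviorParams(coupling=1.0, responder=False),
            pmds,
            seed=5,
        )
        observed = beh.npfi_duration_profile(
            np.stack([t.pressed for t in traces]), cfg.frame_rate
        )[4]
        idx = beh.shuffle_locations(traces, n_shuffle=200, seed=6)
        null = beh.shuffled_npfi_profiles(traces, idx)[:, 4]
        assert observed > np.percentile(null, 95)


class TestQuadraticNullTest:
    levels = np.arange(5.0)

    def test_exact_parabola_recovers_coefficient(self):
        values = 2.0 * self.levels**2
        null = np.tile(values, (50, 1)) - 1.0
        res = beh.quadratic_null_test(values, null, self.levels)
        assert res.observed_beta == pytest.approx(2.0, abs=1e-9)

    def test_linear_values_give_zero_beta(self):
        values = 3.0 * self.levels + 1.0
        null = np.tile(values, (50, 1))
        res = beh.quadratic_null_test(values, null, self.levels)
        assert res.observed_beta == pytest.approx(0.0, abs=1e-9)

    def test_addone_pvalue_and_reporting_convention(self, rng):
        values = 5.0 * self.levels**2
        null = rng.standard_normal((1000, 5))  # betas near 0
        res = beh.quadratic_null_test(values, null, self.levels)
        assert res.p == pytest.approx(1.0 / 1001.0)
        assert res.significant
        assert res.p_report == "p < 0.001"

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            beh.quadratic_null_test(
                np.array([1.0, 2.0]), np.zeros((10, 2)), np.array([0.0, 1.0])
            )


class TestAmountOfPfi:
    def press_event(self, frame, fr):
        return ReportEvent(
            kind="disappearance", target=0, time=frame / fr, frame=frame
        )

    def test_all_buttons_held_gives_four(self):
        fr = 10.0
        trace = ButtonTrace(np.ones((4, 100), dtype=np.uint8), frame_rate=fr)
        ev = self.press_event(30, fr)
        assert beh.amount_of_pfi(trace, ev) == pytest.approx(4.0)

    def test_half_window_single_button_gives_half(self):
        fr = 10.0
        pressed = np.zeros((4, 100), dtype=np.uint8)
        pressed[0, 30:45] = 1  # 1.5 s of the 3 s window
        trace = ButtonTrace(pressed, frame_rate=fr)
        ev = self.press_event(30, fr)
        assert beh.amount_of_pfi(trace, ev) == pytest.approx(0.5)

    def test_matches_frame_scan_oracle(self, rng):
        fr = 10.0
        pressed = (rng.random((4, 200)) < 0.4).astype(np.uint8)
        trace = ButtonTrace(pressed, frame_rate=fr)
        ev = self.press_event(50, fr)
        got = beh.amount_of_pfi(trace, ev)
        total = 0
        for f in range(50, 80):
            for tgt in range(4):
                total += pressed[tgt, f]
        assert got == pytest.approx(total / 30)
        # reappearance variant: [-3, 0] before the release frame
        ev_r = ReportEvent(kind="reappearance", target=0, time=5.0, frame=50)
        got_r = beh.amount_of_pfi(trace, ev_r)
        total_r = pressed[:, 20:50].sum()
        assert got_r == pytest.approx(total_r / 30)

    def test_window_outside_trial_dropped(self):
        fr = 10.0
        trace = ButtonTrace(np.ones((4, 40), dtype=np.uint8), frame_rate=fr)
        assert beh.amount_of_pfi(trace, self.press_event(20, fr)) is None

    def test_amount_never_exceeds_target_count(self, rng):
        fr = 10.0
        trace = ButtonTrace((rng.random((4, 300)) < 0.9).astype(np.uint8), frame_rate=fr)
        for frame in range(0, 260, 13):
            got = beh.amount_of_pfi(trace, self.press_event(frame, fr))
            if got is not None:
                assert 0.0 <= got <= 4.0


class TestSortAndResample:
    def test_exactly_hundred_events_identity(self, rng):
        amounts = rng.uniform(0, 4, 100)
        resampled, _ = beh.sort_and_resample(amounts, target_count=100)
        np.testing.assert_allclose(resampled, np.sort(amounts)[::-1])

    def test_identical_events_stay_identical(self):
        resampled, comp = beh.sort_and_resample(
            np.full(50, 2.5), companion=np.full((50, 7), 1.5), target_count=100
        )
        np.testing.assert_allclose(resampled, 2.5)
        assert comp.shape == (100, 7)
        np.testing.assert_allclose(comp, 1.5)

    def test_linear_amounts_resample_linearly(self):
        amounts = np.linspace(0.0, 4.0, 200)
        resampled, _ = beh.sort_and_resample(amounts, target_count=100)
        assert resampled[0] == pytest.approx(4.0)
        assert resampled[-1] == pytest.approx(0.0)
        np.testing.assert_allclose(resampled, np.linspace(4.0, 0.0, 100), atol=1e-9)

    def test_companion_rows_follow_the_same_sort(self, rng):
        amounts = rng.uniform(0, 4, 30)
        companion = amounts[:, None] * np.ones((30, 5))
        resampled, comp = beh.sort_and_resample(amounts, companion, target_count=30)
        np.testing.assert_allclose(comp[:, 0], resampled, atol=1e-9)


class TestBinByAmount:
    def test_examples_and_boundaries(self):
        groups = beh.bin_by_amount(np.array([0.5, 3.5, 1.0, 2.0, 3.0, 4.0, 0.0]))
        assert 0 in groups[0] and 2 in groups[0]  # (0, 1]
        assert 3 in groups[1]  # (1, 2]
        assert 4 in groups[2]  # (2, 3]
        assert 1 in groups[3] and 5 in groups[3]  # (3, 4]
        assert all(6 not in g for g in groups)  # zero amount excluded

    def test_partition_matches_threshold_oracle(self, rng):
        amounts = rng.uniform(0, 4, 500)
        groups = beh.bin_by_amount(amounts)
        for gi, (lo, hi) in enumerate(zip((0, 1, 2, 3), (1, 2, 3, 4))):
            expected = np.flatnonzero((amounts > lo) & (amounts <= hi))
            np.testing.assert_array_equal(groups[gi], expected)
        covered = np.concatenate(groups)
        assert covered.size == (amounts > 0).sum()
        assert np.unique(covered).size == covered.size
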