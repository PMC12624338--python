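"""Exclusion rule, windowed accuracy, chance-level tests and time courses."""

import math

import numpy as np
import pytest
from scipy import stats

from lwl_echo import (
    AlignedTrial,
    AnalysisConfig,
    StimulusTiming,
    TargetWord,
    TrialGaze,
    GazeFrame,
    analyze_aligned,
    build_task,
    exclude_low_data,
    on_screen_fraction,
    pooled_window_accuracy,
    run_pipeline,
    time_course,
    trial_type_summary,
    window_accuracy,
    yoke_pairs,
)
from lwl_echo.analysis import WindowAccuracy


def aligned(roles, frame_ms=33.0, t0=0.0, trial_number=1, trial_type="carrier1"):
    """Build an aligned trial from a role sequence starting at t_rel = t0."""
    return AlignedTrial(
        trial_number=trial_number,
        trial_type=trial_type,
        frames=[(t0 + i * frame_ms, r) for i, r in enumerate(roles)],
        onset_ms=0.0,
    )


def trial_with_fraction(frac, n=100, trial_number=1):
    n_on = round(frac * n)
    roles = ["target"] * n_on + ["away"] * (n - n_on)
    return aligned(roles, trial_number=trial_number)


class TestExclusion:
    def test_fully_on_screen_trial_is_kept(self):
        kept, dropped = exclude_low_data([trial_with_fraction(1.0)])
        assert len(kept) == 1 and not dropped

    def test_40_percent_on_screen_is_dropped(self):
        kept, dropped = exclude_low_data([trial_with_fraction(0.40)])
        assert not kept and len(dropped) == 1
        assert "0.400" in dropped[0][1]

    def test_boundary_and_oracle(self):
        """Exactly-at-threshold trials are kept (strict 'less than')."""
        fracs = [0.30, 0.50, 0.49, 0.51]
        trials = [trial_with_fraction(f, trial_number=i) for i, f in enumerate(fracs)]
        kept, _ = exclude_low_data(trials)
        oracle = [t for t in trials if on_screen_fraction(t) >= 0.5]
        assert kept == oracle
        assert sorted(on_screen_fraction(t) for t in kept) == [0.50, 0.51]

    def test_denominator_is_the_whole_trial(self):
        # plenty of on-screen frames inside the window, but the whole-trial
        # fraction is below threshold
        roles = ["target"] * 10 + ["off"] * 90
        kept, dropped = exclude_low_data([aligned(roles, t0=300.0)])
        assert not kept and len(dropped) == 1


class TestWindowAccuracy:
    def test_all_target_frames_give_accuracy_one(self):
        acc = window_accuracy(aligned(["target"] * 45, t0=300.0))
        assert acc.accuracy == 1.0

    def test_equal_counts_give_chance(self):
        acc = window_accuracy(aligned(["target", "distractor"] * 20, t0=300.0))
        assert acc.accuracy == 0.5

    def test_scripted_45_frame_trial_matches_manual_tally(self):
        # 45 frames at 33 ms from t_rel = 300: pattern of 4 roles repeating
        pattern = ["target", "target", "distractor", "away"]
        roles = [pattern[i % 4] for i in range(45)]
        acc = window_accuracy(aligned(roles, t0=300.0))
        n_t = sum(1 for i in range(45) if roles[i] == "target" and 300 + i * 33 < 1800)
        n_d = sum(1 for i in range(45) if roles[i] == "distractor" and 300 + i * 33 < 1800)
        assert (acc.n_target_frames, acc.n_distractor_frames) == (n_t, n_d)
        assert acc.accuracy == pytest.approx(n_t / (n_t + n_d), abs=1e-15)

    def test_window_is_half_open_by_default(self):
        tr = AlignedTrial(1, "carrier1", [(300.0, "target"), (1800.0, "distractor")], 0.0)
        assert window_accuracy(tr).accuracy == 1.0
        closed = AnalysisConfig(boundary="closed")
        assert window_accuracy(tr, closed).accuracy == 0.5

    def test_empty_window_is_undefined_not_an_error(self):
        acc = window_accuracy(aligned(["away"] * 50, t0=300.0))
        assert acc.accuracy is None

    def test_matches_brute_force_tally_on_random_trials(self):
        rng = np.random.default_rng(2024)
        config = AnalysisConfig()
        for _ in range(300):
            n = int(rng.integers(1, 150))
            t0 = float(rng.uniform(-600, 400))
            step = float(rng.uniform(20, 50))
            roles = list(rng.choice(["target", "distractor", "away", "off"], size=n))
            tr = aligned(roles, frame_ms=step, t0=t0)
            acc = window_accuracy(tr, config)
            sel = [r for t, r in tr.frames if 300 <= t < 1800 and r in ("target", "distractor")]
            if not sel:
                assert acc.accuracy is None
            else:
                expect = sel.count("target") / len(sel)
                assert acc.accuracy == pytest.approx(expect, abs=1e-12)

    def test_away_frames_never_change_accuracy(self):
        rng = np.random.default_rng(7)
        base = list(rng.choice(["target", "distractor"], size=40))
        tr = aligned(base, t0=300.0)
        ref = window_accuracy(tr).accuracy
        # interleave away/off frames at arbitrary times inside the window
        noisy_frames = list(tr.frames) + [(float(t), "away") for t in rng.uniform(300, 1790, 25)]
        noisy_frames += [(float(t), "off") for t in rng.uniform(300, 1790, 25)]
        noisy = AlignedTrial(1, "carrier1", sorted(noisy_frames), 0.0)
        assert window_accuracy(noisy).accuracy == pytest.approx(ref, abs=1e-15)

    def test_mirror_flip_leaves_accuracy_unchanged(self):
        """Flipping every code and the target side preserves accuracy."""
        rng = np.random.default_rng(11)
        roles = list(rng.choice(["target", "distractor", "away"], size=60))
        tr = aligned(roles, t0=300.0)
        # mirror: roles are a pure function of (code, side); flipping both
        # leaves roles, hence accuracy, unchanged
        swap = {"target": "distractor", "distractor": "target", "away": "away"}
        double_flip = aligned([swap[swap[r]] for r in roles], t0=300.0)
        assert window_accuracy(double_flip).accuracy == window_accuracy(tr).accuracy


def accs(values, trial_type="carrier1"):
    return [
        WindowAccuracy(i, trial_type, v, 1, 1) if v is not None else
        WindowAccuracy(i, trial_type, None, 0, 0)
        for i, v in enumerate(values)
    ]


class TestTrialTypeSummary:
    def test_all_chance_accuracies_give_t_zero(self):
        res = trial_type_summary(accs([0.5, 0.5, 0.5]))
        assert res.t_stat == 0.0 and not res.significant_above_chance

    def test_textbook_vector(self):
        """(0.6, 0.7, 0.8): mean 0.7, sd 0.1 -> t = 0.2/(0.1/sqrt(3)) ~ 3.464."""
        res = trial_type_summary(accs([0.6, 0.7, 0.8]))
        assert res.mean_accuracy == pytest.approx(0.7)
        assert res.t_stat == pytest.approx(0.2 / (0.1 / math.sqrt(3)), abs=1e-12)
        assert res.df == 2

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            vals = rng.uniform(0.05, 0.95, size=int(rng.integers(3, 40)))
            res = trial_type_summary(accs(list(vals)))
            ref_t, ref_p = stats.ttest_1samp(vals, 0.5)
            assert res.t_stat == pytest.approx(float(ref_t), abs=1e-10)
            assert res.p_value == pytest.approx(float(ref_p), abs=1e-10)

    def test_undefined_accuracies_are_excluded(self):
        res = trial_type_summary(accs([0.6, None, 0.8, None]))
        assert res.n_trials == 2

    def test_insufficient_trials_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient trials"):
            trial_type_summary(accs([0.7, None]))

    def test_mixed_trial_types_rejected(self):
        bad = accs([0.6, 0.7]) + accs([0.8, 0.9], trial_type="carrier2")
        with pytest.raises(ValueError, match="one trial type"):
            trial_type_summary(bad)

    def test_zero_variance_above_chance_is_significant_by_construction(self):
        res = trial_type_summary(accs([1.0, 1.0, 1.0]))
        assert res.significant_above_chance
        assert "zero variance" in res.note

    def test_report_line_mirrors_reporting_style(self):
        line = trial_type_summary(accs([0.6, 0.7, 0.8])).report_line()
        assert "mean accuracy 70.00%" in line and "t = 3.46" in line

    def test_frame_pooled_unit(self):
        weighted = [
            WindowAccuracy(1, "carrier1", 0.9, 9, 1),
            WindowAccuracy(2, "carrier1", 0.5, 30, 30),
        ]
        res = trial_type_summary(weighted, AnalysisConfig(test_unit="frames"))
        assert res.mean_accuracy == pytest.approx(39 / 70)
        assert res.df == 69


class TestTimeCourse:
    def test_single_all_target_trial_is_flat_one(self):
        tc = time_course([aligned(["target"] * 60, t0=0.0)])["carrier1"]
        vals = [p for p, n in zip(tc.proportion_to_target, tc.n_frames) if n > 0]
        assert vals and all(v == 1.0 for v in vals)

    def test_mirrored_trials_give_flat_chance(self):
        a = aligned(["target"] * 60, t0=0.0, trial_number=1)
        b = aligned(["distractor"] * 60, t0=0.0, trial_number=2)
        tc = time_course([a, b])["carrier1"]
        vals = [p for p, n in zip(tc.proportion_to_target, tc.n_frames) if n > 0]
        assert vals and all(v == 0.5 for v in vals)

    def test_matches_independent_group_by(self):
        rng = np.random.default_rng(31)
        trials = [
            aligned(
                list(rng.choice(["target", "distractor", "away"], size=90)),
                t0=-500.0,
                trial_number=i,
            )
            for i in range(8)
        ]
        config = AnalysisConfig(bin_ms=100.0)
        tc = time_course(trials, config)["carrier1"]
        # independent recomputation with a flat table + floor-division group-by
        rows = [
            (math.floor((t - config.plot_start_ms) / 100.0), r)
            for tr in trials
            for t, r in tr.frames
            if r in ("target", "distractor") and config.plot_start_ms <= t < config.plot_end_ms
        ]
        for b in range(len(tc.bin_centers_ms)):
            grp = [r for bb, r in rows if bb == b]
            if not grp:
                assert math.isnan(tc.proportion_to_target[b])
            else:
                assert tc.proportion_to_target[b] == pytest.approx(
                    grp.count("target") / len(grp), abs=1e-12
                )

    def test_window_weighted_mean_equals_frame_pooled_accuracy(self):
        """Conservation between the two summaries: the per-bin time course,
        weighted by its denominators, reproduces the pooled window accuracy
        when the bins tile the window exactly."""
        rng = np.random.default_rng(13)
        trials = [
            aligned(
                list(rng.choice(["target", "distractor", "away"], size=70)),
                t0=float(rng.uniform(-100, 350)),
                trial_number=i,
            )
            for i in range(10)
        ]
        config = AnalysisConfig(bin_ms=100.0, plot_start_ms=300.0, plot_end_ms=1800.0)
        tc = time_course(trials, config)["carrier1"]
        num = sum(
            p * n for p, n in zip(tc.proportion_to_target, tc.n_frames) if n > 0
        )
        den = sum(tc.n_frames)
        assert num / den == pytest.approx(pooled_window_accuracy(trials, config), abs=1e-12)


def session_inputs(n_dropped=6):
    """A 36-trial session with `n_dropped` trials engineered off-screen."""
    words = [TargetWord(f"w{i}", "noun") for i in range(12)]
    task = build_task(yoke_pairs(words, seed=4))
    timings = [StimulusTiming(t.audio_script, 500.0) for t in task.trials]
    gaze = []
    for t in task.trials:
        if t.trial_number <= n_dropped:
            codes = ["away"] * 90
        else:
            good = t.target_side
            bad = "left" if good == "right" else "right"
            codes = [good if i % 4 else bad for i in range(90)]
        gaze.append(
            TrialGaze(t.trial_number, [GazeFrame(i * 33.0, c) for i, c in enumerate(codes)])
        )
    return task, gaze, timings


class TestPipeline:
    def test_reports_30_usable_of_36(self):
        task, gaze, timings = session_inputs(n_dropped=6)
        report = run_pipeline(task, gaze, timings)
        assert report.n_trials == 36
        assert report.n_kept == 30 and report.n_dropped == 6
        assert "36 total, 30 usable, 6 excluded" in report.to_text()

    def test_same_inputs_give_byte_identical_reports(self, tmp_path):
        task, gaze, timings = session_inputs()
        for name in ("a", "b"):
            run_pipeline(task, gaze, timings).write(tmp_path / name, figure=False)
        for f in ("per_trial.csv", "summary.csv", "time_course.csv", "report.txt"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_empty_gaze_stage_error(self, tmp_path):
        from lwl_echo import read_frame_codes

        f = tmp_path / "empty.csv"
        f.write_text("trial_number,t_ms,code\n")
        assert read_frame_codes(f) == []

    def test_figure_written(self, tmp_path):
        task, gaze, timings = session_inputs()
        run_pipeline(task, gaze, timings).write(tmp_path, figure=True)
        assert (tmp_path / "time_course.png").stat().st_size > 0
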