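"""Windowed proportion-of-looks analysis with chance-level testing.

Given onset-aligned trials the analysis proceeds in four steps:

1. **Exclusion** — drop trials in which the child looked at the screen
   (either image) for less than 50% of the total trial.
2. **Window accuracy** — per kept trial, the proportion of looks to target
   vs. distractor, ``n_target / (n_target + n_distractor)``, over frames in
   the analytical window 300–1,800 ms after the critical onset.  Away/off
   frames enter neither numerator nor denominator, so chance is 0.5.
3. **Trial-type summary** — mean accuracy per trial type and a one-sample
   Student t-test against chance; "above chance" requires a two-sided
   p < alpha *and* a mean above chance.
4. **Time course** — the pooled proportion of looks to target per time bin,
   for plotting against time since target onset.

The unit of analysis for the t-test defaults to per-trial window accuracies
(df = n_trials - 1); a frame-pooled alternative is available via
``AnalysisConfig.test_unit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaze import AlignedTrial, StimulusTiming, TrialGaze, align_session
from .task import TRIAL_TYPES, TaskStructure


@dataclass
class AnalysisConfig:
    """Analysis parameters (times in ms relative to the critical onset)."""

    window_start_ms: float = 300.0
    window_end_ms: float = 1800.0
    screen_threshold: float = 0.5
    chance: float = 0.5
    bin_ms: float = 33.0
    #: "half_open" counts frames with window_start <= t < window_end;
    #: "closed" also includes t == window_end.
    boundary: str = "half_open"
    #: t-test unit: "trials" (per-trial accuracies) or "frames"
    #: (pooled binary frame vector).
    test_unit: str = "trials"
    alpha: float = 0.05
    plot_start_ms: float = -500.0
    plot_end_ms: float = 2500.0

    def __post_init__(self) -> None:
        if not (0 <= self.window_start_ms < self.window_end_ms):
            raise ValueError("require 0 <= window_start_ms < window_end_ms")
        if not (0 < self.screen_threshold <= 1):
            raise ValueError("screen_threshold must be in (0, 1]")
        if not (0 < self.chance < 1):
            raise ValueError("chance must be in (0, 1)")
        if self.boundary not in ("half_open", "closed"):
            raise ValueError("boundary must be 'half_open' or 'closed'")
        if self.test_unit not in ("trials", "frames"):
            raise ValueError("test_unit must be 'trials' or 'frames'")


@dataclass
class WindowAccuracy:
    """Proportion of looks to target within the analytical window of one
    trial; ``accuracy`` is None when no target/distractor frame falls in the
    window."""

    trial_number: int
    trial_type: str
    accuracy: Optional[float]
    n_target_frames: int
    n_distractor_frames: int


@dataclass
class TrialTypeResult:
    """Mean windowed accuracy and chance-level test for one trial type."""

    trial_type: str
    n_trials: int
    mean_accuracy: float
    t_stat: float
    df: int
    p_value: float
    significant_above_chance: bool
    note: str = ""

    def report_line(self, chance: float = 0.5) -> str:
        p = "p < 0.001" if self.p_value < 0.001 else f"p = {self.p_value:.3f}"
        return (
            f"{self.trial_type}: mean accuracy {100 * self.mean_accuracy:.2f}% "
            f"(n = {self.n_trials}, t = {self.t_stat:.2f}, df = {self.df}, {p}; "
            f"{'above' if self.significant_above_chance else 'not above'} "
            f"chance {chance:g})"
        )


@dataclass
class TimeCourse:
    """Pooled proportion of looks to target per time bin for one trial type."""

    trial_type: str
    bin_centers_ms: list[float]
    proportion_to_target: list[float]  # NaN where no trial contributes
    n_contributing_trials: list[int]
    #: per-bin pooled target+distractor frame counts (the proportions'
    #: denominators), so windowed summaries can be reconciled exactly
    n_frames: list[int]


# ---------------------------------------------------------------------------
# Exclusion
# ---------------------------------------------------------------------------


def on_screen_fraction(trial: AlignedTrial) -> float:
    """Fraction of the trial's frames spent looking at either image."""
    n = len(trial.frames)
    if n == 0:
        raise ValueError(f"trial {trial.trial_number} has no frames")
    on = sum(1 for _, role in trial.frames if role in ("target", "distractor"))
    return on / n


def exclude_low_data(
    trials: Sequence[AlignedTrial], config: AnalysisConfig = AnalysisConfig()
) -> tuple[list[AlignedTrial], list[tuple[AlignedTrial, str]]]:
    """Drop trials with on-screen fraction strictly below the threshold.

    The denominator is the *whole* trial (all frames, pre-onset included);
    exact equality with the threshold is kept.
    """
    kept: list[AlignedTrial] = []
    dropped: list[tuple[AlignedTrial, str]] = []
    for t in trials:
        frac = on_screen_fraction(t)
        if frac < config.screen_threshold:
            dropped.append(
                (t, f"on-screen fraction {frac:.3f} < {config.screen_threshold:g}")
            )
        else:
            kept.append(t)
    return kept, dropped


# ---------------------------------------------------------------------------
# Window accuracy
# ---------------------------------------------------------------------------


def _in_window(t_rel: float, config: AnalysisConfig) -> bool:
    if t_rel < config.window_start_ms:
        return False
    if config.boundary == "half_open":
        return t_rel < config.window_end_ms
    return t_rel <= config.window_end_ms


def window_accuracy(
    trial: AlignedTrial, config: AnalysisConfig = AnalysisConfig()
) -> WindowAccuracy:
    """Proportion of looks to target over the analytical window of one trial."""
    n_t = n_d = 0
    for t_rel, role in trial.frames:
        if not _in_window(t_rel, config):
            continue
        if role == "target":
            n_t += 1
        elif role == "distractor":
            n_d += 1
    acc = n_t / (n_t + n_d) if (n_t + n_d) > 0 else None
    return WindowAccuracy(
        trial_number=trial.trial_number,
        trial_type=trial.trial_type,
        accuracy=acc,
        n_target_frames=n_t,
        n_distractor_frames=n_d,
    )


def pooled_window_accuracy(
    trials: Sequence[AlignedTrial], config: AnalysisConfig = AnalysisConfig()
) -> Optional[float]:
    """Frame-pooled accuracy across trials: total target frames over total
    target+distractor frames in the window."""
    accs = [window_accuracy(t, config) for t in trials]
    n_t = sum(a.n_target_frames for a in accs)
    n_d = sum(a.n_distractor_frames for a in accs)
    return n_t / (n_t + n_d) if (n_t + n_d) > 0 else None


# ---------------------------------------------------------------------------
# Chance-level testing
# ---------------------------------------------------------------------------


def _one_sample_t(values: np.ndarray, chance: float, alpha: float) -> tuple[float, int, float, str]:
    """Closed-form one-sample Student t against `chance`, two-sided."""
    n = len(values)
    df = n - 1
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    note = ""
    if sd == 0.0:
        if mean == chance:
            t = 0.0
            p = 1.0
        else:
            # zero variance off chance: the test statistic diverges
            t = math.inf if mean > chance else -math.inf
            p = 0.0
            note = "zero variance: significant by construction"
    else:
        t = (mean - chance) / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p, note


def trial_type_summary(
    accuracies: Sequence[WindowAccuracy], config: AnalysisConfig = AnalysisConfig()
) -> TrialTypeResult:
    """Summarize one trial type: mean accuracy and a one-sample t-test
    against chance.

    Undefined accuracies (no target/distractor frame in the window) are
    excluded from the mean and the test.  With ``test_unit="frames"`` the
    test runs on the pooled binary frame vector instead of per-trial means.
    """
    types = {a.trial_type for a in accuracies}
    if len(types) != 1:
        raise ValueError(f"accuracies must be of one trial type, got {sorted(types)}")
    trial_type = types.pop()

    defined = [a for a in accuracies if a.accuracy is not None]
    if len(defined) < 2:
        raise ValueError(
            f"insufficient trials for test: {len(defined)} defined accuracies "
            f"in trial type {trial_type!r}"
        )
    per_trial = np.array([a.accuracy for a in defined])
    mean = float(np.mean(per_trial))

    if config.test_unit == "trials":
        values = per_trial
    else:
        values = np.concatenate(
            [
                np.concatenate([np.ones(a.n_target_frames), np.zeros(a.n_distractor_frames)])
                for a in defined
            ]
        )
        mean = float(np.mean(values))
    t, df, p, note = _one_sample_t(values, config.chance, config.alpha)
    return TrialTypeResult(
        trial_type=trial_type,
        n_trials=len(defined),
        mean_accuracy=mean,
        t_stat=t,
        df=df,
        p_value=p,
        significant_above_chance=(p < config.alpha and mean > config.chance),
        note=note,
    )


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------


def time_course(
    trials: Sequence[AlignedTrial], config: AnalysisConfig = AnalysisConfig()
) -> dict[str, TimeCourse]:
    """Pooled proportion of looks to target per time bin, by trial type.

    Bins are half-open ``[edge, edge + bin_ms)`` tiling
    ``[plot_start_ms, plot_end_ms)``.  Bins where no trial contributes a
    target/distractor frame are NaN gaps.
    """
    start, end, width = config.plot_start_ms, config.plot_end_ms, config.bin_ms
    n_bins = int(math.ceil((end - start) / width))
    centers = [start + (i + 0.5) * width for i in range(n_bins)]

    out: dict[str, TimeCourse] = {}
    for tt in TRIAL_TYPES:
        tt_trials = [t for t in trials if t.trial_type == tt]
        if not tt_trials:
            continue
        n_target = np.zeros(n_bins)
        n_distr = np.zeros(n_bins)
        contributing = [set() for _ in range(n_bins)]
        for trial in tt_trials:
            for t_rel, role in trial.frames:
                if role not in ("target", "distractor"):
                    continue
                b = int(math.floor((t_rel - start) / width))
                if not (0 <= b < n_bins):
                    continue
                if role == "target":
                    n_target[b] += 1
                else:
                    n_distr[b] += 1
                contributing[b].add(trial.trial_number)
        denom = n_target + n_distr
        with np.errstate(invalid="ignore"):
            prop = np.where(denom > 0, n_target / np.where(denom > 0, denom, 1), np.nan)
        out[tt] = TimeCourse(
            trial_type=tt,
            bin_centers_ms=centers,
            proportion_to_target=[float(p) for p in prop],
            n_contributing_trials=[len(c) for c in contributing],
            n_frames=[int(d) for d in denom],
        )
    return out


def plot_time_course(
    courses: dict[str, TimeCourse],
    config: AnalysisConfig,
    path: str | Path,
    title: str = "Looking behavior",
) -> None:
    """Figure in the two-panel style: one curve per trial type, a dashed
    chance line, and solid vertical markers at the analytical window."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"carrier1": "#e377c2", "carrier2": "#2ca02c", "single_word": "#1f77b4"}
    labels = {
        "carrier1": 'Carrier 1 ("Find the")',
        "carrier2": 'Carrier 2 ("Look at the")',
        "single_word": "Single word",
    }
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for tt, tc in courses.items():
        ax.plot(
            tc.bin_centers_ms,
            tc.proportion_to_target,
            color=colors.get(tt, "k"),
            label=labels.get(tt, tt),
        )
    ax.axhline(config.chance, linestyle="--", color="grey")
    ax.axvline(config.window_start_ms, color="k")
    ax.axvline(config.window_end_ms, color="k")
    ax.set_xlabel("Time since target onset (ms)")
    ax.set_ylabel("Proportion of looks to target")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class SessionReport:
    """Everything the pipeline computes for one session."""

    n_trials: int
    n_kept: int
    n_dropped: int
    per_trial: pd.DataFrame
    summaries: dict[str, Optional[TrialTypeResult]]
    summary_errors: dict[str, str]
    time_courses: dict[str, TimeCourse]
    config: AnalysisConfig

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for tt in TRIAL_TYPES:
            res = self.summaries.get(tt)
            if res is None:
                rows.append({"trial_type": tt, "error": self.summary_errors.get(tt, "")})
            else:
                rows.append(
                    {
                        "trial_type": tt,
                        "n_trials": res.n_trials,
                        "mean_accuracy": res.mean_accuracy,
                        "t": res.t_stat,
                        "df": res.df,
                        "p": res.p_value,
                        "significant_above_chance": res.significant_above_chance,
                        "note": res.note,
                    }
                )
        return pd.DataFrame(rows)

    def time_course_frame(self) -> pd.DataFrame:
        rows = []
        for tt, tc in self.time_courses.items():
            for c, p, n in zip(
                tc.bin_centers_ms, tc.proportion_to_target, tc.n_contributing_trials
            ):
                rows.append(
                    {"trial_type": tt, "bin_center_ms": c, "proportion": p, "n_trials": n}
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"trials: {self.n_trials} total, {self.n_kept} usable, {self.n_dropped} excluded",
            f"analytical window: {self.config.window_start_ms:g}-{self.config.window_end_ms:g} ms",
        ]
        for tt in TRIAL_TYPES:
            res = self.summaries.get(tt)
            if res is None:
                lines.append(f"{tt}: {self.summary_errors.get(tt, 'no trials')}")
            else:
                lines.append(res.report_line(self.config.chance))
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path, figure: bool = True, title: str = "") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_trial.to_csv(out / "per_trial.csv", index=False)
        self.summary_frame().to_csv(out / "summary.csv", index=False)
        self.time_course_frame().to_csv(out / "time_course.csv", index=False)
        (out / "report.txt").write_text(self.to_text())
        if figure:
            plot_time_course(
                self.time_courses, self.config, out / "time_course.png",
                title=title or "Looking behavior",
            )


def analyze_aligned(
    aligned: Sequence[AlignedTrial], config: AnalysisConfig = AnalysisConfig()
) -> SessionReport:
    """Run exclusion, window accuracy, per-type summaries and time courses on
    already-aligned trials."""
    kept, dropped = exclude_low_data(aligned, config)
    accs = {t.trial_number: window_accuracy(t, config) for t in kept}

    rows = []
    dropped_nums = {t.trial_number: reason for t, reason in dropped}
    for t in aligned:
        acc = accs.get(t.trial_number)
        rows.append(
            {
                "trial_number": t.trial_number,
                "trial_type": t.trial_type,
                "on_screen_fraction": on_screen_fraction(t),
                "kept": t.trial_number not in dropped_nums,
                "accuracy": (acc.accuracy if acc is not None else np.nan),
                "n_target_frames": (acc.n_target_frames if acc else 0),
                "n_distractor_frames": (acc.n_distractor_frames if acc else 0),
                "exclusion_reason": dropped_nums.get(t.trial_number, ""),
            }
        )
    per_trial = pd.DataFrame(rows).sort_values("trial_number").reset_index(drop=True)

    summaries: dict[str, Optional[TrialTypeResult]] = {}
    errors: dict[str, str] = {}
    for tt in TRIAL_TYPES:
        tt_accs = [a for a in accs.values() if a.trial_type == tt]
        if not tt_accs:
            summaries[tt] = None
            errors[tt] = "no usable trials"
            continue
        try:
            summaries[tt] = trial_type_summary(tt_accs, config)
        except ValueError as exc:
            summaries[tt] = None
            errors[tt] = str(exc)

    return SessionReport(
        n_trials=len(aligned),
        n_kept=len(kept),
        n_dropped=len(dropped),
        per_trial=per_trial,
        summaries=summaries,
        summary_errors=errors,
        time_courses=time_course(kept, config),
        config=config,
    )


def run_pipeline(
    task: TaskStructure,
    gaze: Sequence[TrialGaze],
    timings: Sequence[StimulusTiming],
    config: AnalysisConfig = AnalysisConfig(),
) -> SessionReport:
    """Full session analysis: align to critical onsets, exclude low-data
    trials, compute windowed accuracies, chance-level tests and time courses.

    Deterministic: the same inputs and config always produce an identical
    report.
    """
    try:
        aligned = align_session(task, gaze, timings)
    except ValueError as exc:
        raise ValueError(f"alignment stage: {exc}") from exc
    return analyze_aligned(aligned, config)
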