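"""Synthetic frame-coded gaze sessions with known ground truth.

The generator realizes the statistical structure the windowed analysis
assumes.  Each trial is a simple orienting model:

* before the target word, gaze rests on one image (target side with
  probability ``pre_onset_bias``, 0.5 by default — no pre-onset preference);
* at ``onset + latency`` (latency lognormal in ms, matching the heavy right
  tail of toddler gaze-shift latencies) gaze shifts to the target with
  probability ``p_know`` — the per-trial probability that the word is
  understood — and otherwise to the distractor, and stays there;
* away/off-screen episodes are a two-state Markov process: every on-screen
  frame enters an episode with hazard ``p_away_per_frame``; episode length is
  geometric with mean ``away_dur_mean_ms``.  This is the simplest process
  that exercises the 50% screen-time exclusion rule.

Under ``p_know = 0.5`` the generator is the chance model (equal looks to
target vs. distractor), which makes it the null for test calibration.
Per-trial random substreams are derived from ``(seed, trial_number)``, so
adding trials never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .analysis import (
    AnalysisConfig,
    SessionReport,
    analyze_aligned,
    exclude_low_data,
    trial_type_summary,
    window_accuracy,
)
from .gaze import GazeFrame, StimulusTiming, TrialGaze, align_session, write_frame_codes, write_timing
from .screen import TargetWord
from .task import (
    TRIAL_TYPES,
    BuildConfig,
    TaskStructure,
    TrialSpec,
    build_task,
    write_task_csv,
    yoke_pairs,
)


@dataclass
class GazeModelParams:
    """Ground-truth parameters of the gaze generator."""

    p_know: float = 0.5
    latency_mean_ms: float = 400.0
    latency_sd_ms: float = 150.0
    p_away_per_frame: float = 0.02
    away_dur_mean_ms: float = 500.0
    pre_onset_bias: float = 0.5
    frame_rate_hz: float = 30.0
    trial_dur_ms: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_know", "p_away_per_frame", "pre_onset_bias"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.latency_mean_ms < 0 or self.latency_sd_ms < 0:
            raise ValueError("latency parameters must be non-negative")
        if self.away_dur_mean_ms <= 0 or self.frame_rate_hz <= 0 or self.trial_dur_ms <= 0:
            raise ValueError("durations and frame rate must be positive")


@dataclass
class SimulatedSession:
    """A complete synthetic session: task, gaze, timing, and the truth."""

    task: TaskStructure
    gaze: list[TrialGaze]
    timing: list[StimulusTiming]
    truth: GazeModelParams

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_task_csv(self.task, out / "task.csv")
        write_frame_codes(self.gaze, out / "gaze.csv")
        write_timing(self.timing, out / "timing.tsv")


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a (seed, key...) tuple."""
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) from the distribution's mean and sd in ms."""
    if mean <= 0:
        return -math.inf, 0.0  # degenerate at zero latency
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def latency_cdf(t_ms: np.ndarray | float, params: GazeModelParams) -> np.ndarray:
    """CDF of the shift latency at ``t_ms`` after onset."""
    t = np.asarray(t_ms, dtype=float)
    if params.latency_mean_ms == 0:
        return (t >= 0).astype(float)
    mu, sigma = _lognormal_mu_sigma(params.latency_mean_ms, params.latency_sd_ms)
    if sigma == 0:
        return (t >= params.latency_mean_ms).astype(float)
    from scipy.stats import lognorm

    return lognorm.cdf(t, s=sigma, scale=math.exp(mu))


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------


def simulate_trial(
    trial: TrialSpec,
    onset_ms: float,
    params: GazeModelParams,
    rng: np.random.Generator,
) -> TrialGaze:
    """Simulate one trial's frame-coded gaze stream.

    Deterministic given ``rng``'s state.  Frames run at
    ``params.frame_rate_hz`` from 0 to ``params.trial_dur_ms``.
    """
    frame_ms = 1000.0 / params.frame_rate_hz
    n = int(round(params.trial_dur_ms / frame_ms))
    times = np.arange(n) * frame_ms
    if not (0 <= onset_ms <= times[-1]):
        raise ValueError(f"onset {onset_ms} ms outside trial [0, {times[-1]:.1f}] ms")

    other = "left" if trial.target_side == "right" else "right"
    pre_side = trial.target_side if rng.random() < params.pre_onset_bias else other
    if params.latency_mean_ms == 0:
        latency = 0.0
    else:
        mu, sigma = _lognormal_mu_sigma(params.latency_mean_ms, params.latency_sd_ms)
        latency = math.exp(mu) if sigma == 0 else float(rng.lognormal(mu, sigma))
    dest_side = trial.target_side if rng.random() < params.p_know else other

    codes = np.where(times < onset_ms + latency, pre_side, dest_side).astype(object)

    if params.p_away_per_frame > 0:
        p_exit = min(1.0, frame_ms / params.away_dur_mean_ms)
        pos = 0
        while pos < n:
            on_run = int(rng.geometric(params.p_away_per_frame)) - 1
            start = pos + on_run
            if start >= n:
                break
            dur = int(rng.geometric(p_exit))
            episode_code = "away" if rng.random() < 0.5 else "off"
            codes[start : min(n, start + dur)] = episode_code
            pos = start + dur

    frames = [GazeFrame(t_ms=float(t), code=str(c)) for t, c in zip(times, codes)]
    return TrialGaze(
        trial_number=trial.trial_number, frames=frames, frame_rate_hz=params.frame_rate_hz
    )


# ---------------------------------------------------------------------------
# Session-level simulation
# ---------------------------------------------------------------------------

_WORD_BANK = (
    "ball dog cup shoe car book bird fish spoon hat duck sock tree cat bear "
    "frog cookie apple truck baby boat star drum kite"
).split()

_ONSET_BASE_MS = {"carrier1": 600.0, "carrier2": 800.0, "single_word": 300.0}


def _session_targets(n_pairs: int) -> list[TargetWord]:
    words = [
        _WORD_BANK[i] if i < len(_WORD_BANK) else f"word{i:02d}" for i in range(2 * n_pairs)
    ]
    return [TargetWord(word=w, word_class="noun") for w in words]


def simulate_session(
    params: GazeModelParams,
    n_pairs: int = 6,
    per_word_p_know: Optional[Mapping[str, float]] = None,
) -> SimulatedSession:
    """Simulate a full session: seeded task build, per-trial gaze streams and
    a stimulus-timing table, all in the same dialects the real pipeline reads.

    ``per_word_p_know`` overrides the orientation probability for individual
    target words, so mixed known/unknown sessions can be generated.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    targets = _session_targets(n_pairs)
    pair_seed = int(_substream(params.seed, 1).integers(0, 2**31))
    task_seed = int(_substream(params.seed, 2).integers(0, 2**31))
    pairs = yoke_pairs(targets, seed=pair_seed)
    task = build_task(pairs, BuildConfig(seed=task_seed))

    word_index = {t.word: i for i, t in enumerate(targets)}
    timing: list[StimulusTiming] = []
    onsets: dict[int, float] = {}
    seen: set[str] = set()
    for trial in task.trials:
        base = _ONSET_BASE_MS[trial.trial_type]
        onset = base + 10.0 * (word_index[trial.target.word] % 8)
        onsets[trial.trial_number] = onset
        if trial.audio_script not in seen:
            seen.add(trial.audio_script)
            timing.append(
                StimulusTiming(
                    audio_script=trial.audio_script,
                    target_onset_ms=onset,
                    audio_start_ms=0.0,
                )
            )

    gaze: list[TrialGaze] = []
    for trial in task.trials:
        p = params.p_know
        if per_word_p_know is not None:
            p = per_word_p_know.get(trial.target.word, p)
        trial_params = replace(params, p_know=p)
        rng = _substream(params.seed, 1000 + trial.trial_number)
        gaze.append(simulate_trial(trial, onsets[trial.trial_number], trial_params, rng))
    return SimulatedSession(task=task, gaze=gaze, timing=timing, truth=params)


def analyze_session(
    session: SimulatedSession, config: AnalysisConfig = AnalysisConfig()
) -> SessionReport:
    """Run the full analysis pipeline on a simulated session (in memory)."""
    aligned = align_session(session.task, session.gaze, session.timing)
    return analyze_aligned(aligned, config)


# ---------------------------------------------------------------------------
# Calibration: type-I error and power of the chance-level test
# ---------------------------------------------------------------------------


@dataclass
class ConditionRates:
    """Directional rejection rates for one generator condition."""

    label: str
    n_replicates: int
    per_type: dict[str, float]
    pooled: float
    pooled_ci: tuple[float, float]  # normal-approximation 95% CI
    n_tests: int


@dataclass
class CalibrationReport:
    null: ConditionRates
    alt: Optional[ConditionRates]
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = []
        for cond in (self.null, self.alt):
            if cond is None:
                continue
            lines.append(
                f"{cond.label}: pooled directional rejection rate "
                f"{cond.pooled:.4f} (95% CI {cond.pooled_ci[0]:.4f}-{cond.pooled_ci[1]:.4f}, "
                f"{cond.n_tests} tests over {cond.n_replicates} replicates)"
            )
            for tt, r in cond.per_type.items():
                lines.append(f"  {tt}: {r:.4f}")
        lines.extend(self.notes)
        return "\n".join(lines) + "\n"


def _condition_rates(
    label: str,
    params: GazeModelParams,
    n_replicates: int,
    config: AnalysisConfig,
    n_pairs: int,
    seed: int,
    cond_key: int,
    notes: list[str],
) -> ConditionRates:
    hits: dict[str, int] = {tt: 0 for tt in TRIAL_TYPES}
    counts: dict[str, int] = {tt: 0 for tt in TRIAL_TYPES}
    for rep in range(n_replicates):
        rep_seed = int(_substream(seed, cond_key, rep).integers(0, 2**31))
        session = simulate_session(replace(params, seed=rep_seed), n_pairs=n_pairs)
        report = analyze_session(session, config)
        for tt in TRIAL_TYPES:
            res = report.summaries.get(tt)
            if res is None:
                notes.append(
                    f"{label} replicate {rep}, {tt}: {report.summary_errors.get(tt, '')}"
                )
                continue
            counts[tt] += 1
            if res.note:
                notes.append(f"{label} replicate {rep}, {tt}: {res.note}")
            if res.significant_above_chance:
                hits[tt] += 1
    n_tests = sum(counts.values())
    pooled = sum(hits.values()) / n_tests if n_tests else float("nan")
    se = math.sqrt(max(pooled * (1 - pooled), 1e-12) / n_tests) if n_tests else float("nan")
    return ConditionRates(
        label=label,
        n_replicates=n_replicates,
        per_type={tt: (hits[tt] / counts[tt] if counts[tt] else float("nan")) for tt in TRIAL_TYPES},
        pooled=pooled,
        pooled_ci=(pooled - 1.96 * se, pooled + 1.96 * se),
        n_tests=n_tests,
    )


def calibrate_test(
    params_null: GazeModelParams,
    params_alt: Optional[GazeModelParams] = None,
    n_replicates: int = 2000,
    config: AnalysisConfig = AnalysisConfig(),
    n_pairs: int = 6,
    seed: int = 0,
) -> CalibrationReport:
    """Monte-Carlo calibration of the chance-level test.

    Runs the full pipeline per replicate and reports the directional
    rejection rate (significant *above* chance) per trial type and pooled:
    under the null this is the type-I error (nominal alpha/2 for a two-sided
    test), under the alternative it is the power.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    notes: list[str] = []
    null = _condition_rates(
        "null", params_null, n_replicates, config, n_pairs, seed, 11, notes
    )
    alt = None
    if params_alt is not None:
        alt = _condition_rates(
            "alt", params_alt, n_replicates, config, n_pairs, seed, 22, notes
        )
    return CalibrationReport(null=null, alt=alt, notes=notes)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def expected_window_accuracy(
    params: GazeModelParams, config: AnalysisConfig = AnalysisConfig()
) -> float:
    """Closed-form expected window accuracy implied by the generator.

    A window frame at ``t`` ms post onset looks at the target with
    probability ``pre_onset_bias`` if the shift has not happened yet
    (probability ``1 - F(t)``) and ``p_know`` if it has, so the expected
    accuracy is ``(1 - f) * pre_onset_bias + f * p_know`` with ``f`` the mean
    latency CDF over the window.  Away episodes are side-independent and
    cancel from numerator and denominator.
    """
    grid = np.linspace(config.window_start_ms, config.window_end_ms, 2001)
    f = float(np.trapezoid(latency_cdf(grid, params), grid)) / (
        config.window_end_ms - config.window_start_ms
    )
    return (1.0 - f) * params.pre_onset_bias + f * params.p_know


@dataclass
class RecoveryReport:
    """Observed vs. expected accuracy for a session with known truth."""

    observed: dict[str, float]  # per trial type
    expected: float
    bias: dict[str, float]  # observed - expected
    implied_p_know: dict[str, float]
    overall_observed: float
    overall_bias: float

    def to_text(self) -> str:
        lines = [f"expected accuracy: {self.expected:.4f}"]
        for tt, obs in self.observed.items():
            lines.append(
                f"{tt}: observed {obs:.4f}, bias {self.bias[tt]:+.4f}, "
                f"implied p_know {self.implied_p_know[tt]:.3f}"
            )
        lines.append(
            f"overall: observed {self.overall_observed:.4f}, bias {self.overall_bias:+.4f}"
        )
        return "\n".join(lines) + "\n"


def recover_parameters(
    session: SimulatedSession, config: AnalysisConfig = AnalysisConfig()
) -> RecoveryReport:
    """Compare a session's estimated accuracies to the closed-form
    expectation implied by its ground-truth parameters, and invert the
    expectation to an implied ``p_know`` per trial type."""
    params = session.truth
    aligned = align_session(session.task, session.gaze, session.timing)
    kept, _ = exclude_low_data(aligned, config)
    accs = [window_accuracy(t, config) for t in kept]

    expected = expected_window_accuracy(params, config)
    grid = np.linspace(config.window_start_ms, config.window_end_ms, 2001)
    f = float(np.trapezoid(latency_cdf(grid, params), grid)) / (
        config.window_end_ms - config.window_start_ms
    )

    observed: dict[str, float] = {}
    bias: dict[str, float] = {}
    implied: dict[str, float] = {}
    all_defined: list[float] = []
    for tt in TRIAL_TYPES:
        vals = [a.accuracy for a in accs if a.trial_type == tt and a.accuracy is not None]
        if not vals:
            continue
        obs = float(np.mean(vals))
        observed[tt] = obs
        bias[tt] = obs - expected
        implied[tt] = (
            (obs - (1.0 - f) * params.pre_onset_bias) / f if f > 0 else float("nan")
        )
        all_defined.extend(vals)
    overall = float(np.mean(all_defined)) if all_defined else float("nan")
    return RecoveryReport(
        observed=observed,
        expected=expected,
        bias=bias,
        implied_p_know=implied,
        overall_observed=overall,
        overall_bias=overall - expected,
    )
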