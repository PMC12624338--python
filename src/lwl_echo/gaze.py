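"""Frame-coded gaze I/O, critical-onset computation and onset alignment.

Gaze is hand-coded offline from face video, frame by frame, into one of four
codes: ``left`` / ``right`` (looking at the left or right image), ``away``
(on or near the screen but at neither image) and ``off`` (not codable /
off-screen).  This module reads such per-frame exports, computes each trial's
*critical onset* (the moment the target word begins in the trial audio,
``audio_start_ms + target_onset_ms``), and re-references every frame to that
onset while remapping screen sides to target/distractor roles via the trial's
target side.

Side labels are taken from the child's perspective as coded from the face
video; no mirror flip is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .screen import normalize_phrase
from .task import TaskStructure, TrialSpec

#: Canonical gaze codes.
GAZE_CODES = ("left", "right", "away", "off")

#: Default alias map for reading exports (case-insensitive).
DEFAULT_ALIASES: dict[str, str] = {
    "left": "left",
    "right": "right",
    "away": "away",
    "off": "off",
    "l": "left",
    "r": "right",
    "a": "away",
    "o": "off",
}

#: Roles after alignment.
ROLES = ("target", "distractor", "away", "off")

DEFAULT_FRAME_RATE_HZ = 30.0


@dataclass(frozen=True)
class GazeFrame:
    """One coded video frame, timed from trial start."""

    t_ms: float
    code: str


@dataclass
class TrialGaze:
    """All coded frames of one trial."""

    trial_number: int
    frames: list[GazeFrame]
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ


@dataclass(frozen=True)
class StimulusTiming:
    """Where the target word starts within one trial's audio."""

    audio_script: str
    target_onset_ms: float
    audio_start_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.target_onset_ms < 0:
            raise ValueError("target_onset_ms must be >= 0")


@dataclass
class AlignedTrial:
    """Gaze re-referenced to the critical onset, with side codes mapped to
    target/distractor roles."""

    trial_number: int
    trial_type: str
    frames: list[tuple[float, str]]  # (t_rel_ms, role)
    onset_ms: float


# ---------------------------------------------------------------------------
# Reading / writing frame codes
# ---------------------------------------------------------------------------


def read_frame_codes(
    path: str | Path,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    aliases: Optional[Mapping[str, str]] = None,
) -> list[TrialGaze]:
    """Read a per-frame gaze CSV into one :class:`TrialGaze` per trial.

    The file must have columns ``trial_number``, ``code`` and either ``t_ms``
    or ``frame_index`` (converted using ``frame_rate_hz``).  Codes are matched
    case-insensitively through the alias map; unknown codes and non-monotone
    timestamps are errors.
    """
    alias = {k.casefold(): v for k, v in (aliases or DEFAULT_ALIASES).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "trial_number" not in df.columns or "code" not in df.columns:
        raise ValueError("gaze file needs columns trial_number, code and t_ms or frame_index")
    if "t_ms" in df.columns:
        t_ms = df["t_ms"].astype(float)
    elif "frame_index" in df.columns:
        t_ms = df["frame_index"].astype(float) * (1000.0 / frame_rate_hz)
    else:
        raise ValueError("gaze file needs a t_ms or frame_index column")

    bad_rows = [
        i + 2  # header is line 1
        for i, c in enumerate(df["code"])
        if c.strip().casefold() not in alias
    ]
    if bad_rows:
        bad_codes = sorted({df["code"].iloc[i - 2] for i in bad_rows})
        raise ValueError(f"unknown gaze codes {bad_codes} at file lines {bad_rows}")

    codes = [alias[c.strip().casefold()] for c in df["code"]]
    trial_nums = df["trial_number"].astype(int)

    out: dict[int, TrialGaze] = {}
    for tn, t, code in zip(trial_nums, t_ms, codes):
        tg = out.get(tn)
        if tg is None:
            out[tn] = tg = TrialGaze(trial_number=tn, frames=[], frame_rate_hz=frame_rate_hz)
        if tg.frames and t <= tg.frames[-1].t_ms:
            raise ValueError(f"non-monotone timestamps in trial {tn} at t={t}")
        if t < 0:
            raise ValueError(f"negative timestamp in trial {tn}")
        tg.frames.append(GazeFrame(t_ms=float(t), code=code))
    return [out[k] for k in sorted(out)]


def write_frame_codes(trials: Iterable[TrialGaze], path: str | Path) -> None:
    rows = [
        {"trial_number": tg.trial_number, "t_ms": f.t_ms, "code": f.code}
        for tg in trials
        for f in tg.frames
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stimulus timing
# ---------------------------------------------------------------------------


def read_timing(path: str | Path) -> list[StimulusTiming]:
    """Read a stimulus-timing TSV (audio_script, audio_start_ms, target_onset_ms)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        StimulusTiming(
            audio_script=row.audio_script,
            target_onset_ms=float(row.target_onset_ms),
            audio_start_ms=float(getattr(row, "audio_start_ms", 0.0) or 0.0),
        )
        for row in df.itertuples(index=False)
    ]


def write_timing(timings: Iterable[StimulusTiming], path: str | Path) -> None:
    rows = [
        {
            "audio_script": t.audio_script,
            "audio_start_ms": t.audio_start_ms,
            "target_onset_ms": t.target_onset_ms,
        }
        for t in timings
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_critical_onsets(
    task: TaskStructure, timings: Sequence[StimulusTiming]
) -> dict[int, float]:
    """Per-trial critical onset: ``audio_start_ms + target_onset_ms``.

    Audio scripts are matched after normalization (case, punctuation).  Every
    trial must match exactly one timing entry.
    """
    by_script: dict[str, StimulusTiming] = {}
    for t in timings:
        key = normalize_phrase(t.audio_script)
        if key in by_script:
            raise ValueError(f"duplicate timing entry for script {t.audio_script!r}")
        by_script[key] = t

    onsets: dict[int, float] = {}
    missing: list[str] = []
    for trial in task.trials:
        key = normalize_phrase(trial.audio_script)
        timing = by_script.get(key)
        if timing is None:
            missing.append(trial.audio_script)
            continue
        onsets[trial.trial_number] = timing.audio_start_ms + timing.target_onset_ms
    if missing:
        raise ValueError(f"no timing entry for audio scripts: {missing}")
    return onsets


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def map_role(code: str, target_side: str) -> str:
    """Role of a gaze code given the trial's target side (pure function)."""
    if code in ("away", "off"):
        return code
    return "target" if code == target_side else "distractor"


def align_to_onset(gaze: TrialGaze, onset_ms: float, trial: TrialSpec) -> AlignedTrial:
    """Re-reference one trial's frames to the critical onset.

    Frames before onset are retained with negative ``t_rel_ms`` so the full
    time course can be plotted.  The onset must lie within the trial
    recording.
    """
    if not gaze.frames:
        raise ValueError(f"trial {gaze.trial_number} has no frames")
    last = gaze.frames[-1].t_ms
    if not (0 <= onset_ms <= last):
        raise ValueError(
            f"trial {gaze.trial_number}: onset {onset_ms} ms outside recording [0, {last}] ms"
        )
    frames = [(f.t_ms - onset_ms, map_role(f.code, trial.target_side)) for f in gaze.frames]
    return AlignedTrial(
        trial_number=gaze.trial_number,
        trial_type=trial.trial_type,
        frames=frames,
        onset_ms=onset_ms,
    )


def align_session(
    task: TaskStructure,
    gaze: Sequence[TrialGaze],
    timings: Sequence[StimulusTiming],
) -> list[AlignedTrial]:
    """Align every gaze trial of a session to its critical onset."""
    onsets = compute_critical_onsets(task, timings)
    trials_by_num = {t.trial_number: t for t in task.trials}
    out = []
    for tg in gaze:
        if tg.trial_number not in trials_by_num:
            raise ValueError(f"gaze trial {tg.trial_number} not present in task")
        out.append(align_to_onset(tg, onsets[tg.trial_number], trials_by_num[tg.trial_number]))
    return out
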