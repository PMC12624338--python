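"""Build a personalized three-block Looking-While-Listening task.

A task presents each imageable target word three times, once per trial type,
in three contiguous sequential blocks:

1. ``carrier1`` — "Find (the) X" phrases,
2. ``carrier2`` — "Look at (the) X" phrases,
3. ``single_word`` — the bare word preceded by an attention primer
   ("Ooh X" / "Look X").

Targets are placed into *yoked pairs*: each target is always shown with the
same distractor image.  Within each block every target appears exactly once
as the named target, the target side is balanced left/right, side runs are
bounded, and the same image pair never appears back-to-back.  Given a seed,
the generated task is bit-identical across runs.
"""

from __future__ import annotations

import re
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .screen import Lexicon, TargetWord, normalize_phrase

#: The three trial types in presentation order.
TRIAL_TYPES = ("carrier1", "carrier2", "single_word")

#: Display names used in task tables.
TRIAL_TYPE_LABELS = {
    "carrier1": "Carrier 1",
    "carrier2": "Carrier 2",
    "single_word": "Single word",
}

PRIMERS = ("Ooh", "Look")


@dataclass(frozen=True)
class YokedPair:
    """A target–distractor image pairing held constant across the task."""

    target_a: TargetWord
    target_b: TargetWord

    def __post_init__(self) -> None:
        if self.target_a.key == self.target_b.key:
            raise ValueError(f"pair members must differ: {self.target_a.word!r}")

    @property
    def words(self) -> frozenset[str]:
        return frozenset({self.target_a.word, self.target_b.word})


@dataclass
class TrialSpec:
    """One trial: two images, a target side, and the audio script."""

    trial_number: int
    trial_type: str
    left_image: TargetWord
    right_image: TargetWord
    target_side: str  # "left" | "right"
    audio_script: str = ""
    primer: Optional[str] = None

    @property
    def target(self) -> TargetWord:
        return self.left_image if self.target_side == "left" else self.right_image

    @property
    def distractor(self) -> TargetWord:
        return self.right_image if self.target_side == "left" else self.left_image

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset({self.left_image.word, self.right_image.word})


@dataclass
class TaskStructure:
    """The ordered, constraint-checked trial list for one participant."""

    trials: list[TrialSpec]
    seed: Optional[int] = None
    constraints_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def block(self, trial_type: str) -> list[TrialSpec]:
        return [t for t in self.trials if t.trial_type == trial_type]


@dataclass
class BuildConfig:
    """Randomization knobs for task generation.

    ``max_run`` bounds consecutive same-side targets ("target location varied
    throughout the task" operationalized as run length <= 3, standard LWL
    practice).  ``determiner_rule`` maps word class to whether the carrier
    includes "the"; per-word lexicon overrides win.  ``primer_balance``
    splits the single-word block evenly between "Ooh" and "Look".
    """

    max_run: int = 3
    determiner_rule: Mapping[str, bool] = field(
        default_factory=lambda: {
            "noun": True,
            "verb": False,
            "proper_noun": False,
            "fixed_expression": False,
        }
    )
    primer_balance: bool = True
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.max_run < 2:
            raise ValueError("max_run must be >= 2")


# ---------------------------------------------------------------------------
# Yoking
# ---------------------------------------------------------------------------


def yoke_pairs(
    targets: Sequence[TargetWord],
    hints: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> list[YokedPair]:
    """Place targets into yoked pairs.

    ``hints`` maps target word -> partner word for semantically motivated
    pairings (e.g. banana <-> orange); remaining targets are paired from a
    seeded shuffle.  An odd target count is an error.
    """
    if len(targets) % 2 != 0:
        raise ValueError(f"unpairable target list: odd count {len(targets)}")
    by_word = {t.word: t for t in targets}
    if len(by_word) != len(targets):
        raise ValueError("duplicate target words in list")

    pairs: list[YokedPair] = []
    used: set[str] = set()
    if hints:
        for a, b in hints.items():
            if a in used or b in used:
                continue  # the symmetric entry already paired them
            for w in (a, b):
                if w not in by_word:
                    raise ValueError(f"pairing hint references unknown target {w!r}")
            if a == b:
                raise ValueError(f"hint pairs {a!r} with itself")
            pairs.append(YokedPair(by_word[a], by_word[b]))
            used.update((a, b))

    rest = [t for t in targets if t.word not in used]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    rest = [rest[i] for i in order]
    if len(rest) % 2 != 0:
        raise ValueError("pairing hints leave an odd number of unpaired targets")
    for i in range(0, len(rest), 2):
        pairs.append(YokedPair(rest[i], rest[i + 1]))
    return pairs


# ---------------------------------------------------------------------------
# Audio rendering
# ---------------------------------------------------------------------------


def _audio_surface(word: TargetWord) -> str:
    """Surface form of the word inside an audio script.

    Proper nouns keep their capitalization; common nouns, verbs and fixed
    expressions are spoken lowercase ("Find the dog", "Find jump",
    "Find keepy uppy" — but "Find Mickey Mouse").  A lexicon ``audio_form``
    overrides the rule.
    """
    if word.audio_form is not None:
        return word.audio_form
    if word.word_class == "proper_noun":
        return word.word
    return word.word.lower()


def _uses_determiner(word: TargetWord, config: BuildConfig) -> bool:
    if word.use_determiner is not None:
        return word.use_determiner
    return bool(config.determiner_rule.get(word.word_class, False))


def render_audio_script(trial: TrialSpec, config: BuildConfig = BuildConfig()) -> str:
    """Render the auditory stimulus text for one trial.

    carrier1 -> "Find [the] X"; carrier2 -> "Look at [the] X";
    single_word -> "<primer> X".
    """
    word = trial.target
    surface = _audio_surface(word)
    det = "the " if _uses_determiner(word, config) else ""
    if trial.trial_type == "carrier1":
        return f"Find {det}{surface}"
    if trial.trial_type == "carrier2":
        return f"Look at {det}{surface}"
    if trial.trial_type == "single_word":
        if trial.primer not in PRIMERS:
            raise ValueError(f"single_word trial requires a primer, got {trial.primer!r}")
        return f"{trial.primer} {surface}"
    raise ValueError(f"unknown trial_type {trial.trial_type!r}")


# ---------------------------------------------------------------------------
# Task generation
# ---------------------------------------------------------------------------


def _runs_ok(sides: Sequence[str], max_run: int) -> bool:
    run = 0
    prev = None
    for s in sides:
        run = run + 1 if s == prev else 1
        prev = s
        if run > max_run:
            return False
    return True


def _block_order(
    pairs: Sequence[YokedPair],
    rng: np.random.Generator,
    config: BuildConfig,
    prev_sides: Sequence[str],
    prev_pair: Optional[frozenset[str]],
) -> tuple[list[tuple[YokedPair, TargetWord]], list[str]]:
    """Draw one block's trial order and side assignment satisfying the
    constraints, by bounded rejection sampling."""
    units = [(p, t) for p in pairs for t in (p.target_a, p.target_b)]
    n = len(units)
    sides_pool = ["left"] * (n // 2) + ["right"] * (n // 2)
    for _ in range(config.max_attempts):
        order = rng.permutation(n)
        cand = [units[i] for i in order]
        sides = [sides_pool[i] for i in rng.permutation(n)]
        if len(pairs) >= 2:
            keys = [p.words for p, _ in cand]
            if prev_pair is not None and keys[0] == prev_pair:
                continue
            if any(keys[i] == keys[i + 1] for i in range(n - 1)):
                continue
        if not _runs_ok(list(prev_sides) + sides, config.max_run):
            continue
        return cand, sides
    raise RuntimeError(
        f"could not satisfy trial-order constraints in {config.max_attempts} attempts "
        f"(pairs={len(pairs)}, max_run={config.max_run})"
    )


def build_task(pairs: Sequence[YokedPair], config: BuildConfig = BuildConfig()) -> TaskStructure:
    """Generate the full pseudo-randomized task: 3 blocks x 2 x |pairs| trials.

    Within each block each target is the named target exactly once, left and
    right target placements are equal, side runs never exceed
    ``config.max_run`` (enforced across block boundaries too), and the same
    image pair never occurs back-to-back when there are at least two pairs.
    Deterministic given ``config.seed``.
    """
    if not pairs:
        raise ValueError("need at least one yoked pair")
    words = [w for p in pairs for w in (p.target_a.word, p.target_b.word)]
    if len(set(words)) != len(words):
        raise ValueError("each target must belong to exactly one pair")

    rng = np.random.default_rng(config.seed)
    n_block = 2 * len(pairs)
    trials: list[TrialSpec] = []
    all_sides: list[str] = []
    prev_pair: Optional[frozenset[str]] = None
    attempts_used: dict[str, int] = {}

    for trial_type in TRIAL_TYPES:
        window = all_sides[-(config.max_run) :]
        cand, sides = _block_order(pairs, rng, config, window, prev_pair)
        if trial_type == "single_word":
            if config.primer_balance:
                pool = [PRIMERS[i % 2] for i in range(n_block)]
                primers = [pool[i] for i in rng.permutation(n_block)]
            else:
                primers = [PRIMERS[i] for i in rng.integers(0, 2, n_block)]
        else:
            primers = [None] * n_block
        for (pair, target), side, primer in zip(cand, sides, primers):
            distractor = pair.target_b if target is pair.target_a else pair.target_a
            trial = TrialSpec(
                trial_number=len(trials) + 1,
                trial_type=trial_type,
                left_image=target if side == "left" else distractor,
                right_image=target if side == "right" else distractor,
                target_side=side,
                primer=primer,
            )
            trial.audio_script = render_audio_script(trial, config)
            trials.append(trial)
        all_sides.extend(sides)
        prev_pair = cand[-1][0].words if len(pairs) >= 2 else None

    report = {
        "n_trials": len(trials),
        "n_pairs": len(pairs),
        "per_block_side_counts": {
            tt: {
                s: sum(1 for t in trials if t.trial_type == tt and t.target_side == s)
                for s in ("left", "right")
            }
            for tt in TRIAL_TYPES
        },
        "max_side_run": _max_run_length([t.target_side for t in trials]),
    }
    return TaskStructure(trials=trials, seed=config.seed, constraints_report=report)


def _max_run_length(sides: Sequence[str]) -> int:
    best = run = 0
    prev = None
    for s in sides:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Task table I/O
# ---------------------------------------------------------------------------


def _norm_trial_type(label: str) -> str:
    key = re.sub(r"[\s_]+", "", label.strip().casefold())
    mapping = {"carrier1": "carrier1", "carrier2": "carrier2", "singleword": "single_word"}
    if key not in mapping:
        raise ValueError(f"unknown trial type label {label!r}")
    return mapping[key]


def _strip_primer(tokens: list[str]) -> tuple[Optional[str], list[str]]:
    if tokens and tokens[0] in ("ooh", "look"):
        return tokens[0].capitalize(), tokens[1:]
    return None, tokens


def parse_task_table(path: str | Path, lexicon: Optional[Lexicon] = None) -> TaskStructure:
    """Load a task table CSV (trial_number, trial_type, left_image,
    right_image, audio_script) and infer each trial's target side from which
    image the audio names.

    Validation failures against the design constraints (yoking, balance,
    block order, side runs, pair repeats) are reported as ``UserWarning``s so
    published tables can be loaded as-is; an audio script naming neither
    image is an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"trial_number", "trial_type", "left_image", "right_image", "audio_script"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"task table missing columns: {sorted(missing)}")

    def lookup(word: str) -> TargetWord:
        if lexicon is not None:
            entry = lexicon.get(normalize_phrase(word))
            if entry is not None:
                return entry
        return TargetWord(word=word, word_class="noun")

    trials: list[TrialSpec] = []
    errors: list[str] = []
    for row in df.itertuples(index=False):
        audio = row.audio_script.strip().strip('"“”')
        tokens = normalize_phrase(audio).split()
        trial_type = _norm_trial_type(row.trial_type)
        primer = None
        if trial_type == "single_word":
            primer, _ = _strip_primer(tokens)
        left, right = lookup(row.left_image), lookup(row.right_image)
        matches = []
        for s, img in (("left", row.left_image), ("right", row.right_image)):
            img_tokens = normalize_phrase(img).split()
            if img_tokens and tokens[-len(img_tokens) :] == img_tokens:
                matches.append((len(img_tokens), s))
        # the audio ends with the target word; the longer image-name match wins
        matches.sort(reverse=True)
        if len(matches) == 2 and matches[0][0] == matches[1][0]:
            matches = []
        side = matches[0][1] if matches else None
        if side is None:
            errors.append(
                f"trial {row.trial_number}: audio {audio!r} names neither image "
                f"({row.left_image!r} | {row.right_image!r})"
            )
            continue
        trials.append(
            TrialSpec(
                trial_number=int(row.trial_number),
                trial_type=trial_type,
                left_image=left,
                right_image=right,
                target_side=side,
                audio_script=audio,
                primer=primer,
            )
        )
    if errors:
        raise ValueError("; ".join(errors))

    task = TaskStructure(trials=trials)
    for msg in validate_task(task):
        _warnings.warn(msg, UserWarning, stacklevel=2)
    return task


def validate_task(task: TaskStructure, max_run: int = 3) -> list[str]:
    """Independent structural validation; returns human-readable warnings."""
    out: list[str] = []
    types = [t.trial_type for t in task.trials]
    expected_blocks = [tt for tt in TRIAL_TYPES if tt in types]
    blockified = [t for t, _ in _dedupe_consecutive(types)]
    if blockified != expected_blocks:
        out.append(f"block order: trial types not in contiguous {TRIAL_TYPES} order")

    partners: dict[str, set[str]] = {}
    for t in task.trials:
        a, b = t.left_image.word, t.right_image.word
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    for w, ps in sorted(partners.items()):
        if len(ps) != 1:
            out.append(f"yoking: target {w!r} appears with multiple partners {sorted(ps)}")

    for tt in TRIAL_TYPES:
        block = task.block(tt)
        if not block:
            continue
        tgt_counts: dict[str, int] = {}
        for t in block:
            tgt_counts[t.target.word] = tgt_counts.get(t.target.word, 0) + 1
        dup = {w: c for w, c in tgt_counts.items() if c != 1}
        if dup:
            out.append(f"balance: block {tt} target counts not all 1: {dup}")
        n_left = sum(1 for t in block if t.target_side == "left")
        if n_left * 2 != len(block):
            out.append(
                f"balance: block {tt} sides unequal (left={n_left}, right={len(block) - n_left})"
            )
    if not _runs_ok([t.target_side for t in task.trials], max_run):
        out.append(f"runs: a target-side run exceeds {max_run}")
    for i in range(len(task.trials) - 1):
        if (
            task.trials[i].pair_key == task.trials[i + 1].pair_key
            and len(partners) > 2
        ):
            out.append(
                f"repeat: trials {task.trials[i].trial_number} and "
                f"{task.trials[i + 1].trial_number} show the same pair back-to-back"
            )
    return out


def _dedupe_consecutive(seq: Sequence[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for s in seq:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + 1)
        else:
            out.append((s, 1))
    return out


def write_task_csv(task: TaskStructure, path: str | Path) -> None:
    """Write the task in the printed-table column layout plus target_side."""
    rows = [
        {
            "trial_number": t.trial_number,
            "trial_type": TRIAL_TYPE_LABELS[t.trial_type],
            "left_image": t.left_image.word,
            "right_image": t.right_image.word,
            "audio_script": t.audio_script,
            "target_side": t.target_side,
        }
        for t in task.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
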