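"""Shared fixtures: published task tables, per-participant lexicons and an
independent task constraint checker (deliberately written from scratch, not
via the builder's own validation code)."""

from __future__ import annotations

from pathlib import Path

import pytest

from lwl_echo import TaskStructure
from lwl_echo.screen import Lexicon, read_lexicon
from lwl_echo.task import parse_task_table

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def p1_lexicon() -> Lexicon:
    return read_lexicon(DATA / "participant1_lexicon.tsv")


@pytest.fixture(scope="session")
def p2_lexicon() -> Lexicon:
    return read_lexicon(DATA / "participant2_lexicon.tsv")


def _load_quiet(path, lexicon):
    import warnings

    # published tables pre-date the builder's randomization constraints;
    # loading reports deviations as warnings, never errors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return parse_task_table(path, lexicon=lexicon)


@pytest.fixture(scope="session")
def p1_task(p1_lexicon) -> TaskStructure:
    return _load_quiet(DATA / "participant1_task.csv", p1_lexicon)


@pytest.fixture(scope="session")
def p2_task(p2_lexicon) -> TaskStructure:
    return _load_quiet(DATA / "participant2_task.csv", p2_lexicon)


def check_task_constraints(task: TaskStructure, n_pairs: int, max_run: int = 3) -> list[str]:
    """Independent structural checker for generated tasks.

    Verifies trial count, contiguous block order, per-block once-per-target
    coverage, per-block left/right balance, bounded side runs, yoking
    (constant partner) and no back-to-back pair repeats.  Written directly
    over the trial list, sharing no code with the builder.
    """
    problems: list[str] = []
    trials = task.trials
    if len(trials) != 6 * n_pairs:
        problems.append(f"expected {6 * n_pairs} trials, got {len(trials)}")

    order = ["carrier1"] * (2 * n_pairs) + ["carrier2"] * (2 * n_pairs) + [
        "single_word"
    ] * (2 * n_pairs)
    if [t.trial_type for t in trials] != order:
        problems.append("trial types not in three contiguous sequential blocks")

    partner: dict[str, str] = {}
    for t in trials:
        a, b = t.left_image.word, t.right_image.word
        for x, y in ((a, b), (b, a)):
            if partner.setdefault(x, y) != y:
                problems.append(f"{x} paired with both {partner[x]} and {y}")

    for block_start in range(0, len(trials), 2 * n_pairs):
        block = trials[block_start : block_start + 2 * n_pairs]
        targets = [
            (t.left_image.word if t.target_side == "left" else t.right_image.word)
            for t in block
        ]
        if sorted(targets) != sorted(set(targets)) or len(set(targets)) != 2 * n_pairs:
            problems.append(f"block at {block_start}: targets not each-exactly-once")
        lefts = sum(t.target_side == "left" for t in block)
        if lefts != n_pairs:
            problems.append(f"block at {block_start}: unbalanced sides ({lefts} left)")

    sides = [t.target_side for t in trials]
    run, prev = 0, None
    for s in sides:
        run = run + 1 if s == prev else 1
        prev = s
        if run > max_run:
            problems.append(f"side run exceeds {max_run}")
            break

    if n_pairs >= 2:
        for i in range(len(trials) - 1):
            k1 = frozenset({trials[i].left_image.word, trials[i].right_image.word})
            k2 = frozenset({trials[i + 1].left_image.word, trials[i + 1].right_image.word})
            if k1 == k2:
                problems.append(f"pair repeated back-to-back at trial {i + 1}")

    for t in trials:
        if t.trial_type == "single_word" and t.primer not in ("Ooh", "Look"):
            problems.append(f"trial {t.trial_number}: missing primer")
        if t.trial_type != "single_word" and t.primer is not None:
            problems.append(f"trial {t.trial_number}: unexpected primer")
    return problems
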