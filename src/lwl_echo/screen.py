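"""Identify confirmed delayed echoes and extract imageable target words.

The screening pipeline has three stages:

1. :func:`consensus_candidates` — keep only utterances that *both* trained
   coders independently flagged as possible delayed echolalia.
2. :func:`confirm_with_parent` — check each candidate against a parent-report
   checklist; phrases the parent never heard the child repeat are excluded,
   and phrases the parent adds (common at home but absent from the language
   samples) become new confirmed candidates.
3. :func:`extract_targets` — pull the imageable nouns/verbs (and multiword
   proper names or fixed expressions) out of each confirmed echo, using an
   explicit per-child imageability lexicon.

Imageability is a human judgment and therefore lives in the lexicon file, not
in code.  Phrase matching between transcripts and checklist entries is a
normalized exact match (case-folded, punctuation-stripped, whitespace
collapsed): the checklist is constructed *from* the candidate list, so strict
matching is both faithful and auditable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("lwl_echo")

#: Parent-report frequency levels, ordered.  Only the Never / non-Never
#: distinction gates inclusion in the task.
FREQUENCY_LEVELS = ("Never", "Monthly", "Weekly", "Daily")

#: Lexical classes a target word may carry.
WORD_CLASSES = ("noun", "verb", "proper_noun", "fixed_expression")


# ---------------------------------------------------------------------------
# Text normalization
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^\w\s]+", re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class MatcherConfig:
    """Controls how phrases are normalized before exact matching."""

    casefold: bool = True
    strip_punctuation: bool = True
    collapse_whitespace: bool = True


def normalize_phrase(text: str, config: MatcherConfig = MatcherConfig()) -> str:
    """Normalize a phrase for matching (case-fold, strip punctuation,
    collapse whitespace).  Curly quotes count as punctuation."""
    out = text
    if config.casefold:
        out = out.casefold()
    if config.strip_punctuation:
        out = _PUNCT_RE.sub(" ", out)
    if config.collapse_whitespace:
        out = _WS_RE.sub(" ", out).strip()
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Utterance:
    """One transcribed child utterance from a language sample."""

    utterance_id: str
    transcript: str
    sample_id: str = ""
    timestamp_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.transcript and self.sample_id != "parent_report":
            # Empty transcripts are tolerated only for degenerate-input tests;
            # they yield zero targets downstream.
            logger.warning("utterance %s has an empty transcript", self.utterance_id)


@dataclass(frozen=True)
class CoderAnnotation:
    """One coder's judgment of one utterance."""

    utterance_id: str
    coder_id: str
    flagged: bool
    cues: frozenset[str] = frozenset()
    note: str = ""


@dataclass(frozen=True)
class ParentReport:
    """One row of the parent checklist."""

    phrase: str
    frequency: str
    source: str = ""
    parent_added: bool = False

    def __post_init__(self) -> None:
        if self.frequency not in FREQUENCY_LEVELS:
            raise ValueError(
                f"frequency {self.frequency!r} not one of {FREQUENCY_LEVELS}"
            )


@dataclass
class EchoCandidate:
    """An utterance flagged as possible delayed echolalia, with its
    parent-confirmation status and (optional) source."""

    utterance: Utterance
    coder_flags: dict[str, bool]
    confirmed: bool = False
    frequency: Optional[str] = None
    source: str = ""
    parent_added: bool = False
    #: Optional free-text note (e.g. verbatim vs. mitigated); never gates
    #: inclusion.
    note: str = ""


@dataclass(frozen=True)
class TargetWord:
    """An imageable word (or multiword name) usable as a task target.

    ``use_determiner`` and ``audio_form`` are per-word overrides for audio
    rendering; ``None`` means "use the default rule for this word class".
    """

    word: str
    word_class: str
    imageable: bool = True
    source_phrase: str = ""
    source_media: str = ""
    use_determiner: Optional[bool] = None
    audio_form: Optional[str] = None

    def __post_init__(self) -> None:
        if self.word_class not in WORD_CLASSES:
            raise ValueError(
                f"word_class {self.word_class!r} not one of {WORD_CLASSES}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.word, self.word_class)


#: A lexicon maps the *normalized* form of a word to its entry.  Multiword
#: proper names and fixed expressions are single entries.
Lexicon = dict[str, TargetWord]


def lexicon_from_entries(entries: Iterable[TargetWord]) -> Lexicon:
    lex: Lexicon = {}
    for entry in entries:
        lex[normalize_phrase(entry.word)] = entry
    return lex


# ---------------------------------------------------------------------------
# Stage 1: dual-coder consensus
# ---------------------------------------------------------------------------


def consensus_candidates(
    annotations: Sequence[CoderAnnotation],
    utterances: Sequence[Utterance],
) -> tuple[list[EchoCandidate], list[tuple[str, str]]]:
    """Intersect the two coders' flagged sets.

    Returns ``(candidates, rejection_log)``.  A candidate is retained only if
    *both* coders flagged the utterance as possible delayed echolalia; every
    other utterance appears in the rejection log with reason ``"single-coder"``
    (exactly one flag) or ``"unflagged"`` (no flags).

    Raises ``ValueError`` if an annotation references an unknown utterance, if
    the annotation set does not contain exactly two coders, if any
    (utterance, coder) pair is annotated more than once, or if any pair is
    missing an annotation.
    """
    by_id = {u.utterance_id: u for u in utterances}
    if len(by_id) != len(utterances):
        raise ValueError("duplicate utterance_id in utterance list")

    coder_ids = sorted({a.coder_id for a in annotations})
    if len(coder_ids) != 2:
        raise ValueError(
            f"expected exactly two coders, found {len(coder_ids)}: {coder_ids}"
        )

    flags: dict[tuple[str, str], bool] = {}
    for ann in annotations:
        if ann.utterance_id not in by_id:
            raise ValueError(f"annotation references unknown utterance {ann.utterance_id!r}")
        pair = (ann.utterance_id, ann.coder_id)
        if pair in flags:
            raise ValueError(f"duplicate annotation for {pair}")
        flags[pair] = ann.flagged

    missing = [
        (u.utterance_id, c)
        for u in utterances
        for c in coder_ids
        if (u.utterance_id, c) not in flags
    ]
    if missing:
        raise ValueError(f"missing annotation for utterance-coder pairs: {missing}")

    candidates: list[EchoCandidate] = []
    rejections: list[tuple[str, str]] = []
    for utt in utterances:
        per_coder = {c: flags[(utt.utterance_id, c)] for c in coder_ids}
        n_flagged = sum(per_coder.values())
        if n_flagged == 2:
            candidates.append(EchoCandidate(utterance=utt, coder_flags=per_coder))
        elif n_flagged == 1:
            rejections.append((utt.utterance_id, "single-coder"))
        else:
            rejections.append((utt.utterance_id, "unflagged"))
    return candidates, rejections


# ---------------------------------------------------------------------------
# Stage 2: parent confirmation
# ---------------------------------------------------------------------------


def confirm_with_parent(
    candidates: Sequence[EchoCandidate],
    reports: Sequence[ParentReport],
    matcher_config: MatcherConfig = MatcherConfig(),
) -> list[EchoCandidate]:
    """Apply the parent checklist to the consensus candidates.

    Candidates whose phrase the parent reports ``Never`` having heard are
    marked ``confirmed=False``; Monthly/Weekly/Daily confirm the candidate and
    attach the reported source.  Parent-added phrases with no matching
    candidate are appended as new confirmed candidates.

    The checklist must be complete: a candidate with no matching report is an
    error (the checklist is constructed from the candidate list).
    """
    report_by_norm: dict[str, ParentReport] = {}
    for rep in reports:
        key = normalize_phrase(rep.phrase, matcher_config)
        if key in report_by_norm:
            raise ValueError(f"duplicate checklist phrase after normalization: {rep.phrase!r}")
        report_by_norm[key] = rep

    out: list[EchoCandidate] = []
    matched_keys: set[str] = set()
    unmatched: list[str] = []
    for cand in candidates:
        key = normalize_phrase(cand.utterance.transcript, matcher_config)
        rep = report_by_norm.get(key)
        if rep is None:
            unmatched.append(cand.utterance.transcript)
            continue
        matched_keys.add(key)
        out.append(
            EchoCandidate(
                utterance=cand.utterance,
                coder_flags=dict(cand.coder_flags),
                confirmed=rep.frequency != "Never",
                frequency=rep.frequency,
                source=rep.source,
                note=cand.note,
            )
        )
    if unmatched:
        raise ValueError(
            "candidates with no matching checklist entry: " + "; ".join(repr(t) for t in unmatched)
        )

    n_added = 0
    for key, rep in report_by_norm.items():
        if key in matched_keys:
            continue
        if rep.parent_added:
            n_added += 1
            out.append(
                EchoCandidate(
                    utterance=Utterance(
                        utterance_id=f"parent:{n_added}",
                        transcript=rep.phrase,
                        sample_id="parent_report",
                    ),
                    coder_flags={},
                    confirmed=rep.frequency != "Never",
                    frequency=rep.frequency,
                    source=rep.source,
                    parent_added=True,
                )
            )
        else:
            logger.warning(
                "checklist phrase %r matches no candidate and is not parent-added; ignored",
                rep.phrase,
            )
    return out


# ---------------------------------------------------------------------------
# Stage 3: target extraction
# ---------------------------------------------------------------------------


def extract_targets(
    confirmed: Sequence[EchoCandidate],
    lexicon: Lexicon,
) -> list[TargetWord]:
    """Extract every imageable lexicon word found in the confirmed echoes.

    Multiword lexicon entries ("Mickey Mouse", "Keepy Uppy") are matched
    greedily, longest-first, over the normalized token sequence of each
    phrase.  Results are deduplicated by (word, word_class); each target
    carries the first source phrase it was found in.  Phrases that yield no
    imageable word produce a log entry.  The output is sorted so the target
    set is independent of the order of the confirmed list.
    """
    if not confirmed:
        raise ValueError("nothing to extract: empty confirmed-candidate list")
    bad = [c.utterance.transcript for c in confirmed if not c.confirmed]
    if bad:
        raise ValueError(f"unconfirmed candidates passed to extract_targets: {bad}")

    entry_tokens = {key: tuple(key.split()) for key in lexicon}
    max_len = max((len(t) for t in entry_tokens.values()), default=1)

    # phrase order must not matter: scan in a canonical order
    ordered = sorted(confirmed, key=lambda c: normalize_phrase(c.utterance.transcript))

    found: dict[tuple[str, str], TargetWord] = {}
    for cand in ordered:
        phrase = cand.utterance.transcript
        tokens = normalize_phrase(phrase).split()
        hits = 0
        i = 0
        while i < len(tokens):
            match = None
            for n in range(min(max_len, len(tokens) - i), 0, -1):
                key = " ".join(tokens[i : i + n])
                if key in lexicon:
                    match = lexicon[key]
                    i += n
                    break
            if match is None:
                i += 1
                continue
            if match.imageable:
                hits += 1
                if match.key not in found:
                    found[match.key] = replace(
                        match, source_phrase=phrase, source_media=cand.source
                    )
        if hits == 0:
            logger.info("phrase yields no imageable target: %r", phrase)

    return sorted(found.values(), key=lambda t: (t.word.casefold(), t.word_class))


# ---------------------------------------------------------------------------
# File I/O (plain UTF-8 TSV/CSV with header rows)
# ---------------------------------------------------------------------------


def read_utterances(path: str | Path) -> list[Utterance]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        ts = getattr(row, "timestamp_s", "")
        out.append(
            Utterance(
                utterance_id=row.utterance_id,
                transcript=row.transcript,
                sample_id=getattr(row, "sample_id", ""),
                timestamp_s=float(ts) if ts not in ("", None) else None,
            )
        )
    return out


_TRUE = {"1", "true", "yes", "y", "t"}


def _as_bool(value: str) -> bool:
    return str(value).strip().casefold() in _TRUE


def read_annotations(path: str | Path) -> list[CoderAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        cues = getattr(row, "cues", "")
        out.append(
            CoderAnnotation(
                utterance_id=row.utterance_id,
                coder_id=row.coder_id,
                flagged=_as_bool(row.flagged),
                cues=frozenset(c.strip() for c in cues.split(",") if c.strip()),
            )
        )
    return out


def read_checklist(path: str | Path) -> list[ParentReport]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        ParentReport(
            phrase=row.phrase,
            frequency=row.frequency,
            source=getattr(row, "source", ""),
            parent_added=_as_bool(getattr(row, "parent_added", "")),
        )
        for row in df.itertuples(index=False)
    ]


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a per-child imageability lexicon (TSV).

    Required columns: word, word_class, imageable.  Optional columns:
    use_determiner (blank = class default), audio_form (surface form used in
    audio scripts, blank = class default).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        det = getattr(row, "use_determiner", "")
        audio = getattr(row, "audio_form", "")
        entries.append(
            TargetWord(
                word=row.word,
                word_class=row.word_class,
                imageable=_as_bool(row.imageable),
                use_determiner=_as_bool(det) if det.strip() != "" else None,
                audio_form=audio if audio.strip() != "" else None,
            )
        )
    return lexicon_from_entries(entries)


def write_echo_inventory(
    candidates: Sequence[EchoCandidate],
    targets: Sequence[TargetWord],
    path: str | Path,
) -> None:
    """Write the confirmed-echo inventory: one row per (echo phrase, target)."""
    by_phrase: dict[str, list[str]] = {}
    for t in targets:
        by_phrase.setdefault(t.source_phrase, []).append(t.word)
    rows = []
    for cand in candidates:
        if not cand.confirmed:
            continue
        phrase = cand.utterance.transcript
        words = by_phrase.get(phrase, [])
        rows.append(
            {
                "echo_phrase": phrase,
                "target_words": "; ".join(words),
                "frequency": cand.frequency or "",
                "source": cand.source,
                "parent_added": cand.parent_added,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_rejections(rejections: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(rejections, columns=["utterance_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
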