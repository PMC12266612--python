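"""Review corpora: I/O, clause segmentation, tokenization.

A review is a free-text record tied to a doctor and a week index.
Reviews are split into clauses at punctuation marks — the clause is the
unit of aspect classification and sentiment scoring — and clauses are
tokenized with an optional stopword filter. The default tokenizer is a
whitespace split; real Chinese text needs a word segmenter, which can be
plugged in as a callable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

#: Chinese and ASCII sentence/clause punctuation used as clause boundaries.
DEFAULT_DELIMITERS = frozenset("，。！？；、,.!?;:…")


@dataclass(frozen=True)
class Review:
    """One patient review: opaque ids plus a week index and raw text."""

    review_id: str
    doctor_id: str
    week: int
    text: str

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError(f"week must be non-negative, got {self.week}")


@dataclass(frozen=True)
class Clause:
    """A punctuation-delimited sub-unit of a review, optionally tokenized."""

    review_id: str
    ordinal: int
    text: str
    tokens: tuple[str, ...] = ()


@dataclass(frozen=True)
class TokenizerConfig:
    """Clause-boundary characters, stopwords, and tokenizer mode.

    ``mode`` is ``"whitespace"`` (default) or ``"segmenter"``; the latter
    requires ``segmenter``, a callable mapping text to a token list (e.g.
    a Chinese word segmenter).
    """

    delimiter_set: frozenset[str] = DEFAULT_DELIMITERS
    stopword_list: frozenset[str] = frozenset()
    mode: str = "whitespace"
    segmenter: Callable[[str], list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.delimiter_set:
            raise ValueError("delimiter_set must be non-empty")
        if self.mode not in ("whitespace", "segmenter"):
            raise ValueError(f"unknown tokenizer mode: {self.mode!r}")
        if self.mode == "segmenter" and self.segmenter is None:
            raise ValueError("mode='segmenter' requires a segmenter callable")


def segment_clauses(text: str, cfg: TokenizerConfig | None = None) -> list[Clause]:
    """Split ``text`` into clauses at delimiter characters.

    Maximal runs of non-delimiter characters become clauses; runs that
    are empty or pure whitespace are dropped. Clause text is preserved
    verbatim (no trimming), so joining clause texts with single
    delimiters recovers the original up to delimiter identity.
    The ``review_id`` of the returned clauses is empty; callers attach it.
    """
    cfg = cfg or TokenizerConfig()
    delims = cfg.delimiter_set
    clauses: list[Clause] = []
    run: list[str] = []

    def flush() -> None:
        piece = "".join(run)
        run.clear()
        if piece.strip():
            clauses.append(Clause(review_id="", ordinal=len(clauses), text=piece))

    for ch in text:
        if ch in delims:
            flush()
        else:
            run.append(ch)
    flush()
    return clauses


def tokenize(clause: Clause, cfg: TokenizerConfig | None = None) -> Clause:
    """Return ``clause`` with ``tokens`` populated; stopwords are removed.

    Token order is preserved. A clause whose every token is a stopword
    ends up with an empty token tuple.
    """
    cfg = cfg or TokenizerConfig()
    if cfg.mode == "segmenter":
        raw = cfg.segmenter(clause.text)  # type: ignore[misc]
    else:
        raw = clause.text.split()
    tokens = tuple(t for t in raw if t not in cfg.stopword_list)
    return replace(clause, tokens=tokens)


def segment_and_tokenize(review: Review, cfg: TokenizerConfig | None = None) -> list[Clause]:
    """Segment a review and tokenize every clause, attaching the review id."""
    cfg = cfg or TokenizerConfig()
    out = []
    for cl in segment_clauses(review.text, cfg):
        cl = tokenize(replace(cl, review_id=review.review_id), cfg)
        out.append(cl)
    return out


# ---------------------------------------------------------------------------
# I/O: JSON-lines corpora, CSV clause tables

_REVIEW_FIELDS = ("review_id", "doctor_id", "week", "text")


def read_corpus(path: str | Path) -> list[Review]:
    """Read a JSON-lines corpus (one review object per line).

    Raises ``ValueError`` naming the offending line for malformed JSON,
    missing fields, or duplicate review ids.
    """
    path = Path(path)
    reviews: list[Review] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            missing = [f for f in _REVIEW_FIELDS if f not in rec]
            if missing:
                raise ValueError(f"{path}:{lineno}: missing fields {missing}")
            rid = str(rec["review_id"])
            if rid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate review_id {rid!r}")
            seen.add(rid)
            reviews.append(
                Review(
                    review_id=rid,
                    doctor_id=str(rec["doctor_id"]),
                    week=int(rec["week"]),
                    text=str(rec["text"]),
                )
            )
    return reviews


def write_corpus(reviews: Iterable[Review], path: str | Path) -> None:
    """Write reviews as UTF-8 JSON-lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in reviews:
            fh.write(
                json.dumps(
                    {
                        "review_id": r.review_id,
                        "doctor_id": r.doctor_id,
                        "week": r.week,
                        "text": r.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_clauses(clauses: Iterable[Clause], path: str | Path) -> None:
    """Write clauses to CSV: review_id, ordinal, text, space-joined tokens."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["review_id", "ordinal", "text", "tokens"])
        for cl in clauses:
            writer.writerow([cl.review_id, cl.ordinal, cl.text, " ".join(cl.tokens)])


def read_clauses(path: str | Path) -> list[Clause]:
    """Read a clause CSV written by :func:`write_clauses`."""
    path = Path(path)
    out: list[Clause] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                Clause(
                    review_id=row["review_id"],
                    ordinal=int(row["ordinal"]),
                    text=row["text"],
                    tokens=tuple(row["tokens"].split()) if row["tokens"] else (),
                )
            )
    return out
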