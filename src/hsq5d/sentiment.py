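"""Rule-based lexicon sentiment scoring of clauses.

Each clause is scanned for sentiment-bearing words. A sentiment word at
position ``k`` contributes its signed polarity, multiplied by the degree
weights and sign-flipped once per negation word found in its *scope*:
the token span after the previous sentiment word (or the clause start)
up to ``k - 1``. The raw clause score is the sum of contributions; the
normalized score divides by the clause token count. Clause scores with
aspect labels aggregate to doctor-week-dimension scores, normalized by
the total token count of the contributing clauses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SentimentLexicons:
    """Polarity values, degree-adverb multipliers, and negation words.

    The three word sets must be pairwise disjoint. Degree weights are
    strictly positive multipliers; words absent from the degree table
    carry an implicit weight of 1.
    """

    polarity: Mapping[str, float]
    degree: Mapping[str, float] = field(default_factory=dict)
    negation: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        pol, deg, neg = set(self.polarity), set(self.degree), set(self.negation)
        for a, b, name in (
            (pol, deg, "polarity/degree"),
            (pol, neg, "polarity/negation"),
            (deg, neg, "degree/negation"),
        ):
            overlap = a & b
            if overlap:
                raise ValueError(f"{name} lexicons overlap: {sorted(overlap)[:5]}")
        bad = [w for w, v in self.degree.items() if v <= 0]
        if bad:
            raise ValueError(f"degree weights must be > 0: {bad[:5]}")


@dataclass(frozen=True)
class ClauseScore:
    """Signed sentiment of one clause: raw sum and per-token normalization."""

    review_id: str
    ordinal: int
    dimension: str
    raw: float
    normalized: float
    n_tokens: int


def score_clause(
    tokens: Sequence[str],
    lexicons: SentimentLexicons,
    *,
    review_id: str = "",
    ordinal: int = 0,
    dimension: str = "other",
) -> ClauseScore:
    """Score one tokenized clause with the scope rule described above.

    A clause with no sentiment word scores 0. ``tokens`` must be
    non-empty.
    """
    if not tokens:
        raise ValueError("cannot score an empty clause")
    raw = 0.0
    scope_start = 0
    for k, tok in enumerate(tokens):
        p = lexicons.polarity.get(tok)
        if p is None:
            continue
        weight = 1.0
        n_neg = 0
        for t in tokens[scope_start:k]:
            weight *= lexicons.degree.get(t, 1.0)
            if t in lexicons.negation:
                n_neg += 1
        raw += p * weight * (-1.0 if n_neg % 2 else 1.0)
        scope_start = k + 1
    return ClauseScore(
        review_id=review_id,
        ordinal=ordinal,
        dimension=dimension,
        raw=raw,
        normalized=raw / len(tokens),
        n_tokens=len(tokens),
    )


def aggregate_dimension_scores(
    clause_scores: Iterable[ClauseScore],
    doctor_week: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Aggregate clause scores to doctor-week-dimension rows.

    ``doctor_week`` maps review_id -> (doctor_id, week). Clauses labeled
    "other" are excluded. Per (doctor, week, dimension) group the score
    is (sum of raw clause scores) / (sum of clause token counts); groups
    with no clauses emit no row.

    Returns a DataFrame with columns doctor_id, week, dimension, score,
    n_clauses, n_tokens.
    """
    rows = []
    for cs in clause_scores:
        if cs.dimension == "other":
            continue
        doctor_id, week = doctor_week[cs.review_id]
        rows.append((doctor_id, week, cs.dimension, cs.raw, cs.n_tokens))
    if not rows:
        return pd.DataFrame(
            columns=["doctor_id", "week", "dimension", "score", "n_clauses", "n_tokens"]
        )
    df = pd.DataFrame(rows, columns=["doctor_id", "week", "dimension", "raw", "n_tokens"])
    agg = (
        df.groupby(["doctor_id", "week", "dimension"], sort=True)
        .agg(raw_sum=("raw", "sum"), n_clauses=("raw", "size"), n_tokens=("n_tokens", "sum"))
        .reset_index()
    )
    agg["score"] = agg["raw_sum"] / agg["n_tokens"]
    return agg[["doctor_id", "week", "dimension", "score", "n_clauses", "n_tokens"]]


# ---------------------------------------------------------------------------
# Lexicon file I/O: three TSV files (word<TAB>value / word<TAB>weight / word)


def _read_tsv_table(path: Path, n_cols: int, value_name: str) -> dict[str, float]:
    table: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, got {len(parts)}"
                )
            word = parts[0]
            if n_cols == 1:
                value = 1.0
            else:
                try:
                    value = float(parts[1])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric {value_name} {parts[1]!r}"
                    ) from exc
            if word in table:
                logger.warning("%s:%d: duplicate word %r, last value wins", path, lineno, word)
            table[word] = value
    return table


def read_lexicons(
    polarity_path: str | Path,
    degree_path: str | Path | None = None,
    negation_path: str | Path | None = None,
) -> SentimentLexicons:
    """Read the three lexicon TSV files; missing degree/negation files mean
    empty tables. Disjointness across files is enforced."""
    polarity = _read_tsv_table(Path(polarity_path), 2, "polarity")
    degree = _read_tsv_table(Path(degree_path), 2, "weight") if degree_path else {}
    negation = (
        frozenset(_read_tsv_table(Path(negation_path), 1, "")) if negation_path else frozenset()
    )
    return SentimentLexicons(polarity=polarity, degree=degree, negation=negation)


def write_lexicons(lexicons: SentimentLexicons, directory: str | Path) -> dict[str, Path]:
    """Write lexicons as polarity.tsv / degree.tsv / negation.tsv under
    ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "polarity": directory / "polarity.tsv",
        "degree": directory / "degree.tsv",
        "negation": directory / "negation.tsv",
    }
    with paths["polarity"].open("w", encoding="utf-8") as fh:
        for w, v in sorted(lexicons.polarity.items()):
            fh.write(f"{w}\t{v:g}\n")
    with paths["degree"].open("w", encoding="utf-8") as fh:
        for w, v in sorted(lexicons.degree.items()):
            fh.write(f"{w}\t{v:g}\n")
    with paths["negation"].open("w", encoding="utf-8") as fh:
        for w in sorted(lexicons.negation):
            fh.write(f"{w}\n")
    return paths
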