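"""Synthetic review corpora, lexicons, and demand panels with ground truth.

Real platform review data cannot be redistributed, so every stage of
the pipeline is exercised on generated data whose true structure is
known. The generator emits:

* a sentiment lexicon (schematic tokens, balanced positive/negative
  polarity words, degree adverbs, negation words, neutral filler);
* a clause-structured review corpus — each clause carries one of the
  six aspect labels, is built from aspect-exclusive vocabulary plus one
  sentiment word whose sign follows a logistic link on the doctor's
  latent quality for that dimension, with optional degree/negation
  decoration — joined into review text by clause delimiters so that
  segmentation recovers the generated clause boundaries exactly;
* a doctor-week demand panel generated from the validation regression
  (latent log demand = α + Γ·X_{t−1} + controls + θ_t + μ_i + ε, with
  a Poisson-count mode through the exponential link);
* ground-truth tables tying every artifact row back to its generating
  labels, polarities, quality draws, and effects.

Default coefficients Γ, aspect prevalences, and quality means mirror
the published estimates of the platform study the pipeline implements
(see docs/methods.md for the exact provenance of each default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from hsq5d.constants import DIMENSIONS, LABELS
from hsq5d.corpus import Clause, Review, TokenizerConfig, segment_clauses
from hsq5d.sentiment import SentimentLexicons, score_clause

#: Published panel estimates used as the generator's true coefficients,
#: in canonical dimension order.
TABLE1_GAMMA = (1.12, 5.60, 0.82, 2.65, 0.26)

#: Cross-sectional SDs of the five dimension scores (expertise, process,
#: attitude, empathy, outcome) used when scores are drawn directly.
DIMENSION_SCORE_SDS = (0.03, 0.02, 0.04, 0.03, 0.10)

#: Mean dimension scores; expertise/attitude/outcome are published
#: descriptive statistics, process/empathy are package choices.
QUALITY_MEANS = (0.04, 0.04, 0.06, 0.03, 0.03)

#: Clause-label prevalences from the published clause classification
#: counts (871,522 process / 795,568 attitude / 563,312 expertise /
#: 299,663 outcome / 135,032 empathy / 2,812,759 other).
_CLAUSE_COUNTS = {
    "expertise": 563_312,
    "process": 871_522,
    "attitude": 795_568,
    "empathy": 135_032,
    "outcome": 299_663,
    "other": 2_812_759,
}
ASPECT_PREVALENCE = tuple(
    _CLAUSE_COUNTS[lab] / sum(_CLAUSE_COUNTS.values()) for lab in LABELS
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    # ~11 reviews per doctor-week and ~8 clauses per review match the
    # published corpus ratios (672,195 reviews / 4,925 doctors / 12 weeks;
    # 5,477,856 clauses / 672,195 reviews)
    n_doctors: int = 50
    n_weeks: int = 10
    reviews_per_doctor_week: float = 11.0      # Poisson mean
    clauses_per_review: tuple[int, int] = (4, 12)
    aspect_prevalence: tuple[float, ...] = ASPECT_PREVALENCE
    # vocabulary sizes
    n_aspect_terms: int = 20                   # exclusive terms per label
    n_sentiment_words: int = 20                # per polarity sign
    n_degree_words: int = 3
    n_negation_words: int = 2
    n_filler_words: int = 30
    degree_weights: tuple[float, ...] = (0.5, 1.5, 2.0)
    p_degree: float = 0.3                      # P(degree adverb before sentiment word)
    p_negation: float = 0.15                   # P(negation word before sentiment word)
    # latent quality -> polarity link
    quality_means: tuple[float, ...] = QUALITY_MEANS
    quality_sds: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5)
    polarity_slope: float = 2.0                # P(positive) = logistic(slope * quality)
    # demand model truth
    alpha: float = 0.0
    gamma: tuple[float, ...] = TABLE1_GAMMA
    score_sds: tuple[float, ...] = DIMENSION_SCORE_SDS
    doctor_effect_sd: float = 1.0
    week_effect_sd: float = 1.0
    noise_sd: float = 0.5
    demand_mode: str = "latent_log"            # or "count"
    with_controls: bool = False
    control_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.aspect_prevalence) - 1.0) > 1e-9:
            raise ValueError("aspect_prevalence must sum to 1")
        if self.reviews_per_doctor_week <= 0:
            raise ValueError("reviews_per_doctor_week must be > 0")
        if any(s < 0 for s in self.quality_sds + self.score_sds):
            raise ValueError("SDs must be non-negative")
        if self.demand_mode not in ("latent_log", "count"):
            raise ValueError(f"unknown demand_mode {self.demand_mode!r}")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_lexicons(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[SentimentLexicons, dict[str, list[str]]]:
    """Build schematic lexicons and the aspect-term manifest.

    Words are tagged identifiers (``pos3``, ``neg1``, ``deg0``, ``not0``,
    ``expertise_t4``, ``fill7``), guaranteeing disjointness between all
    word classes. Positive and negative polarity words are balanced
    (+1/−1). The manifest maps each label to its exclusive term list.
    """
    del seed  # vocabulary is structural, not random
    polarity = {f"pos{i}": 1.0 for i in range(config.n_sentiment_words)}
    polarity.update({f"neg{i}": -1.0 for i in range(config.n_sentiment_words)})
    weights = config.degree_weights
    degree = {
        f"deg{i}": weights[i % len(weights)] for i in range(config.n_degree_words)
    }
    negation = frozenset(f"not{i}" for i in range(config.n_negation_words))
    manifest = {
        lab: [f"{lab}_t{i}" for i in range(config.n_aspect_terms)] for lab in LABELS
    }
    manifest["filler"] = [f"fill{i}" for i in range(config.n_filler_words)]
    return SentimentLexicons(polarity=polarity, degree=degree, negation=negation), manifest


@dataclass
class CorpusTruth:
    """Ground truth for a generated corpus."""

    clause_labels: pd.DataFrame        # review_id, ordinal, label, polarity
    doctor_quality: pd.DataFrame       # doctor_id, one column per dimension
    dimension_scores: pd.DataFrame     # doctor_id, week, dimension, score, n_clauses, n_tokens


def generate_corpus(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[list[Review], list["LabeledClauseRecord"], CorpusTruth, SentimentLexicons]:
    """Generate reviews with clause-level ground truth.

    Returns (reviews, labeled clause records, truth, lexicons). The
    truth dimension scores are computed by applying the package's own
    clause-scoring and aggregation rules to the generated clauses with
    their true labels, so a perfect classifier reproduces them exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lexicons, manifest = generate_lexicons(config)
    pos_words = sorted(w for w, v in lexicons.polarity.items() if v > 0)
    neg_words = sorted(w for w, v in lexicons.polarity.items() if v < 0)
    deg_words = sorted(lexicons.degree)
    not_words = sorted(lexicons.negation)
    filler = manifest["filler"]
    dim_index = {d: i for i, d in enumerate(DIMENSIONS)}

    quality = {
        f"d{di:04d}": np.array(
            [rng.normal(m, s) for m, s in zip(config.quality_means, config.quality_sds)]
        )
        for di in range(config.n_doctors)
    }

    reviews: list[Review] = []
    labeled: list[LabeledClauseRecord] = []
    truth_rows = []
    lo, hi = config.clauses_per_review
    prev = np.array(config.aspect_prevalence)
    rid = 0
    for doctor_id, q in quality.items():
        for week in range(config.n_weeks):
            n_reviews = rng.poisson(config.reviews_per_doctor_week)
            for _ in range(n_reviews):
                review_id = f"r{rid:06d}"
                rid += 1
                n_clauses = int(rng.integers(lo, hi + 1))
                clause_texts = []
                for ordinal in range(n_clauses):
                    label = LABELS[int(rng.choice(len(LABELS), p=prev))]
                    toks = list(rng.choice(manifest[label], size=2, replace=False))
                    if label == "other":
                        positive = rng.random() < 0.5
                    else:
                        positive = rng.random() < _logistic(
                            config.polarity_slope * q[dim_index[label]]
                        )
                    decoration = []
                    if rng.random() < config.p_degree and deg_words:
                        decoration.append(str(rng.choice(deg_words)))
                    negated = bool(not_words) and rng.random() < config.p_negation
                    if negated:
                        decoration.append(str(rng.choice(not_words)))
                    # surface word sign is flipped under negation so the
                    # clause's net polarity still follows the quality link
                    surface_positive = positive != negated
                    sentiment = str(rng.choice(pos_words if surface_positive else neg_words))
                    toks += decoration + [sentiment]
                    if config.n_filler_words:
                        toks += list(
                            rng.choice(filler, size=int(rng.integers(0, 3)), replace=False)
                        )
                    clause_texts.append(" ".join(toks))
                    labeled.append(
                        LabeledClauseRecord(
                            review_id=review_id,
                            ordinal=ordinal,
                            doctor_id=doctor_id,
                            week=week,
                            tokens=tuple(toks),
                            label=label,
                            polarity=1.0 if positive else -1.0,
                        )
                    )
                    truth_rows.append((review_id, ordinal, label, 1.0 if positive else -1.0))
                reviews.append(
                    Review(
                        review_id=review_id,
                        doctor_id=doctor_id,
                        week=week,
                        text="，".join(clause_texts),
                    )
                )

    clause_labels = pd.DataFrame(
        truth_rows, columns=["review_id", "ordinal", "label", "polarity"]
    )
    doctor_quality = pd.DataFrame(
        [{"doctor_id": d, **dict(zip(DIMENSIONS, q))} for d, q in quality.items()]
    )
    truth_scores = _oracle_dimension_scores(labeled, lexicons)
    truth = CorpusTruth(
        clause_labels=clause_labels,
        doctor_quality=doctor_quality,
        dimension_scores=truth_scores,
    )
    return reviews, labeled, truth, lexicons


@dataclass(frozen=True)
class LabeledClauseRecord:
    """A generated clause with its full provenance."""

    review_id: str
    ordinal: int
    doctor_id: str
    week: int
    tokens: tuple[str, ...]
    label: str
    polarity: float

    def to_clause(self) -> Clause:
        return Clause(
            review_id=self.review_id,
            ordinal=self.ordinal,
            text=" ".join(self.tokens),
            tokens=self.tokens,
        )


def _oracle_dimension_scores(
    labeled: list[LabeledClauseRecord], lexicons: SentimentLexicons
) -> pd.DataFrame:
    """Dimension scores under the oracle classifier (true labels)."""
    from hsq5d.sentiment import aggregate_dimension_scores

    scores = [
        score_clause(
            rec.tokens,
            lexicons,
            review_id=rec.review_id,
            ordinal=rec.ordinal,
            dimension=rec.label,
        )
        for rec in labeled
    ]
    doctor_week = {rec.review_id: (rec.doctor_id, rec.week) for rec in labeled}
    return aggregate_dimension_scores(scores, doctor_week)


def draw_dimension_scores(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw doctor-week dimension scores directly: i.i.d. normal with the
    configured means and cross-sectional SDs. Used for panel-only
    simulations where the text stage is not exercised."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nd, nw, k = config.n_doctors, config.n_weeks, len(DIMENSIONS)
    draws = rng.normal(
        np.asarray(config.quality_means), np.asarray(config.score_sds), size=(nd, nw, k)
    )
    doctor_ids = np.repeat([f"d{i:04d}" for i in range(nd)], nw * k)
    weeks = np.tile(np.repeat(np.arange(nw), k), nd)
    dims = np.tile(np.array(DIMENSIONS), nd * nw)
    return pd.DataFrame(
        {"doctor_id": doctor_ids, "week": weeks, "dimension": dims, "score": draws.ravel()}
    )


@dataclass
class PanelTruth:
    """Generating effects of a synthetic demand panel."""

    doctor_effects: pd.Series
    week_effects: pd.Series
    noise: pd.DataFrame      # doctor_id, week, eps
    gamma: tuple[float, ...]
    alpha: float


def generate_panel(
    config: GeneratorConfig,
    dimension_scores: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, PanelTruth]:
    """Generate demand from the validation regression's data model.

    Demand at week t uses the dimension scores at week t−1, so rows are
    produced for weeks 1..n_weeks−1 wherever all five lagged scores
    exist. Returns (demand table, controls table or None, truth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wide = dimension_scores.pivot_table(
        index=["doctor_id", "week"], columns="dimension", values="score"
    )
    doctors = sorted(dimension_scores["doctor_id"].unique())
    weeks = range(1, config.n_weeks)
    mu = pd.Series(
        rng.normal(0.0, config.doctor_effect_sd, size=len(doctors)), index=doctors
    )
    theta = pd.Series(
        rng.normal(0.0, config.week_effect_sd, size=config.n_weeks),
        index=range(config.n_weeks),
    )

    controls = None
    control_contrib = {}
    if config.with_controls:
        controls = _draw_controls(doctors, rng)
        effects = config.control_effects or {
            "chronic": -0.14, "rank": -0.08, "gender": 0.045,
            "log_rating": -0.15, "log_visits": 0.53, "log_votes": 0.14,
            "log_thanks": 0.21, "log_gifts": 0.25,
        }
        logged = controls.set_index("doctor_id").copy()
        for col in ("visits", "votes", "thanks", "gifts"):
            logged[f"log_{col}"] = np.log1p(logged[col])
        for d in doctors:
            control_contrib[d] = sum(
                coef * float(logged.loc[d, var]) for var, coef in effects.items()
                if var in logged.columns
            )
    gamma = np.array(config.gamma)
    wide = wide.reindex(columns=list(DIMENSIONS))
    score_row = dict(zip(wide.index, wide.to_numpy(dtype=float)))

    rows, noise_rows = [], []
    for d in doctors:
        for t in weeks:
            x = score_row.get((d, t - 1))
            if x is None or np.isnan(x).any():
                continue
            eps = rng.normal(0.0, config.noise_sd)
            latent = (
                config.alpha + float(gamma @ x) + control_contrib.get(d, 0.0)
                + theta[t] + mu[d] + eps
            )
            if config.demand_mode == "count":
                y = int(rng.poisson(np.exp(latent)))
            else:
                y = latent
            rows.append((d, t, y))
            noise_rows.append((d, t, eps))

    demand = pd.DataFrame(rows, columns=["doctor_id", "week", "demand"])
    truth = PanelTruth(
        doctor_effects=mu,
        week_effects=theta,
        noise=pd.DataFrame(noise_rows, columns=["doctor_id", "week", "eps"]),
        gamma=config.gamma,
        alpha=config.alpha,
    )
    return demand, controls, truth


def _draw_controls(doctors: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Time-invariant doctor controls from simple documented distributions,
    centred near the published descriptive statistics."""
    n = len(doctors)
    return pd.DataFrame(
        {
            "doctor_id": doctors,
            "chronic": rng.binomial(1, 0.4958, size=n),
            "gender": rng.binomial(1, 0.3486, size=n),
            "rank": rng.integers(1, 5, size=n),
            "log_rating": np.log(np.clip(rng.normal(3.72, 0.58, size=n), 0.5, None)),
            "visits": rng.lognormal(mean=11.0, sigma=1.5, size=n).astype(int),
            "votes": rng.lognormal(mean=3.5, sigma=1.2, size=n).astype(int),
            "thanks": rng.lognormal(mean=2.5, sigma=1.2, size=n).astype(int),
            "gifts": rng.lognormal(mean=3.4, sigma=1.3, size=n).astype(int),
        }
    )


def coefficient_recovery_study(
    n_doctors: int = 500,
    n_weeks: int = 20,
    n_replicates: int = 100,
    seed: int = 1,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the demand-model coefficients.

    Each replicate draws doctor-week dimension scores i.i.d. normal with
    the configured means and SDs, generates latent log-demand from the
    validation regression with the published coefficient vector as
    truth, and re-estimates it by two-way fixed effects with
    doctor-clustered errors. Returns one row per replicate with the five
    estimates and the panel size; column order follows the canonical
    dimension order.
    """
    from hsq5d.panel import build_panel, fit_fe

    base = config or GeneratorConfig(n_doctors=n_doctors, n_weeks=n_weeks)
    seeder = np.random.default_rng(seed)
    rep_seeds = seeder.integers(0, 2**31 - 1, size=(n_replicates, 2))
    rows = []
    for score_seed, panel_seed in rep_seeds:
        scores = draw_dimension_scores(base, seed=int(score_seed))
        demand, _, _ = generate_panel(base, scores, seed=int(panel_seed))
        res = fit_fe(build_panel(scores, demand), mode="twoway_fe")
        rows.append([float(res.params[d]) for d in DIMENSIONS] + [res.n])
    return pd.DataFrame(rows, columns=list(DIMENSIONS) + ["n_obs"])


# ---------------------------------------------------------------------------
# Named presets


@dataclass
class ScenarioBundle:
    """Everything one run of the pipeline needs, with ground truth."""

    config: GeneratorConfig
    reviews: list[Review]
    labeled: list[LabeledClauseRecord]
    lexicons: SentimentLexicons
    corpus_truth: CorpusTruth
    demand: pd.DataFrame
    controls: pd.DataFrame | None
    panel_truth: PanelTruth


_PRESETS = {
    "separable-small": GeneratorConfig(
        n_doctors=12,
        n_weeks=6,
        reviews_per_doctor_week=6.0,
        clauses_per_review=(2, 6),
        aspect_prevalence=(0.15, 0.15, 0.15, 0.15, 0.15, 0.25),  # all cues well-populated
        n_filler_words=0,       # clauses carry only class-exclusive + sentiment tokens
        p_degree=0.0,
        p_negation=0.0,
        noise_sd=0.1,
    ),
    "paper-defaults": GeneratorConfig(),
    "null-effects": GeneratorConfig(
        n_doctors=50,
        n_weeks=10,
        gamma=(0.0, 0.0, 0.0, 0.0, 0.0),
    ),
}


def scenario(name: str, seed: int = 0) -> ScenarioBundle:
    """Build a full named scenario: corpus + lexicons + labels + panel.

    Presets: "separable-small" (tiny, noise-free, vocabulary-separable),
    "paper-defaults" (published coefficients and prevalences as truth),
    "null-effects" (Γ = 0).
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    config = replace(_PRESETS[name], seed=seed)
    reviews, labeled, corpus_truth, lexicons = generate_corpus(config)
    demand, controls, panel_truth = generate_panel(
        config, corpus_truth.dimension_scores, seed=seed + 1
    )
    return ScenarioBundle(
        config=config,
        reviews=reviews,
        labeled=labeled,
        lexicons=lexicons,
        corpus_truth=corpus_truth,
        demand=demand,
        controls=controls,
        panel_truth=panel_truth,
    )
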