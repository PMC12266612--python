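# Methods

This note documents the models, defaults, and numerical choices behind
`hsq5d`, and what the synthetic-data experiments do and do not show.

## Clause segmentation and tokenization

A clause is a maximal run of non-delimiter characters with non-whitespace
content. The default delimiter inventory is the union of CJK and ASCII
sentence/clause punctuation `，。！？；、,.!?;:…`; it is configurable because
punctuation conventions vary across platforms. Clause text is kept verbatim
(no trimming) so that re-joining clauses with single delimiters recovers the
original text up to delimiter identity; whitespace-only runs are dropped.
Tokenization defaults to a whitespace split with stopword removal, which is
exact for the schematic synthetic corpora; for real Chinese text a word
segmenter can be plugged in as a callable (`TokenizerConfig(mode="segmenter",
segmenter=...)`). The package deliberately carries no segmenter dependency.

## Topic model

Latent Dirichlet allocation with symmetric priors, inferred by collapsed
Gibbs sampling: token topics are resampled from
`p(z=k) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ)` with the token's own counts removed.
Defaults: `α = 50/K`, `β = 0.01` (common fitting practice), single chain,
seeded and fully reproducible.

Held-out evaluation uses fold-in Gibbs: topic-word distributions `φ̂` are
frozen from training counts, each held-out document's mixture `θ̂` is a
20-sweep Gibbs point estimate, and perplexity is
`exp(−Σ log Σ_k θ̂_dk φ̂_kw / N)`. Out-of-vocabulary tokens are dropped.
Fold-in is simpler than left-to-right evaluation and adequate for comparing
topic counts.

**Topic-count selection caveat.** With `α = 50/K` the total prior mass `Kα`
is constant in K, so on short documents held-out perplexity decreases
essentially monotonically in K — the prior never penalizes extra topics.
`select_topic_count` therefore accepts its own `alpha`; a weak K-independent
prior (`alpha ≈ 0.5`) restores a perplexity minimum at the true topic count
on synthetic corpora and is what the documentation and tests use for
selection. Ties in mean perplexity (compared at 1e-9 to absorb float noise)
break toward larger mean log-likelihood, then smaller K.

Near-duplicate topics are merged greedily: while any pair of smoothed
topic-word vectors has cosine similarity above the threshold (default 0.75),
the most similar pair's count rows are summed and topics renumbered. Count
conservation is asserted after every merge. Annotator agreement on topic
labels is the mean per-topic cosine of bag-of-words label vectors.

## Aspect classifier

A shallow linear classifier in the fastText style: features are words
(optional word bigrams), each with a d-dimensional embedding; a clause is
the mean of its feature embeddings; a 6-way softmax produces probabilities.
Plain softmax suffices for six classes. Training is per-example SGD on the
negative log-likelihood with the learning rate decaying linearly to zero
over `epochs × n` updates. Defaults follow the grid-search optimum used
throughout: learning rate 0.8, 25 epochs, dimension 20, unigrams only.
Embeddings initialize uniform(−1/d, 1/d), output weights at zero; training
is deterministic given the seed. Ties in the argmax break by the fixed class
order (expertise, process, attitude, empathy, outcome, other). A clause with
no in-vocabulary features falls back to "other" with uniform probabilities,
so unclassifiable text never contributes to a quality dimension downstream.

Train/test splitting is stratified per label (within one clause of the
target fraction). Cohen's kappa uses marginal chance agreement; the
degenerate case of two identical constant annotators returns 1 by
convention. Gold-standard construction from two annotators keeps only
agreeing pairs and logs the dropped count.

## Sentiment scoring

The scorer implements the standard lexicon algorithm: for each sentiment
word at position k, its *scope* is the token span after the previous
sentiment word (or clause start) up to k−1. Degree-adverb weights inside the
scope multiply; an odd number of negation words flips the sign. Scoping to
the preceding segment (rather than the whole clause) prevents one adverb
from being counted against two sentiment words. The clause's raw score is
the sum of contributions; the normalized score divides by the clause token
count. Doctor-week-dimension aggregation divides the summed raw scores by
the summed token counts of the contributing clauses — the two
normalizations coincide for single-clause groups. Clauses labeled "other"
are excluded from aggregation. Scores are not capped or rescaled.

The shipped lexicons are synthetic (schematic tokens, polarities ±1, degree
weights 0.5/1.5/2): real sentiment dictionaries are licensed and cannot be
redistributed, and the algorithm is lexicon-agnostic. Lexicon files are
three TSVs (word/value, word/weight, word); the three word sets must be
disjoint, duplicate entries within a file resolve last-wins with a warning.

## Panel model and estimation

The validation regression is
`Y_it = α + Γ X_{i,t−1} + Ctrl_it + θ_t + μ_i + ε_it`, demand explained by
the previous week's five dimension sentiments plus doctor controls and
two-way fixed effects, errors clustered by doctor. Count-valued controls
(homepage visits, votes, thanks, gifts) enter as `log(1+count)`, which
handles zeros; demand can be regressed raw (latent-log simulations) or as
`log(1+Y)` (count mode).

Two estimation modes are exposed because published tables of this model
report coefficients on time-invariant doctor attributes (chronic, rank,
gender) that a true doctor-FE model cannot identify:

* `twoway_fe` — the within estimator via alternating doctor/week demeaning
  (exact in one pass on balanced panels, iterated to 1e-12 group-mean
  convergence otherwise). Numerically identical (1e-8, verified in tests)
  to OLS on full doctor and week dummy columns. Time-invariant controls are
  dropped with a notice.
* `pooled_weekfe` — pooled OLS with week dummies, keeping time-invariant
  controls identifiable.

Clustered covariance is the CR1 sandwich with correction
`G/(G−1) · (N−1)/(N−K)`, K counted as the equivalent dummy-regression
column count; this matches statsmodels' clustered OLS exactly. p-values use
the normal reference (cluster counts are large in intended use). The
reported R² includes the variance explained by the fixed effects, which is
what a stepwise "information load" comparison of nested models needs; when
a newly added stepwise regressor is exactly collinear with the current
model it contributes ΔR² = 0 rather than an error. Missing score weeks
follow a `drop` (default) or `carry_forward` policy. The outlier robustness
helper removes the ⌊fN⌋ lowest and highest rows by the dependent variable
with a stable sort, so ties resolve by row order.

## Synthetic-data generator

The generator emulates the review-to-demand structure the pipeline assumes,
with defaults pinned to the published study's printed facts:

* **Scale ratios**: ~11 reviews per doctor-week and 4–12 clauses per review
  (means of the printed corpus ratios: 672,195 reviews / 4,925 doctors /
  12 weekly crawls; 5,477,856 clauses / 672,195 reviews). Default test
  scale is 50 doctors × 10 weeks; the recovery study uses 500 × 20.
* **Clause-label prevalences** from the printed classification counts:
  process .159, attitude .145, expertise .103, outcome .055, empathy .025,
  other .513.
* **Dimension-score means** 0.04 (expertise), 0.06 (attitude), 0.03
  (outcome) are printed descriptive statistics; process 0.04 and empathy
  0.03 are unprinted and were fixed once at comparable magnitudes.
  Cross-sectional score SDs (0.03, 0.02, 0.04, 0.03, 0.10) are backed out
  of the printed one-SD marginal effects.
* **True coefficients** Γ = (1.12, 5.60, 0.82, 2.65, 0.26); doctor and week
  effects N(0,1); noise N(0, 0.5²).

Clauses are schematic token strings: two aspect-exclusive terms, one
sentiment word whose sign follows `P(positive) = logistic(2 × quality)` on
the doctor's latent quality for that dimension, optional degree (p=0.3) and
negation (p=0.15) decoration — under negation the surface sentiment word is
flipped so the clause's *net* polarity still follows the quality link — and
filler tokens. Reviews join clauses with a delimiter, so segmentation
recovers the generated boundaries exactly. Ground-truth dimension scores
are computed by applying the package's own scoring rules to the generated
clauses under their true labels; a perfect classifier therefore reproduces
them exactly (the "pipeline identity" test), and a trained classifier on
the separable preset does so in practice.

What this does **not** show: the generator's vocabulary-separable clauses
make classification far easier than real clinical language; its sentiment
words are unambiguous; reviews arrive homogeneously (Poisson) with no
review-length or selection effects; and controls are generated
independently of quality. Passing tests demonstrate correctness of the
algorithms and of the estimator under the assumed data-generating process,
not performance on real reviews.

Presets: `separable-small` (tiny, noise-free, uniform prevalences — a
smoke-test fixture), `paper-defaults` (everything above), `null-effects`
(Γ = 0, used to check test size).

## Recovery study and problem sizes

`coefficient_recovery_study` (used by `scripts/acceptance.py`) simulates
100 replicate panels of 500 doctors × 20 weeks (~9,500 usable rows each,
~950,000 total), drawing dimension scores i.i.d. normal at the configured
means/SDs, generating latent log demand, and re-fitting `twoway_fe` per
replicate. Replicate seeds derive deterministically from the single
top-level seed. With noise SD 0.5 the per-replicate coefficient SEs range
from ~0.05 (outcome, score SD 0.10) to ~0.25 (process, score SD 0.02), so
replicate means settle within a few hundredths to a few tenths of the
truth; the estimator is unbiased, and the suite asserts recovery within
2 Monte-Carlo standard errors. Test problem sizes throughout the suite
(e.g. 120 doctors × 10 weeks × 12 replicates for the in-suite recovery
check, 5 seeds for topic-count recovery) were chosen as the smallest scales
at which the statistical assertions have comfortable margins.

## Known limitations

* Single-chain Gibbs at small scale occasionally sticks in a merged-topic
  mode; the topic-count recovery rate on disjoint synthetic corpora is
  ~80%, not 100%, and the suite asserts exactly that.
* The within estimator assumes strict exogeneity; the lagged-sentiment
  design does not address dynamic-panel (Nickell) bias, which the short-T
  simulations here do not surface because the regressors are i.i.d.
* Cue-coverage percentages use half-up rounding to two decimals to match
  conventional reporting; stored counts allow exact recomputation.
* The CLI is a thin convenience layer; the library API is the primary
  interface and the only one the tests target in depth.
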