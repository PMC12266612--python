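# hsq5d

Assess the service quality of health-care providers from patients' online
reviews, and validate the resulting quality scores against patient demand.

Online health platforms host far too many doctors for questionnaire-based
quality assessment (SERVQUAL-style surveys) to scale. `hsq5d` implements a
text-mining alternative built around a five-dimension quality framework —
**expertise**, **service-delivery process**, **communication attitude**,
**empathy**, and **outcome** (HSQ-5D) — turning free-text reviews into
doctor-week quality scores:

1. **Clause segmentation** — reviews split at punctuation into clauses, the
   unit of analysis.
2. **Topic discovery** — collapsed-Gibbs LDA with 3-fold cross-validated
   perplexity to choose the topic count, cosine-similarity merging of
   near-duplicate topics (threshold 0.75), and annotator label-agreement
   scoring. This is the exploratory stage that motivates the five dimensions.
3. **Aspect classification** — a fastText-style averaged n-gram embedding
   classifier assigns each clause one of the five dimensions or "other".
4. **Lexicon sentiment** — each clause gets a signed score: a sentiment word
   with polarity *p* preceded in its scope by degree adverbs (weights
   multiply) and *k* negation words contributes *p · Πw · (−1)^k*; the clause
   score normalizes by token count, and clause scores aggregate to
   doctor-week-dimension scores.
5. **Panel validation** — the demand regression

   ```
   Y_it = α + Γ X_{i,t−1} + Ctrl_it + θ_t + μ_i + ε_it
   ```

   where `Y_it` is (log) patient demand for doctor *i* in week *t* and
   `X_{i,t−1}` the five lagged dimension sentiments, is estimated by the
   two-way fixed-effects within estimator with CR1 doctor-clustered standard
   errors. One-SD marginal effects `exp(γσ)−1` translate coefficients into
   percent demand changes, and a stepwise-R² "information load" curve
   measures how much variance each dimension adds.

Real review corpora cannot be redistributed, so the package ships a
first-class synthetic-data generator (`hsq5d.synthetic`) producing
clause-structured reviews with known aspect labels, latent doctor quality
driving sentiment polarity, and demand panels generated from the regression
above with the published coefficient vector (1.12, 5.60, 0.82, 2.65, 0.26)
as ground truth — every stage is testable end to end against that truth.

## Worked example

`examples/04_demand_regression.py` simulates 600 doctors over 16 weeks from
the demand model and re-estimates it:

```
mode=twoway_fe  n=9000  doctors=600 weeks=15  R2=0.9015
variable              coef        se       t       p
expertise           1.1857    0.1983    5.98   0.000
process             5.1810    0.2742   18.89   0.000
attitude            0.6070    0.1402    4.33   0.000
empathy             2.8188    0.1922   14.67   0.000
outcome             0.2588    0.0588    4.40   0.000

one-SD marginal effects (percent change in demand):
  expertise  gamma*sd = +0.0356  -> +3.6%
```

Each coefficient sits within sampling error of its generating value
(1.12, 5.60, 0.82, 2.65, 0.26); the marginal effect says a one-standard-
deviation improvement in perceived expertise raises weekly demand by ~3.6%.
The other examples cover segmentation and sentiment scoring (`01`), topic
discovery (`02`), aspect classification and Cohen's kappa (`03`), and the
full pipeline with cue-coverage statistics (`05`). A thin CLI mirrors the
stages (`hsq5d simulate | segment | lda | train-aspect | classify | score |
panel | regress | infoload | coverage | run-all`).

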