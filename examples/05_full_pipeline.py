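"""Run the whole pipeline end to end on a generated scenario.

Generates reviews with known clause labels and latent doctor quality,
trains the aspect classifier on a labeled subset, classifies and scores
every clause, aggregates doctor-week dimension scores, computes cue
coverage, and fits the demand regression.
"""

from hsq5d.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(preset="separable-small", seed=1))

print(f"reviews: {report['n_reviews']}, clauses: {report['n_clauses']}")
print(f"classifier held-out accuracy: {report['aspect_eval']['accuracy']:.3f}")

cov = report["coverage"]
print("\nshare of reviews mentioning each dimension:")
for dim, share in cov["review_share"].items():
    print(f"  {dim:<10} {share:6.2f}%  ({cov['review_counts'][dim]}/{cov['n_reviews']})")
print(f"reviews with >= 1 cue: {cov['review_k_or_more']['1']:.2f}%"
      if "1" in cov["review_k_or_more"] else
      f"reviews with >= 1 cue: {cov['review_k_or_more'][1]:.2f}%")

reg = report["regression"]
print(f"\ndemand regression ({reg['mode']}, n={reg['n']}, R2={reg['r2']:.3f}):")
for dim, coef in reg["coefficients"].items():
    print(f"  {dim:<10} {coef:+.3f}  (clustered SE {reg['clustered_se'][dim]:.3f})")

print(
    "\ncoefficients close to the generating values (1.12, 5.60, 0.82, 2.65,\n"
    "0.26) confirm the text stages preserve the quality signal end to end."
)
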