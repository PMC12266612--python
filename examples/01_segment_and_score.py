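"""Segment a review into clauses and score each clause's sentiment.

Builds a tiny lexicon by hand, splits one review at punctuation marks,
and applies the scope rule (degree adverbs multiply, an odd number of
negations flips the sign, scores normalize by clause length).
"""

from hsq5d import SentimentLexicons, TokenizerConfig, score_clause, segment_clauses, tokenize

lexicons = SentimentLexicons(
    polarity={"good": 1.0, "kind": 1.0, "bad": -1.0},
    degree={"very": 2.0, "slightly": 0.5},
    negation=frozenset({"not"}),
)

review = "very kind doctor, treatment not good, slightly bad wait."
cfg = TokenizerConfig(delimiter_set=frozenset(",."))

print(f"review: {review!r}\n")
for clause in segment_clauses(review, cfg):
    clause = tokenize(clause, cfg)
    s = score_clause(clause.tokens, lexicons)
    print(f"  clause {clause.ordinal}: {clause.text.strip()!r:28} "
          f"raw {s.raw:+.1f}  normalized {s.normalized:+.3f}")

print(
    "\nraw is the signed sum of sentiment-word contributions after degree\n"
    "and negation adjustment; normalized divides by the token count, so\n"
    "longer clauses with the same cue carry a weaker per-word signal."
)
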