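"""Fixed label sets shared across the pipeline.

The five quality dimensions follow the HSQ-5D framework (expertise,
service-delivery process, communication attitude, empathy, outcome);
"other" is the residual class for clauses that express none of them.
The tuple order is canonical: it fixes classifier tie-breaking, column
order in panels, and the order of regression coefficients.
"""

DIMENSIONS: tuple[str, ...] = ("expertise", "process", "attitude", "empathy", "outcome")
LABELS: tuple[str, ...] = DIMENSIONS + ("other",)
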