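"""Parameter recovery: consensus rises with the generator's coupling.

Runs the full pipeline over synthetic sessions at three coupling levels
(30 sessions each here; the validation suite uses 100). Mean consensus
should grow monotonically from near the chance rate at kappa = 0 to
essentially 100% at kappa = 1 — the pipeline recovers the planted degree
of physiological synchrony.
"""

from ppgphylo import coupling_sweep

sweep = coupling_sweep([0.0, 0.5, 1.0], n_seeds=30, master_seed=0)
print(sweep.round(3).to_string(index=False))
print("\nmean_consensus_pct: average Table-style consensus over sessions;")
print("full_support_rate: fraction of sessions where all three measures agree;")
print("cherry_rate_*: per-measure frequency of the Care-giver/During-care clade.")
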