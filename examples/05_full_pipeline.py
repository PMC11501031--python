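"""One-call end-to-end run: simulate -> DE -> motifs -> enrichment -> pools.

Equivalent to `matdecay run --mode both --seed 1 --outdir example_run` on the
command line.  Writes the full artifact tree (TSVs, manifest, summary JSON)
and prints the summary counts.
"""

import json

from matdecay.pipeline import RunConfig, run

cfg = RunConfig(
    mode="both",
    seed=1,
    outdir="example_run",
    sim=dict(n_genes=1500, depth=400_000, housekeeping_top_n=30),
    thresholds=dict(n_trials=200, trial_n=150, pool_size=60),
)
summary = run(cfg)
print(json.dumps(summary, indent=2))
print("\nArtifacts under example_run/: de_*.tsv, motif_stats.tsv,")
print("enrichment_trials.tsv, pools.tsv, reexpression.tsv, manifest.json.")
print("pool_label_recovery_pct compares called pools against planted truth;")
print("the weak 1.6-fold nos-null stabilization is the limiting call.")
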