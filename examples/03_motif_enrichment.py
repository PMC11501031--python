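"""Length-matched resampling test for 3'-UTR motif enrichment.

Simulates 3' UTRs in which targeted mRNAs carry a planted Nanos-response-
element-like motif (UAUAUA-UGU-A) at probability 0.5 versus 0.2 for
non-targets, then asks — over 200 trials, each comparing length-matched
random subsets — whether the motif and its +4-position variants are enriched
among targeted UTRs (one-sided Fisher per trial, Hommel-adjusted across the
variant family within each trial).
"""

from matdecay import (
    MotifPattern,
    SimParams,
    presence_enrichment_trials,
    simulate_counts,
    simulate_utrs,
    variant_patterns,
)

params = SimParams(
    n_genes=2000,
    depth=400_000,
    motif_prob_target=0.5,
    motif_prob_nontarget=0.2,
    seed=7,
    housekeeping_top_n=10,
)
_, truth = simulate_counts(params)
utrs = simulate_utrs(params, truth)
by_id = {u.gene_id: u for u in utrs}
targeted = [by_id[g] for g in truth.loc[truth["is_target"], "gene_id"]]
nontargeted = [by_id[g] for g in truth.loc[~truth["is_target"], "gene_id"]]

# the +4 family: substitutions at the position after the UGU core
family = variant_patterns(MotifPattern("NRE", "UAUAUAUGUA"), position=9, label="+4")
trials = presence_enrichment_trials(
    targeted, nontargeted, family, n_trials=200, n=300, seed=7
)

print(f"{len(targeted)} targeted vs {len(nontargeted)} nontargeted UTRs, "
      f"{trials.n_trials} trials of 300 vs 300 length-matched sequences\n")
print(trials.summary().to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nOnly the planted +4A variant reaches vanishing adjusted p-values;")
print("the unplanted +4G/+4C mutants behave like null patterns, and +4U sees")
print("only background matches.  This is the read-out used to conclude a")
print("motif is preferentially present in regulated 3' UTRs.")
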