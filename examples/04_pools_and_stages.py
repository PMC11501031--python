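"""Partition genes into regulatory pools and summarize their stage profiles.

Uses the published pool counts as a worked overlap example, then runs the
synthetic stage-resolved resource (poly(A) tail length, translational
efficiency, abundance across five stages from stage-11 oocyte to 2-3 h
embryo) through the pool-wise trajectory summary.
"""

import numpy as np
import pandas as pd

from matdecay import (
    GeneSet,
    SimParams,
    StageParams,
    overlap_fraction,
    reexpression_enrichment,
    simulate_counts,
    simulate_stage_table,
)
from matdecay.pools import stage_profile_summary

# --- overlap arithmetic on the published counts -------------------------
stabilized = {f"g{i}" for i in range(1185)}
depleted = {f"g{i}" for i in range(1019)} | {f"b{i}" for i in range(1528)}
ov = overlap_fraction(depleted, stabilized)
print(f"stabilized mRNAs also depleted by the chimera: "
      f"{ov['overlap']}/{ov['denominator']} = {ov['percent_int']}%")

# --- pool-wise stage trajectories on synthetic truth --------------------
params = SimParams(n_genes=1500, depth=300_000, seed=9, housekeeping_top_n=10)
_, truth = simulate_counts(params)
measures = simulate_stage_table(truth, StageParams(seed=9))
pools = pd.DataFrame(
    {
        "gene_id": truth["gene_id"],
        "pool": np.where(truth["is_target"], "B", "C"),
        "upf1nos_target": truth["is_target"],
        "nos_stabilized": False,
    }
).set_index("gene_id", drop=False)

out = stage_profile_summary(measures, pools, pool_pairs=(("B", "C"),))
med = out["medians"].pivot_table(
    index="stage", columns=["quantity", "pool"], values="median", sort=False
)
print("\nmedian translational efficiency by stage (targets=B, others=C):")
print(med["translational_efficiency"].round(2).to_string())
act_p = out["tests"].query(
    "stage == 'activated_egg' and quantity == 'translational_efficiency'"
)["wilcoxon_p"].iloc[0]
print(f"\nB-vs-C Wilcoxon at egg activation: p = {act_p:.2e}")
rep = out["repressed"]["repressed_at_activation"]
print(f"fraction repressed (TE < 1) at activation: {rep.mean()*100:.0f}%")
print("\nTargeted mRNAs fail the translational activation non-targets get at")
print("egg activation — the trajectory signature of Nanos-primed repression.")
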