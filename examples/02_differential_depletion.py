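"""Call depleted genes under massive asymmetric loss: library-size vs anchor.

Runs the same chimera-vs-wildtype contrast twice on the default synthetic
study.  Library-size normalization mis-centres the fold changes (null genes
drift to +0.6 log2 units and some are called 'enriched'); anchor-gene
correction factors, computed from 20 highly expressed genes with stable rank
order, restore the null genes to zero and recover the planted 40% depleted
fraction.
"""

from matdecay import SimParams, de_contrast, simulate_counts

params = SimParams(seed=1)
cm, truth = simulate_counts(params)
design = params.design()

for norm in ("library_size", "anchor"):
    de = de_contrast(
        cm,
        design,
        params.chimera_genotype,
        params.reference_genotype,
        normalization=norm,
        lfc_threshold=1.0,
        pool_size=60,
    )
    null_genes = de.index[~truth.loc[de.index, "is_target"]]
    med = float(de.loc[null_genes, "log2fc"].median())
    depleted = float((de["status"] == "depleted").mean() * 100)
    enriched = float((de["status"] == "enriched").mean() * 100)
    print(f"{norm:>13}: null-gene median log2FC {med:+.3f} | "
          f"called depleted {depleted:.1f}% | called enriched {enriched:.1f}%")
    if norm == "anchor":
        factors = de.attrs["norm_factors"].factors
        chim = [s for s in cm.sample_ids if s.startswith("upf1nos_")]
        print(f"{'':>13}  correction factors per chimera replicate: "
              + ", ".join(f"{factors[s]:.3f}" for s in chim)
              + "  (expected ~1.54 = 1/(1-0.4+0.4/8))")

print("\nPlanted truth: ~42% of tested genes are depleted 8-fold.")
print("Anchor normalization recovers that; library-size normalization both")
print("shifts the null and manufactures spurious enrichment.")
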