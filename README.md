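# matdecay

Analysis toolkit for RNA-seq experiments in which a **large, asymmetric
fraction of the transcriptome is truly depleted** — the situation created when
a degradation-tethering chimera (e.g. Upf1 fused to the translational
repressor Nanos) is expressed in the *Drosophila* female germline and destroys
much of the maternal mRNA pool. It is written for people analysing such
tether-and-degrade screens, or re-analysing maternal-to-zygotic-transition
(MZT) datasets, who need statistics that survive global depletion.

Standard library-size normalization fails in this regime: with sequencing
depth fixed, destroying a fraction *f* of the transcriptome *δ*-fold inflates
every unregulated gene's raw counts by

```
1 / (1 − f + f/δ)        (≈ 1.54, i.e. +0.62 log2 units, at f = 0.4, δ = 8)
```

so null genes masquerade as enriched. The package provides:

* **`matdecay.de`** — anchor-gene correction factors (per test replicate, the
  mean depth-scaled count ratio over the 20 most abundant genes with stable
  rank order between conditions — genes assumed unregulated), plus count
  filtering, isoform→gene binning, moment/shrinkage NB dispersion estimation,
  a conditional negative-binomial exact test, Benjamini–Hochberg FDR, and
  depleted/enriched/unchanged calls at configurable |log2FC| and FDR
  thresholds.
* **`matdecay.motifs`** — IUPAC-degenerate scanning of 3′-UTR sequences
  (overlap-counting, sense strand), e.g. the modified Nanos Response Element
  `UAUAUAUGUW` (+4 ∈ {U, A}), its single-position variants, and per-kilobase
  site densities.
* **`matdecay.enrichment`** — the length-matched resampling presence test
  (per trial: equal-size subsets matched on UTR-length deciles, one-sided
  Fisher exact per motif, Hommel adjustment across the variant family),
  Wilcoxon density comparisons, tricube local-linear LOESS with pointwise
  bands, and a rank-based competitive gene-set ("barcode") test.
* **`matdecay.pools`** — partition of maternal genes into regulatory pools
  (A: depleted by the chimera *and* stabilized in *nos⁻*; B: chimera-only;
  C: neither; nos_only), overlap percentages, zygotic-reexpression Fisher
  tests, decay-class crosstabs and pool-wise poly(A)/TE/abundance stage
  trajectories.
* **`matdecay.simulate`** — a seeded generator producing counts (fixed-depth
  gamma-multinomial, so the oversampling artifact arises mechanically), 3′
  UTRs with planted motifs, stage-resolved poly(A)/TE tables and external
  gene-set memberships, with full ground truth for every gene.
* **`matdecay.pipeline` / `matdecay` CLI** — one-config orchestration of all
  stages with a reproducibility manifest.

## Worked example

```bash
python examples/02_differential_depletion.py
```

prints (seed 1, 6,000 genes, 40% depleted 8-fold, NB dispersion 0.05,
triplicates at 2×10⁶ reads):

```
 library_size: null-gene median log2FC +0.610 | called depleted 42.6% | called enriched 4.9%
       anchor: null-gene median log2FC -0.041 | called depleted 42.6% | called enriched 0.0%
               correction factors per chimera replicate: 1.598, 1.535, 1.589  (expected ~1.54 = 1/(1-0.4+0.4/8))
```

Reading: under library-size normalization the truly unregulated genes sit
+0.61 log2 units from zero — the closed-form oversampling bias — and ~5% of
them are spuriously called enriched. The anchor correction factors recover
the theoretical 1.54 within a few percent, recentre the null at ≈0, and the
depleted-call fraction matches the planted truth. The other examples cover
the generator itself (`01`), the resampling motif-enrichment test (`03`,
planted motif reaches median adjusted p ≈ 10⁻¹⁴ while unplanted
single-mutant variants stay at p = 1), pool trajectories (`04`), and the
end-to-end pipeline (`05`).

The CLI mirrors example 05:

```bash
matdecay run --mode both --seed 1 --outdir run_out
```

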