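"""Count filtering, anchor-gene normalization and NB exact differential expression.

The centrepiece is normalization that is robust to *asymmetric global
depletion*.  When a large fraction of the transcriptome is truly depleted in
one condition, library-size (total-count) normalization silently rescales the
depleted samples so that unregulated genes appear enriched.  The fix is to
compute a per-replicate correction factor from a small set of highly expressed
*anchor* genes assumed unregulated (housekeeping mRNAs): the factor is the
mean, over anchors, of the depth-scaled count ratio between the test replicate
and the reference condition.

Testing is a conditional negative-binomial exact test on group sums, with a
moment-based common dispersion shrunk per gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormFactors",
    "bin_isoforms",
    "filter_low",
    "anchor_factors",
    "library_size_factors",
    "normalized_counts",
    "estimate_dispersion",
    "nb_exact_test",
    "exact_test_matrix",
    "bh_fdr",
    "call_de",
    "de_contrast",
]


@dataclass
class CountMatrix:
    """Integer read counts, genes (rows) x samples (columns).

    `level` is "gene" or "isoform"; at isoform level `isoform_to_gene` maps
    each row id to its parent gene for :func:`bin_isoforms`.
    """

    counts: pd.DataFrame
    level: str = "gene"
    isoform_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.level not in ("gene", "isoform"):
            raise ValueError(f"invalid level {self.level!r}")
        if not self.counts.index.is_unique:
            raise ValueError("row ids must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, level: str = "gene") -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.astype(np.int64), level=level)


@dataclass
class NormFactors:
    """Per-sample positive scaling constants (the correction factors).

    Normalized abundance of gene g in sample s is
    ``count / (library_size * factor) * 1e6`` (CPM against an effective
    library).  ``method`` is "library_size" (all factors 1) or "anchor".
    """

    factors: pd.Series
    method: str = "library_size"
    anchor_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


def bin_isoforms(cm: CountMatrix) -> CountMatrix:
    """Sum isoform counts into gene-level counts; reads are conserved."""
    if cm.level != "isoform":
        raise ValueError("bin_isoforms requires an isoform-level matrix")
    mapping = cm.isoform_to_gene or {}
    orphans = [i for i in cm.counts.index if i not in mapping]
    if orphans:
        raise ValueError(f"isoforms with no gene mapping: {orphans[:10]}")
    genes = cm.counts.index.map(mapping)
    binned = cm.counts.groupby(genes, sort=True).sum()
    return CountMatrix(counts=binned, level="gene")


def _group_sizes(design: pd.DataFrame) -> pd.Series:
    return design.groupby("genotype")["sample_id"].count()


def filter_low(
    cm: CountMatrix,
    design: pd.DataFrame,
    min_count: int = 30,
    min_total: int = 30,
) -> CountMatrix:
    """Drop weakly expressed genes before testing.

    A gene is kept if (i) its CPM exceeds the CPM equivalent of `min_count`
    reads at the median library size in at least as many samples as the
    smallest genotype group, and (ii) its total count across samples is at
    least `min_total`.  At typical depths the CPM rule removes genes below
    roughly 2 counts per million.
    """
    missing = set(cm.sample_ids) - set(design["sample_id"])
    if missing:
        raise ValueError(f"samples missing from design: {sorted(missing)}")
    lib = cm.library_sizes()
    cpm = cm.counts / lib * 1e6
    cutoff = min_count / np.median(lib.to_numpy()) * 1e6
    k = int(_group_sizes(design.loc[design["sample_id"].isin(cm.sample_ids)]).min())
    keep = ((cpm >= cutoff).sum(axis=1) >= k) & (cm.counts.sum(axis=1) >= min_total)
    if not keep.any():
        warnings.warn("filter_low removed every gene")
    return CountMatrix(
        counts=cm.counts.loc[keep],
        level=cm.level,
        isoform_to_gene=cm.isoform_to_gene,
    )


def library_size_factors(cm: CountMatrix) -> NormFactors:
    """Baseline normalization: factors of 1 (depth handled via library sizes)."""
    return NormFactors(
        factors=pd.Series(1.0, index=cm.sample_ids), method="library_size"
    )


def anchor_factors(
    cm: CountMatrix,
    reference_samples: list[str],
    test_samples: list[str],
    n_anchor: int = 20,
    pool_size: int = 30,
) -> NormFactors:
    """Correction factors from highly expressed anchor genes.

    Candidate anchors are the `pool_size` genes with the highest mean
    depth-scaled abundance across the reference samples; survivors are those
    that also rank within the top `pool_size` in every test sample (a similar
    rank order implies they are unlikely to be regulated).  The `n_anchor`
    most abundant survivors are the anchors.  For each test replicate the
    factor is the mean over anchors of (depth-scaled test count) /
    (mean depth-scaled reference count).  Reference samples get factor 1.
    """
    ref = list(reference_samples)
    tst = list(test_samples)
    if set(ref) & set(tst):
        raise ValueError("reference and test samples must be disjoint")
    scaled = cm.counts / cm.library_sizes()
    ref_mean = scaled[ref].mean(axis=1)
    if len(ref_mean) < n_anchor:
        raise ValueError("fewer candidate genes than n_anchor")
    pool = set(ref_mean.nlargest(pool_size).index)
    survivors = set(pool)
    for s in tst:
        survivors &= set(scaled[s].nlargest(pool_size).index)
    if len(survivors) < n_anchor:
        raise ValueError(
            f"only {len(survivors)} anchor candidates survive rank matching; "
            f"raise pool_size (currently {pool_size})"
        )
    anchors = ref_mean.loc[sorted(survivors)].nlargest(n_anchor).index
    factors = pd.Series(1.0, index=cm.sample_ids, dtype=float)
    for s in tst:
        factors[s] = float((scaled.loc[anchors, s] / ref_mean.loc[anchors]).mean())
    return NormFactors(
        factors=factors, method="anchor", anchor_gene_ids=list(anchors)
    )


def normalized_counts(cm: CountMatrix, norm: NormFactors) -> pd.DataFrame:
    """Counts rescaled to a common effective depth (geometric mean)."""
    eff = cm.library_sizes() * norm.factors.reindex(cm.sample_ids)
    common = float(np.exp(np.log(eff.to_numpy()).mean()))
    return cm.counts / eff * common


def estimate_dispersion(
    cm: CountMatrix,
    design: pd.DataFrame,
    norm: NormFactors,
    prior_df: float = 10.0,
    default_phi: float = 0.1,
    min_mean: float = 20.0,
) -> pd.Series:
    """Per-gene NB dispersion: moment estimates shrunk to a common value.

    Within each genotype group with >= 2 replicates the per-gene moment
    estimate is (var - mean) / (mean^2 - var/n), pooled over groups; the
    common dispersion is the mean of these over well-expressed genes, and
    per-gene values are shrunk toward it with weights proportional to the
    residual degrees of freedom against `prior_df`.  The result carries the
    common value in ``.attrs['common']``.
    """
    y = normalized_counts(cm, norm)
    design = design.set_index("sample_id").loc[cm.sample_ids]
    groups = [g.index for _, g in design.groupby("genotype") if len(g) >= 2]
    if not groups:
        warnings.warn(
            "no group has >= 2 replicates; using the configured prior dispersion"
        )
        phi = pd.Series(default_phi, index=cm.gene_ids)
        phi.attrs["common"] = default_phi
        return phi

    num = np.zeros(len(cm.gene_ids))
    den = np.zeros(len(cm.gene_ids))
    mean_expr = np.zeros(len(cm.gene_ids))
    df_resid = 0
    for samples in groups:
        sub = y[samples].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m**2 - v / sub.shape[1]
        mean_expr += m
        df_resid += sub.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    ok = (mean_expr / len(groups) > min_mean) & (den > 0)
    common = float(np.clip(per_gene[ok].mean(), 0.0, None)) if ok.any() else default_phi
    shrunk = (df_resid * np.clip(per_gene, 0.0, None) + prior_df * common) / (
        df_resid + prior_df
    )
    phi = pd.Series(np.clip(shrunk, 0.0, None), index=cm.gene_ids)
    phi.attrs["common"] = common
    return phi


def _conditional_log_pmf(
    total: int, f_a: np.ndarray, f_b: np.ndarray, phi: float
) -> np.ndarray:
    """log P(S_A = k | S_A + S_B = total) for k = 0..total.

    Under the null the group sums are moment-matched NB variables with means
    proportional to the summed effective-depth factors and size
    (sum f)^2 / (phi * sum f^2) (= n/phi for equal factors); with phi = 0 the
    conditional collapses to Binomial(total, sum(f_a) / sum(f)).
    """
    k = np.arange(total + 1)
    sa, sb = f_a.sum(), f_b.sum()
    if phi <= 0:
        return stats.binom.logpmf(k, total, sa / (sa + sb))
    mu = total / (sa + sb)
    r_a = sa**2 / (phi * (f_a**2).sum())
    r_b = sb**2 / (phi * (f_b**2).sum())
    p_a = r_a / (r_a + sa * mu)
    p_b = r_b / (r_b + sb * mu)
    la = stats.nbinom.logpmf(k, r_a, p_a)
    lb = stats.nbinom.logpmf(k[::-1], r_b, p_b)
    joint = la + lb
    # normalize over all splits of the total
    m = joint.max()
    return joint - (m + np.log(np.exp(joint - m).sum()))


def nb_exact_test(
    counts_a,
    counts_b,
    factors_a=None,
    factors_b=None,
    phi: float = 0.0,
) -> float:
    """Two-sided conditional NB exact test for one gene.

    Per-sample factors are relative effective depths (default 1); rather than
    rescaling counts to a common depth, the null folds the factors into the
    conditional distribution of the group sums, so raw integer counts are
    compared directly: the two-sided p-value is the total probability of all
    splits of the observed sum that are no more probable than the observed
    split.  With phi = 0 and single samples this is the exact binomial test
    of a against a+b with p0 = f_a / (f_a + f_b).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    fa = np.ones_like(a) if factors_a is None else np.asarray(factors_a, dtype=float)
    fb = np.ones_like(b) if factors_b is None else np.asarray(factors_b, dtype=float)
    if (fa <= 0).any() or (fb <= 0).any():
        raise ValueError("factors must be positive")
    s_a = int(round(float(a.sum())))
    total = s_a + int(round(float(b.sum())))
    if total == 0:
        return 1.0
    logp = _conditional_log_pmf(total, fa, fb, phi)
    obs = logp[s_a]
    return min(1.0, float(np.exp(logp[logp <= obs + 1e-12]).sum()))


def exact_test_matrix(
    cm: CountMatrix,
    design: pd.DataFrame,
    norm: NormFactors,
    test_genotype: str,
    ref_genotype: str,
    phi: pd.Series,
) -> pd.DataFrame:
    """Gene-wise exact tests plus log2FC/abundance for one contrast.

    log2 fold change uses mean normalized counts with a 0.5 pseudo-count in
    both groups so it stays finite for totally depleted genes; abundance is
    the log2 CPM of the pooled mean.
    """
    d = design.set_index("sample_id")
    a_samples = [s for s in cm.sample_ids if d.loc[s, "genotype"] == test_genotype]
    b_samples = [s for s in cm.sample_ids if d.loc[s, "genotype"] == ref_genotype]
    if not a_samples or not b_samples:
        raise ValueError("contrast genotypes not present in the design")
    eff = cm.library_sizes() * norm.factors.reindex(cm.sample_ids)
    y = normalized_counts(cm, norm)
    mean_a = y[a_samples].mean(axis=1)
    mean_b = y[b_samples].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    pooled = y[a_samples + b_samples].mean(axis=1)
    common_depth = float(np.exp(np.log(eff.to_numpy()).mean()))
    abundance = np.log2((pooled + 0.5) / common_depth * 1e6)

    rel = (eff / common_depth).to_numpy()
    rel = pd.Series(rel, index=cm.sample_ids)
    counts_a = cm.counts[a_samples].to_numpy()
    counts_b = cm.counts[b_samples].to_numpy()
    fa = rel[a_samples].to_numpy()
    fb = rel[b_samples].to_numpy()
    phi_arr = phi.reindex(cm.gene_ids).to_numpy()
    pvals = np.empty(len(cm.gene_ids))
    for i in range(len(cm.gene_ids)):
        pvals[i] = nb_exact_test(counts_a[i], counts_b[i], fa, fb, float(phi_arr[i]))
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": log2fc.to_numpy(),
            "avg_abundance": abundance.to_numpy(),
            "p_value": pvals,
        }
    ).set_index("gene_id", drop=False)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    stats_df: pd.DataFrame,
    lfc_threshold: float,
    fdr_threshold: float = 0.05,
    exclude=None,
) -> pd.DataFrame:
    """Attach FDR and depleted/enriched/unchanged status calls.

    Boundary conventions: |log2fc| >= threshold is inclusive; fdr < alpha is
    strict.  Genes in `exclude` keep their statistics but are flagged
    `excluded` and set to unchanged so they drop out of target sets.
    """
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be positive")
    out = stats_df.copy()
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    sig = out["fdr"] < fdr_threshold
    status = np.where(
        sig & (out["log2fc"] <= -lfc_threshold),
        "depleted",
        np.where(sig & (out["log2fc"] >= lfc_threshold), "enriched", "unchanged"),
    )
    out["status"] = status
    exclude = set(exclude or ())
    unknown = exclude - set(out.index)
    if unknown:
        log.info("%d excluded ids absent from stats; ignored", len(unknown))
    out["excluded"] = out.index.isin(exclude)
    out.loc[out["excluded"], "status"] = "unchanged"
    return out


def de_contrast(
    cm: CountMatrix,
    design: pd.DataFrame,
    test_genotype: str,
    ref_genotype: str,
    normalization: str = "anchor",
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    min_count: int = 30,
    min_total: int = 30,
    n_anchor: int = 20,
    pool_size: int = 30,
    exclude=None,
) -> pd.DataFrame:
    """Full DE pipeline for one two-group contrast.

    Filters weak genes on the contrast samples, computes normalization
    factors ("anchor" or "library_size"), estimates dispersion, runs the NB
    exact test and returns the annotated result table.
    """
    d = design.set_index("sample_id")
    a = [s for s in cm.sample_ids if d.loc[s, "genotype"] == test_genotype]
    b = [s for s in cm.sample_ids if d.loc[s, "genotype"] == ref_genotype]
    sub = CountMatrix(counts=cm.counts[b + a], level=cm.level)
    sub_design = design.loc[design["sample_id"].isin(b + a)]
    sub = filter_low(sub, sub_design, min_count=min_count, min_total=min_total)
    if normalization == "anchor":
        norm = anchor_factors(sub, b, a, n_anchor=n_anchor, pool_size=pool_size)
    elif normalization == "library_size":
        norm = library_size_factors(sub)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    phi = estimate_dispersion(sub, sub_design, norm)
    table = exact_test_matrix(sub, sub_design, norm, test_genotype, ref_genotype, phi)
    result = call_de(table, lfc_threshold, fdr_threshold, exclude=exclude)
    result.attrs["norm_factors"] = norm
    result.attrs["common_dispersion"] = phi.attrs.get("common")
    return result
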