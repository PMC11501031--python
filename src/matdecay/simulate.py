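"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates an experiment in which a large, asymmetric fraction of a
maternal transcriptome is truly depleted in one genotype while sequencing depth
stays fixed.  Under fixed depth the unregulated genes are mechanically
*oversampled* in the depleted genotype: their raw counts rise by a factor
1/(1-f+f/delta), where f is the depleted gene fraction and delta the true
fold-depletion.  That normalization failure mode is the reason the anchor-gene
correction in :mod:`matdecay.de` exists, so it must arise mechanically here.

Counts are drawn by a gamma-multinomial scheme: per replicate, gene weights
w_g ~ Gamma(1/phi, mu_g * phi) and counts ~ Multinomial(depth, w/sum(w)).
Marginally each gene is close to NB(mu_g, phi) while every column sums exactly
to the configured depth.  phi = 0 degenerates to multinomially-thinned Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import CountMatrix
from .motifs import UTRRecord

__all__ = [
    "STAGES",
    "SimParams",
    "StageParams",
    "simulate_counts",
    "simulate_utrs",
    "simulate_stage_table",
    "write_dataset",
]

#: Ordered developmental stages covered by the poly(A)/TE resource tables.
STAGES = (
    "stage_11_oocyte",
    "stage_14_oocyte",
    "activated_egg",
    "embryo_0_1h",
    "embryo_2_3h",
)

DECAY_CLASSES = ("maternal", "zygotic", "both", "other")
_DEGRADED_CLASSES = frozenset({"maternal", "zygotic", "both"})


@dataclass
class SimParams:
    """Study-condition parameters for the synthetic generator.

    Defaults are the conditions the downstream analysis is designed for:
    6,000 maternal genes, triplicates, 2x10^6 reads per sample, 40% of genes
    depleted 8-fold in the chimera genotype, NB dispersion 0.05, and a weaker
    (1.6-fold) stabilization of a subset of genes in the nos-null genotype.
    """

    n_genes: int = 6000
    n_reps: int = 3
    genotypes: tuple[str, ...] = (
        "wt",
        "upf1",
        "nos",
        "upf1nosL7",
        "upf1nos",
        "nosnull",
    )
    depth: int = 2_000_000
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    target_fraction: float = 0.4
    depletion_factor: float = 8.0
    # nos-null contrast: genes stabilized (enriched) in the nosnull genotype.
    stabilized_fraction_of_targets: float = 0.4
    stabilized_fraction_of_nontargets: float = 0.04
    stabilization_factor: float = 1.6
    # a small set of genes perturbed by the Upf1 moiety alone; these are
    # excluded from target calling downstream.
    upf1_altered_fraction: float = 0.045
    upf1_effect: float = 4.0
    # the most abundant genes are housekeeping mRNAs assumed unregulated —
    # the premise anchor normalization rests on
    housekeeping_top_n: int = 50
    # 3' UTR model
    utr_length_logmean: float = 6.2
    utr_length_logsd: float = 0.6
    utr_length_cap: int = 2600
    utr_length_min: int = 30
    target_length_shift: float = 0.0  # added to logmean for targets (length-bias knob)
    motif_prob_target: float = 0.5
    motif_prob_nontarget: float = 0.2
    planted_motif: str = "UAUAUAUGUA"
    background_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}
    )
    # external-set planting probabilities (target, non-target)
    pum_bound_prob: tuple[float, float] = (0.12, 0.05)
    bru_repressed_prob: tuple[float, float] = (0.03, 0.03)
    unstable_unfertilized_prob: tuple[float, float] = (0.3, 0.08)
    # zygotic reexpression probability per pool (A, B, C, nos_only)
    reexpression_prob: dict[str, float] = field(
        default_factory=lambda: {"A": 0.10, "B": 0.43, "C": 0.20, "nos_only": 0.20}
    )
    # probability that a gene is degraded in the early embryo (target, non-target)
    degraded_prob: tuple[float, float] = (0.9, 0.45)
    chimera_genotype: str = "upf1nos"
    reference_genotype: str = "wt"
    nosnull_genotype: str = "nosnull"
    seed: int = 1

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.depletion_factor < 1.0:
            raise ValueError("depletion_factor must be >= 1")
        if self.dispersion < 0.0:
            raise ValueError("dispersion must be >= 0")
        comp = sum(self.background_composition.values())
        if abs(comp - 1.0) > 1e-8:
            raise ValueError(f"background composition sums to {comp}, expected 1")
        if set(self.background_composition) != {"A", "C", "G", "U"}:
            raise ValueError("background composition must cover exactly A, C, G, U")

    def design(self) -> pd.DataFrame:
        """Sample design table matching :func:`simulate_counts` column order."""
        rows = []
        for g in self.genotypes:
            timepoint = "2-3h" if g == self.nosnull_genotype else "nc9-10"
            for r in range(1, self.n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{r}",
                        "genotype": g,
                        "replicate": r,
                        "timepoint": timepoint,
                    }
                )
        return pd.DataFrame(rows)


def _stratified_flags(
    rng: np.random.Generator,
    order: np.ndarray,
    fraction: float,
    stratum: int = 5,
    n_total: int | None = None,
) -> np.ndarray:
    """Boolean flags hitting `fraction` within small strata of `order`.

    Stratifying over abundance ranks pins the abundance-weighted flagged mass
    at `fraction`, which keeps the fixed-depth oversampling artifact at its
    closed-form magnitude instead of fluctuating with the heavy upper tail of
    the abundance law.  `order` holds gene indices (ascending abundance) and
    may cover a subset of the `n_total` genes.
    """
    n = n_total if n_total is not None else (int(order.max()) + 1 if len(order) else 0)
    flags = np.zeros(n, dtype=bool)
    if fraction <= 0 or not len(order):
        return flags
    n_strata = max(1, len(order) // stratum)
    cum = 0.0
    taken = 0
    for s in np.array_split(order, n_strata):
        cum += fraction * len(s)
        # cumulative rounding so the overall fraction is hit exactly even
        # when fraction * stratum size is far from an integer
        k = min(int(round(cum)) - taken, len(s))
        taken += k
        if k > 0:
            flags[rng.choice(s, size=k, replace=False)] = True
    return flags


def simulate_counts(params: SimParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the count matrix and the per-gene ground truth.

    Returns ``(CountMatrix, truth)`` where ``truth`` is a DataFrame indexed by
    gene id with the planted regulatory structure: target/stabilized flags,
    true log2 fold changes, pool labels and external-set memberships.
    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, n)
    order = np.argsort(baseline)

    # The most abundant genes are treated as unregulated housekeeping mRNAs;
    # the target fraction over the remaining genes is scaled up so that the
    # abundance-weighted depleted read mass still equals target_fraction,
    # which keeps the fixed-depth oversampling artifact at its closed form.
    n_hk = min(params.housekeeping_top_n, n)
    housekeeping = order[n - n_hk :] if n_hk else order[:0]
    order_rest = order[: n - n_hk]
    hk_share = baseline[housekeeping].sum() / baseline.sum() if n_hk else 0.0
    f_adj = min(1.0, params.target_fraction / max(1.0 - hk_share, 1e-12))
    is_target = _stratified_flags(rng, order_rest, f_adj, n_total=n)
    is_stab = np.zeros(n, dtype=bool)
    t_idx = np.flatnonzero(is_target)
    nt_idx = np.flatnonzero(~is_target)
    k_t = int(round(params.stabilized_fraction_of_targets * len(t_idx)))
    k_nt = int(round(params.stabilized_fraction_of_nontargets * len(nt_idx)))
    if k_t:
        is_stab[rng.choice(t_idx, k_t, replace=False)] = True
    if k_nt:
        is_stab[rng.choice(nt_idx, k_nt, replace=False)] = True
    is_stab[housekeeping] = False

    is_upf1 = _stratified_flags(
        rng, order_rest, params.upf1_altered_fraction, stratum=25, n_total=n
    )
    upf1_dir = np.where(rng.random(n) < 0.5, -1, 1) * is_upf1

    pool = np.where(
        is_target & is_stab,
        "A",
        np.where(is_target, "B", np.where(is_stab, "nos_only", "C")),
    )

    delta = params.depletion_factor
    gamma = params.stabilization_factor
    multipliers: dict[str, np.ndarray] = {}
    for g in params.genotypes:
        m = np.ones(n)
        if g == params.chimera_genotype:
            m = np.where(is_target, 1.0 / delta, 1.0)
        elif g == params.nosnull_genotype:
            m = np.where(is_stab, gamma, 1.0)
        elif g == "upf1":
            m = np.where(upf1_dir != 0, params.upf1_effect ** upf1_dir, 1.0)
        multipliers[g] = m

    phi = params.dispersion
    design = params.design()
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, row in design.iterrows():
        e = baseline * multipliers[row["genotype"]]
        if phi > 0:
            w = rng.gamma(1.0 / phi, e * phi)
        else:
            w = e
        counts[:, j] = rng.multinomial(params.depth, w / w.sum())

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"].to_numpy()),
        level="gene",
    )

    def _per_class(p_t: float, p_nt: float) -> np.ndarray:
        p = np.where(is_target, p_t, p_nt)
        return rng.random(n) < p

    reexp_p = np.array([params.reexpression_prob[p] for p in pool])
    is_reexp = rng.random(n) < reexp_p
    degraded = _per_class(*params.degraded_prob)
    decay = np.where(
        degraded,
        rng.choice(["maternal", "zygotic", "both"], size=n, p=[0.4, 0.3, 0.3]),
        "other",
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_target": is_target,
            "is_stabilized": is_stab,
            "is_upf1_altered": is_upf1,
            "true_log2fc_chimera": np.where(is_target, -np.log2(delta), 0.0),
            "true_log2fc_nosnull": np.where(is_stab, np.log2(gamma), 0.0),
            "pool": pool,
            "pum_bound": _per_class(*params.pum_bound_prob),
            "bru_repressed": _per_class(*params.bru_repressed_prob),
            "unstable_unfertilized": _per_class(*params.unstable_unfertilized_prob),
            "zygotically_reexpressed": is_reexp,
            "decay_class": decay,
            "planted_site_count": 0,
        }
    ).set_index("gene_id", drop=False)
    truth.index.name = None
    return cm, truth


def simulate_utrs(params: SimParams, truth: pd.DataFrame) -> list[UTRRecord]:
    """Simulate one 3' UTR per gene, planting the configured motif.

    Lengths are i.i.d. log-normal truncated to ``[utr_length_min,
    utr_length_cap]``; targets may draw from a shifted length law when
    ``target_length_shift`` is nonzero.  With probability ``motif_prob_target``
    (targets) or ``motif_prob_nontarget`` (non-targets) a single exact copy of
    ``planted_motif`` overwrites the background sequence at a uniform-random
    valid offset — overwriting (not inserting) keeps the length law
    independent of planting.  ``truth['planted_site_count']`` is updated in
    place.  Deterministic given ``params.seed``.
    """
    params.validate()
    # distinct stream from simulate_counts so the two stages are independent
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7213]))
    alphabet = np.array(["A", "C", "G", "U"])
    probs = np.array([params.background_composition[b] for b in alphabet])
    motif = params.planted_motif.upper().replace("T", "U")
    mlen = len(motif)

    records: list[UTRRecord] = []
    planted = np.zeros(len(truth), dtype=int)
    for i, (gene_id, is_target) in enumerate(
        zip(truth["gene_id"].to_numpy(), truth["is_target"].to_numpy())
    ):
        logmean = params.utr_length_logmean + (
            params.target_length_shift if is_target else 0.0
        )
        length = int(round(rng.lognormal(logmean, params.utr_length_logsd)))
        length = min(max(length, params.utr_length_min), params.utr_length_cap)
        seq = rng.choice(alphabet, size=length, p=probs)
        p_plant = params.motif_prob_target if is_target else params.motif_prob_nontarget
        if rng.random() < p_plant:
            if mlen > length:
                warnings.warn(
                    f"motif ({mlen} nt) longer than UTR of {gene_id} "
                    f"({length} nt); planting skipped"
                )
            else:
                off = rng.integers(0, length - mlen + 1)
                seq[off : off + mlen] = list(motif)
                planted[i] = 1
        records.append(UTRRecord(gene_id=gene_id, sequence="".join(seq)))
    truth["planted_site_count"] = planted
    return records


@dataclass
class StageParams:
    """Configured pool trajectories for the stage-resolved resource table.

    Trajectories are (stage -> mean) vectors over :data:`STAGES` for targeted
    and non-targeted genes.  Defaults encode the regulatory contrast the
    analysis expects: targets keep short/shortening poly(A) tails and are
    translationally repressed (TE < 1) at egg activation, then their abundance
    drops between the 0-1 h and 2-3 h embryo windows; non-targets lengthen
    their tails and are translationally activated (TE > 1).
    """

    polya_target: tuple[float, ...] = (55.0, 50.0, 45.0, 45.0, 40.0)
    polya_nontarget: tuple[float, ...] = (50.0, 55.0, 75.0, 90.0, 90.0)
    te_target: tuple[float, ...] = (0.8, 0.8, 0.7, 0.8, 0.8)
    te_nontarget: tuple[float, ...] = (0.9, 1.0, 1.5, 1.6, 1.5)
    abundance_target: tuple[float, ...] = (5.0, 5.0, 5.0, 5.0, 3.5)
    abundance_nontarget: tuple[float, ...] = (5.0, 5.0, 5.0, 5.0, 4.7)
    polya_sd: float = 8.0
    te_sd: float = 0.2
    abundance_sd: float = 0.5
    stages: tuple[str, ...] = STAGES
    seed: int = 9

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")
        for name in (
            "polya_target",
            "polya_nontarget",
            "te_target",
            "te_nontarget",
            "abundance_target",
            "abundance_nontarget",
        ):
            if len(getattr(self, name)) != len(self.stages):
                raise ValueError(f"{name} must have one value per stage")


def simulate_stage_table(
    truth: pd.DataFrame, stage_params: StageParams | None = None
) -> pd.DataFrame:
    """Per-gene, per-stage poly(A) length, TE and abundance measurements.

    Gaussian noise around the configured pool trajectories; deterministic
    given ``stage_params.seed``.
    """
    sp = stage_params or StageParams()
    sp.validate()
    rng = np.random.default_rng(sp.seed)
    is_target = truth["is_target"].to_numpy()
    n = len(truth)
    rows = []
    for s_idx, stage in enumerate(sp.stages):
        polya = np.where(
            is_target, sp.polya_target[s_idx], sp.polya_nontarget[s_idx]
        ) + rng.normal(0.0, sp.polya_sd, n)
        te = np.where(
            is_target, sp.te_target[s_idx], sp.te_nontarget[s_idx]
        ) + rng.normal(0.0, sp.te_sd, n)
        ab = np.where(
            is_target, sp.abundance_target[s_idx], sp.abundance_nontarget[s_idx]
        ) + rng.normal(0.0, sp.abundance_sd, n)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": truth["gene_id"].to_numpy(),
                    "stage": stage,
                    "poly_a_length": np.clip(polya, 0.0, None),
                    "translational_efficiency": np.clip(te, 0.01, None),
                    "abundance": ab,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_dataset(
    outdir,
    params: SimParams,
    stage_params: StageParams | None = None,
) -> dict[str, str]:
    """Simulate a full dataset and write it as plain-text artifacts.

    Writes counts.tsv, design.tsv, truth.tsv, utrs.fasta, stages.tsv and
    gene_sets.tsv under `outdir`; returns the path map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(params)
    utrs = simulate_utrs(params, truth)
    stages = simulate_stage_table(truth, stage_params)

    paths = {
        "counts": str(outdir / "counts.tsv"),
        "design": str(outdir / "design.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "utrs": str(outdir / "utrs.fasta"),
        "stages": str(outdir / "stages.tsv"),
        "gene_sets": str(outdir / "gene_sets.tsv"),
    }
    cm.to_tsv(paths["counts"])
    params.design().to_csv(paths["design"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["utrs"], "w") as fh:
        for rec in utrs:
            fh.write(f">{rec.gene_id}\n{rec.sequence}\n")
    stages.to_csv(paths["stages"], sep="\t", index=False)
    sets = []
    for col in (
        "pum_bound",
        "bru_repressed",
        "unstable_unfertilized",
        "zygotically_reexpressed",
    ):
        for gid in truth.loc[truth[col], "gene_id"]:
            sets.append({"set_name": col, "gene_id": gid})
    pd.DataFrame(sets, columns=["set_name", "gene_id"]).to_csv(
        paths["gene_sets"], sep="\t", index=False
    )
    return paths
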