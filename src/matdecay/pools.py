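"""Regulatory-pool partition, overlap arithmetic and stage-trajectory summaries.

Maternal genes tested in both contrasts are partitioned by two flags —
depleted by the chimera (target) and enriched in the nos-null embryo at
2-3 h (stabilized) — into pools A (both), B (target only), C (neither) and
nos_only (stabilized only).  The module then quantifies overlaps between
pools and external gene sets (zygotic reexpression, decay classes) and
summarizes pool-wise poly(A)/TE/abundance trajectories across stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet
from .simulate import STAGES

log = logging.getLogger(__name__)

__all__ = [
    "restrict_to_common",
    "assign_pools",
    "overlap_fraction",
    "reexpression_enrichment",
    "stage_profile_summary",
    "decay_class_crosstab",
]

POOLS = ("A", "B", "C", "nos_only")
DECAY_VOCAB = frozenset({"maternal", "zygotic", "both", "other"})
DEGRADED = frozenset({"maternal", "zygotic", "both"})


def restrict_to_common(de1: pd.DataFrame, de2: pd.DataFrame) -> list[str]:
    """Sorted ids of non-excluded genes tested in both contrasts."""
    ids1 = set(de1.loc[~de1["excluded"], "gene_id"])
    ids2 = set(de2.loc[~de2["excluded"], "gene_id"])
    common = sorted(ids1 & ids2)
    if not common:
        raise ValueError("no genes common to the two contrasts")
    return common


def assign_pools(
    de_chimera: pd.DataFrame,
    de_nosnull: pd.DataFrame,
    common: list[str],
) -> pd.DataFrame:
    """Pool labels from the two DE status calls, over the common gene set.

    Thresholds are whatever was baked into each DEResult's status column
    (2-fold for the chimera contrast, log2 +/- 0.5 for the nos-null one).
    """
    for de, name in ((de_chimera, "chimera"), (de_nosnull, "nos-null")):
        missing = set(common) - set(de["gene_id"])
        if missing:
            raise ValueError(
                f"{len(missing)} common genes missing a status in the {name} result"
            )
    target = de_chimera.loc[common, "status"] == "depleted"
    stab = de_nosnull.loc[common, "status"] == "enriched"
    pool = np.where(
        target & stab, "A", np.where(target, "B", np.where(stab, "nos_only", "C"))
    )
    return pd.DataFrame(
        {
            "gene_id": common,
            "upf1nos_target": target.to_numpy(),
            "nos_stabilized": stab.to_numpy(),
            "pool": pool,
        }
    ).set_index("gene_id", drop=False)


def overlap_fraction(numerator_set, denominator_set) -> dict:
    """100 * |num & den| / |den|, with both counts and an integer percent."""
    num = set(numerator_set)
    den = set(denominator_set)
    if not den:
        raise ValueError("denominator set is empty")
    k = len(num & den)
    pct = 100.0 * k / len(den)
    return {
        "overlap": k,
        "denominator": len(den),
        "percent": pct,
        "percent_int": int(round(pct)),
    }


def reexpression_enrichment(
    pools: pd.DataFrame, zygotic: GeneSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pool zygotic-reexpression fractions and pairwise Fisher tests.

    Returns (fractions, pairwise) where fractions has one row per pool with
    counts and percent reexpressed, and pairwise holds the two-sided Fisher
    exact p-value for each pool pair's 2x2 reexpressed/not table.
    """
    reexp = pools["gene_id"].isin(zygotic.members)
    frac_rows = []
    counts: dict[str, tuple[int, int]] = {}
    for pool in POOLS:
        mask = pools["pool"] == pool
        n = int(mask.sum())
        k = int((mask & reexp).sum())
        counts[pool] = (k, n)
        frac_rows.append(
            {
                "pool": pool,
                "n": n,
                "reexpressed": k,
                "percent": 100.0 * k / n if n else np.nan,
            }
        )
    pair_rows = []
    for i, p1 in enumerate(POOLS):
        for p2 in POOLS[i + 1 :]:
            k1, n1 = counts[p1]
            k2, n2 = counts[p2]
            if n1 == 0 or n2 == 0:
                log.info("skipping Fisher test for empty pool pair %s/%s", p1, p2)
                continue
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            pair_rows.append({"pool_1": p1, "pool_2": p2, "fisher_p": p})
    return pd.DataFrame(frac_rows), pd.DataFrame(pair_rows)


def stage_profile_summary(
    measures: pd.DataFrame,
    pools: pd.DataFrame,
    pool_pairs: tuple = (("A", "C"), ("B", "C")),
    quantities: tuple = ("poly_a_length", "translational_efficiency", "abundance"),
) -> dict[str, pd.DataFrame]:
    """Pool-wise stage trajectories and between-pool rank-sum tests.

    Returns a dict with "medians" (pool x stage x quantity medians and IQRs),
    "tests" (two-sided Wilcoxon p per pool pair, stage and quantity) and
    "repressed" (per-gene flag TE < 1 at the activated-egg stage).
    """
    unknown = set(measures["stage"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    pool_map = pools[["gene_id", "pool"]].reset_index(drop=True)
    merged = measures.merge(pool_map, on="gene_id", how="inner")
    med_rows, test_rows = [], []
    for (pool, stage), grp in merged.groupby(["pool", "stage"], sort=False):
        for q in quantities:
            v = grp[q]
            med_rows.append(
                {
                    "pool": pool,
                    "stage": stage,
                    "quantity": q,
                    "median": float(v.median()),
                    "iqr": float(v.quantile(0.75) - v.quantile(0.25)),
                    "n": len(v),
                }
            )
    for stage in STAGES:
        at_stage = merged[merged["stage"] == stage]
        for p1, p2 in pool_pairs:
            g1 = at_stage[at_stage["pool"] == p1]
            g2 = at_stage[at_stage["pool"] == p2]
            if g1.empty or g2.empty:
                log.info("stage %s absent for pool pair %s/%s; skipped", stage, p1, p2)
                continue
            for q in quantities:
                p = float(
                    stats.mannwhitneyu(g1[q], g2[q], alternative="two-sided")[1]
                )
                test_rows.append(
                    {
                        "stage": stage,
                        "pool_1": p1,
                        "pool_2": p2,
                        "quantity": q,
                        "wilcoxon_p": p,
                    }
                )
    act = merged[merged["stage"] == "activated_egg"]
    repressed = pd.DataFrame(
        {
            "gene_id": act["gene_id"].to_numpy(),
            "repressed_at_activation": (
                act["translational_efficiency"] < 1.0
            ).to_numpy(),
        }
    )
    return {
        "medians": pd.DataFrame(med_rows),
        "tests": pd.DataFrame(test_rows),
        "repressed": repressed,
    }


def decay_class_crosstab(
    pools: pd.DataFrame, decay_labels: pd.Series
) -> dict[str, object]:
    """Pool x decay-class contingency table and degradation percentages.

    `decay_labels` maps gene_id to one of maternal/zygotic/both/other, where
    the first three mean the mRNA is degraded in the early embryo (by
    maternal and/or zygotic pathways).  Genes without a label count as
    "other".  Returns the crosstab, the percent degraded within each pool,
    and the percent of chimera targets (pools A+B) that are degraded.
    """
    unknown = set(decay_labels.dropna().unique()) - DECAY_VOCAB
    if unknown:
        raise ValueError(f"unknown decay class labels: {sorted(unknown)}")
    labels = decay_labels.reindex(pools["gene_id"]).fillna("other")
    tab = pd.crosstab(pools["pool"], labels.to_numpy())
    tab = tab.reindex(index=POOLS, columns=sorted(DECAY_VOCAB), fill_value=0)
    degraded = labels.isin(DEGRADED).to_numpy()
    pct_rows = []
    for pool in POOLS:
        mask = (pools["pool"] == pool).to_numpy()
        n = int(mask.sum())
        pct_rows.append(
            {
                "pool": pool,
                "n": n,
                "degraded": int((mask & degraded).sum()),
                "percent_degraded": 100.0 * (mask & degraded).sum() / n
                if n
                else np.nan,
            }
        )
    targets = pools["pool"].isin(("A", "B")).to_numpy()
    pct_targets_degraded = (
        100.0 * (targets & degraded).sum() / targets.sum() if targets.any() else np.nan
    )
    return {
        "crosstab": tab,
        "per_pool": pd.DataFrame(pct_rows),
        "percent_targets_degraded": float(pct_targets_degraded),
    }
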