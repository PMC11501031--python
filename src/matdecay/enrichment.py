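"""Resampling motif-enrichment statistics and competitive gene-set tests.

The central procedure compares the fraction of 3' UTRs bearing at least one
motif between targeted and nontargeted mRNAs.  Because presence scales with
UTR length, each of many trials draws a random subset of targeted UTRs and a
nontargeted subset *matched on the length distribution* (decile bins of the
pooled lengths), tests each motif variant with a one-sided Fisher exact test,
and adjusts p-values across the variant family within the trial by Hommel's
step-up procedure.  The distribution of per-trial adjusted p-values over
trials is the reported evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifPattern, UTRRecord, scan

__all__ = [
    "TrialSet",
    "GeneSet",
    "BarcodeData",
    "length_matched_sample",
    "presence_enrichment_trials",
    "hommel_adjust",
    "density_compare",
    "loess_curve",
    "competitive_set_test",
]


@dataclass
class GeneSet:
    """A named set of gene ids (an externally defined annotation)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        self.name = name
        self.members = frozenset(members)


@dataclass
class TrialSet:
    """Result of the length-matched resampling enrichment test.

    `pvalues` and `adjusted` are (n_trials x n_patterns) DataFrames of raw
    one-sided Fisher p-values and within-trial Hommel-adjusted p-values.
    """

    n_trials: int
    patterns: list[str]
    pvalues: pd.DataFrame
    adjusted: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = []
        for pat in self.patterns:
            p = self.pvalues[pat]
            a = self.adjusted[pat]
            rows.append(
                {
                    "pattern": pat,
                    "median_p": float(p.median()),
                    "median_adjusted_p": float(a.median()),
                    "q25_adjusted_p": float(a.quantile(0.25)),
                    "q75_adjusted_p": float(a.quantile(0.75)),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class BarcodeData:
    """Ranked statistic with member marks, for barcode enrichment plots."""

    table: pd.DataFrame  # columns: rank, gene_id, statistic, member
    p_value: float
    direction: str


def length_matched_sample(
    targeted: list[UTRRecord],
    nontargeted: list[UTRRecord],
    n: int,
    n_bins: int = 10,
    seed=None,
    max_retries: int = 100,
):
    """Draw equal-size samples with matched 3' UTR length distributions.

    Targeted records are drawn uniformly without replacement; nontargeted
    records are drawn to reproduce the targeted sample's histogram over
    length-quantile bins computed from the pooled length distribution.  If a
    bin cannot be filled from the nontargeted class the targeted sample is
    redrawn, up to `max_retries` times.
    """
    if not targeted or not nontargeted:
        raise ValueError("both classes must be non-empty")
    if n > min(len(targeted), len(nontargeted)):
        raise ValueError("n exceeds the smaller class size")
    rng = np.random.default_rng(seed)
    t_len = np.array([u.length for u in targeted])
    n_len = np.array([u.length for u in nontargeted])
    pooled = np.concatenate([t_len, n_len])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    t_bin = np.searchsorted(edges, t_len, side="right") - 1
    n_bin = np.searchsorted(edges, n_len, side="right") - 1

    for _ in range(max_retries):
        t_pick = rng.choice(len(targeted), size=n, replace=False)
        need = np.bincount(t_bin[t_pick], minlength=n_bins)
        picks: list[np.ndarray] = []
        ok = True
        for b in range(n_bins):
            if need[b] == 0:
                continue
            avail = np.flatnonzero(n_bin == b)
            if len(avail) < need[b]:
                ok = False
                break
            picks.append(rng.choice(avail, size=need[b], replace=False))
        if ok:
            n_pick = np.concatenate(picks) if picks else np.array([], dtype=int)
            return (
                [targeted[i] for i in t_pick],
                [nontargeted[i] for i in n_pick],
            )
    raise ValueError(
        f"could not fill length bins from the nontargeted class in "
        f"{max_retries} attempts"
    )


def hommel_adjust(p) -> np.ndarray:
    """Hommel (1988) step-up adjusted p-values.

    Implements the simes-based algorithm as used for p-value adjustment:
    adjusted values are >= raw, <= 1, and bounded above by the Bonferroni
    adjustment.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 1:
        return p.copy()
    o = np.argsort(p, kind="stable")
    ps = p[o]
    q = np.full(n, min(float(np.min(n * ps / np.arange(1, n + 1))), 1.0))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)  # indices 0 .. n-m
        i2 = np.arange(n - m + 1, n)  # indices n-m+1 .. n-1
        q1 = np.min(m * ps[i2] / np.arange(2, m + 1))
        q[i1] = np.minimum(m * ps[i1], q1)
        q[i2] = q[n - m]
        pa = np.maximum(pa, q)
    adjusted = np.maximum(pa, ps)
    out = np.empty(n)
    out[o] = np.minimum(adjusted, 1.0)
    return out


def presence_enrichment_trials(
    targeted: list[UTRRecord],
    nontargeted: list[UTRRecord],
    patterns: list[MotifPattern],
    n_trials: int = 1000,
    n: int | None = None,
    n_bins: int = 10,
    seed=None,
) -> TrialSet:
    """Length-matched resampling presence-enrichment test.

    Per trial and pattern, a 2x2 presence/absence x targeted/nontargeted
    table is tested with a one-sided Fisher exact test (enrichment among
    targeted), and p-values are Hommel-adjusted across the pattern family
    within the trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not patterns:
        raise ValueError("patterns must be non-empty")
    rng = np.random.default_rng(seed)
    n = n or min(len(targeted), len(nontargeted))

    # presence is a property of the record, not the trial: scan once
    t_presence = np.array(
        [[scan(u, pat) >= 1 for pat in patterns] for u in targeted], dtype=bool
    )
    n_presence = np.array(
        [[scan(u, pat) >= 1 for pat in patterns] for u in nontargeted], dtype=bool
    )
    t_index = {id(u): i for i, u in enumerate(targeted)}
    n_index = {id(u): i for i, u in enumerate(nontargeted)}

    raw = np.empty((n_trials, len(patterns)))
    for t in range(n_trials):
        sub_t, sub_n = length_matched_sample(
            targeted, nontargeted, n=n, n_bins=n_bins, seed=rng
        )
        ti = [t_index[id(u)] for u in sub_t]
        ni = [n_index[id(u)] for u in sub_n]
        for j in range(len(patterns)):
            a = int(t_presence[ti, j].sum())
            c = int(n_presence[ni, j].sum())
            table = [[a, c], [len(ti) - a, len(ni) - c]]
            raw[t, j] = stats.fisher_exact(table, alternative="greater")[1]
    adjusted = np.vstack([hommel_adjust(row) for row in raw])
    names = [p.name for p in patterns]
    return TrialSet(
        n_trials=n_trials,
        patterns=names,
        pvalues=pd.DataFrame(raw, columns=names),
        adjusted=pd.DataFrame(adjusted, columns=names),
    )


def density_compare(
    dens_t, dens_n, pattern: str | None = None
) -> dict[str, float]:
    """Two-sided rank-sum comparison of per-gene motif densities.

    Returns group means, SEMs and the Mann-Whitney/Wilcoxon rank-sum p-value.
    """
    a = np.asarray(dens_t, dtype=float)
    b = np.asarray(dens_n, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for a SEM")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        p = 1.0  # all ties carry no rank information
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
    return {
        "pattern": pattern,
        "mean_t": float(a.mean()),
        "mean_n": float(b.mean()),
        "sem_t": float(a.std(ddof=1) / np.sqrt(len(a))),
        "sem_n": float(b.std(ddof=1) / np.sqrt(len(b))),
        "wilcoxon_p": p,
    }


def loess_curve(
    x,
    y,
    span: float = 0.75,
    grid=None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """LOESS: local linear regression with tricube weights, plus a 95% band.

    At each grid point the bandwidth covers the `span` fraction of nearest
    points; the pointwise band is fit +/- 1.96 standard errors, with the
    variance from the locally weighted residual scale and the smoother's hat
    vector.  Returns columns grid, fit, lo, hi.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 points")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    k = max(2, int(np.ceil(span * len(x))))
    fit = np.empty(len(grid))
    se = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).tiny
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        W = w[use]
        X = np.column_stack([np.ones(use.sum()), x[use] - g])
        XtW = X.T * W
        beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ y[use], rcond=None)
        fit[i] = beta[0]
        # hat vector for the fitted value at g
        li = np.linalg.pinv(XtW @ X)[0] @ XtW
        resid = y[use] - X @ beta
        dof = max(use.sum() - 2, 1)
        sigma2 = float((W * resid**2).sum() / W.sum()) * use.sum() / dof
        se[i] = np.sqrt(sigma2 * float((li**2).sum()))
    return pd.DataFrame(
        {"grid": grid, "fit": fit, "lo": fit - 1.96 * se, "hi": fit + 1.96 * se}
    )


def competitive_set_test(
    stat: pd.Series,
    gene_set: GeneSet,
    direction: str = "two-sided",
    vif: float = 1.0,
) -> BarcodeData:
    """Rank-based competitive gene-set test with barcode output.

    Tests whether set members' statistics are shifted relative to all other
    scored genes via a Mann-Whitney rank-sum test; `direction` is "down"
    (members lower), "up", or "two-sided".  `vif` > 1 inflates the variance
    of the normal approximation to acknowledge inter-gene correlation, in the
    spirit of variance-inflated competitive tests.
    """
    members = stat.index.isin(gene_set.members)
    n_m = int(members.sum())
    if n_m < 2:
        raise ValueError("need >= 2 set members among scored genes")
    if n_m == len(stat):
        raise ValueError("gene set covers all scored genes; no complement")
    alt = {"down": "less", "up": "greater", "two-sided": "two-sided"}[direction]
    a = stat.to_numpy()[members]
    b = stat.to_numpy()[~members]
    if vif == 1.0:
        p = float(stats.mannwhitneyu(a, b, alternative=alt)[1])
    else:
        n1, n2 = len(a), len(b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        sigma = np.sqrt(vif * n1 * n2 * (n1 + n2 + 1) / 12)
        z = (u - mu) / sigma
        if alt == "less":
            p = float(stats.norm.cdf(z))
        elif alt == "greater":
            p = float(stats.norm.sf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
    order = np.argsort(stat.to_numpy(), kind="stable")
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(stat) + 1),
            "gene_id": stat.index.to_numpy()[order],
            "statistic": stat.to_numpy()[order],
            "member": members[order],
        }
    )
    return BarcodeData(table=table, p_value=p, direction=direction)
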