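"""DE core: binning, filtering, anchor factors, dispersion, exact test, calls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matdecay.de import (
    CountMatrix,
    anchor_factors,
    bh_fdr,
    bin_isoforms,
    call_de,
    estimate_dispersion,
    filter_low,
    library_size_factors,
    nb_exact_test,
)


def make_design(samples, genotypes):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "genotype": genotypes,
            "replicate": list(range(1, len(samples) + 1)),
            "timepoint": "t0",
        }
    )


class TestBinIsoforms:
    def test_single_isoform_identity(self):
        counts = pd.DataFrame(
            {"s1": [10, 5], "s2": [3, 8]}, index=["gA.1", "gB.1"]
        )
        cm = CountMatrix(counts, level="isoform", isoform_to_gene={"gA.1": "gA", "gB.1": "gB"})
        out = bin_isoforms(cm)
        assert out.counts.loc["gA", "s1"] == 10
        assert out.level == "gene"

    def test_additivity(self):
        counts = pd.DataFrame({"s1": [10, 5, 0]}, index=["g.1", "g.2", "g.3"])
        cm = CountMatrix(counts, level="isoform", isoform_to_gene={f"g.{i}": "g" for i in (1, 2, 3)})
        assert bin_isoforms(cm).counts.loc["g", "s1"] == 15

    def test_reads_conserved_on_random_matrix(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(500, 4)),
            index=[f"iso{i}" for i in range(500)],
            columns=list("abcd"),
        )
        mapping = {f"iso{i}": f"gene{i % 80}" for i in range(500)}
        cm = CountMatrix(counts, level="isoform", isoform_to_gene=mapping)
        out = bin_isoforms(cm)
        assert (out.counts.sum() == counts.sum()).all()

    def test_orphan_isoforms_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["i1", "i2"])
        cm = CountMatrix(counts, level="isoform", isoform_to_gene={"i1": "g1"})
        with pytest.raises(ValueError, match="i2"):
            bin_isoforms(cm)


class TestFilterLow:
    def make(self, rows, libs_scale=1):
        """Matrix with 6 samples in 2 groups of 3; equal library sizes by a filler gene."""
        samples = [f"s{i}" for i in range(6)]
        counts = pd.DataFrame(rows, columns=samples).astype(int)
        counts.index = [f"g{i}" for i in range(len(rows))]
        # filler keeps all library sizes at 1e6 so the CPM cutoff is exactly min_count
        filler = 1_000_000 * libs_scale - counts.sum(axis=0)
        counts.loc["filler"] = filler.to_numpy()
        design = make_design(samples, ["x"] * 3 + ["y"] * 3)
        return CountMatrix(counts), design

    def test_all_zero_gene_removed(self):
        cm, design = self.make([[0] * 6, [100] * 6])
        kept = filter_low(cm, design).gene_ids
        assert "g0" not in kept and "g1" in kept

    def test_total_boundary(self):
        # total 29 in one group above per-sample threshold -> removed;
        # total 30 (10,10,10 in one group) -> kept
        cm, design = self.make([[0, 0, 0, 10, 10, 9], [0, 0, 0, 10, 10, 10]])
        kept = filter_low(cm, design, min_count=10, min_total=30).gene_ids
        assert "g0" not in kept and "g1" in kept

    def test_matches_brute_force_rules(self):
        rng = np.random.default_rng(1)
        n = 400
        base = rng.integers(0, 200, size=(n, 6))
        base[rng.random(n) < 0.05] = rng.integers(0, 3, size=(int((rng.random(n) < 0).sum()) or 1, 6))
        counts = pd.DataFrame(base, index=[f"g{i}" for i in range(n)], columns=[f"s{i}" for i in range(6)])
        cm = CountMatrix(counts)
        design = make_design(list(counts.columns), ["x"] * 3 + ["y"] * 3)
        kept = set(filter_low(cm, design).gene_ids)
        # independent re-statement of the two rules
        lib = counts.sum(axis=0)
        cutoff = 30 / np.median(lib) * 1e6
        cpm = counts / lib * 1e6
        expected = {
            g
            for g in counts.index
            if (cpm.loc[g] >= cutoff).sum() >= 3 and counts.loc[g].sum() >= 30
        }
        assert kept == expected

    def test_empty_result_warns(self):
        cm, design = self.make([[1] * 6])
        cm = CountMatrix(cm.counts.drop(index="filler"))
        with pytest.warns(UserWarning, match="removed every gene"):
            filter_low(cm, design, min_count=10**6, min_total=10**9)


class TestAnchorFactors:
    def equal_matrix(self, scale=1.0):
        rng = np.random.default_rng(0)
        base = np.sort(rng.integers(100, 10_000, size=200))[::-1]
        ref = np.tile(base[:, None], (1, 3))
        test = (base[:, None] * scale * np.ones((1, 3))).astype(int)
        counts = pd.DataFrame(
            np.hstack([ref, test]),
            index=[f"g{i}" for i in range(200)],
            columns=["r1", "r2", "r3", "t1", "t2", "t3"],
        )
        return CountMatrix(counts)

    def test_identity_factor(self):
        nf = anchor_factors(self.equal_matrix(1.0), ["r1", "r2", "r3"], ["t1", "t2", "t3"])
        assert nf.factors[["t1", "t2", "t3"]].to_numpy() == pytest.approx(1.0, abs=1e-9)
        assert nf.method == "anchor"
        assert len(nf.anchor_gene_ids) == 20

    def test_uniform_doubling_is_depth_not_composition(self):
        # doubling every gene doubles depth; depth-scaled ratios stay 1
        nf = anchor_factors(self.equal_matrix(2.0), ["r1", "r2", "r3"], ["t1", "t2", "t3"])
        assert nf.factors[["t1", "t2", "t3"]].to_numpy() == pytest.approx(1.0, abs=1e-6)

    def test_anchor_subset_doubled_yields_factor_two(self):
        cm = self.equal_matrix(1.0)
        counts = cm.counts.copy()
        # double the test counts of the 30 most abundant genes only:
        # depth-scaled anchor ratios then measure the composition shift
        top = counts["r1"].nlargest(30).index
        counts.loc[top, ["t1", "t2", "t3"]] *= 2
        nf = anchor_factors(CountMatrix(counts), ["r1", "r2", "r3"], ["t1", "t2", "t3"])
        total_ref = counts[["r1", "r2", "r3"]].sum().mean()
        total_test = counts["t1"].sum()
        expected = 2.0 * total_ref / total_test
        assert nf.factors["t1"] == pytest.approx(expected, rel=1e-6)

    def test_recovers_oversampling_correction_on_default_sim(self, default_sim):
        """Chimera factors ~ 1/(1-f+f/delta) = 1.54, within 5%."""
        params, cm, truth = default_sim
        wt = [f"wt_{i}" for i in (1, 2, 3)]
        ch = [f"upf1nos_{i}" for i in (1, 2, 3)]
        sub = CountMatrix(cm.counts[wt + ch])
        nf = anchor_factors(sub, wt, ch, n_anchor=20, pool_size=60)
        expected = 1.0 / (
            1 - params.target_fraction + params.target_fraction / params.depletion_factor
        )
        for f in nf.factors[ch]:
            assert f == pytest.approx(expected, rel=0.05)

    def test_too_few_survivors_raises(self):
        cm = self.equal_matrix(1.0)
        counts = cm.counts.copy()
        # deplete most of the top pool in the test samples so they drop in rank
        top = counts["r1"].nlargest(25).index
        counts.loc[top, ["t1", "t2", "t3"]] //= 50
        with pytest.raises(ValueError, match="pool_size"):
            anchor_factors(CountMatrix(counts), ["r1", "r2", "r3"], ["t1", "t2", "t3"])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            anchor_factors(self.equal_matrix(), ["r1"], ["r1", "t1"])


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        from matdecay.simulate import SimParams, simulate_counts

        params = SimParams(n_genes=2000, depth=500_000, dispersion=0.0, seed=4,
                           target_fraction=0.0, housekeeping_top_n=10)
        cm, _ = simulate_counts(params)
        phi = estimate_dispersion(cm, params.design(), library_size_factors(cm))
        assert phi.attrs["common"] <= 0.01

    def test_recovers_planted_dispersion(self):
        from matdecay.simulate import SimParams, simulate_counts

        params = SimParams(dispersion=0.1, seed=2, target_fraction=0.0,
                           housekeeping_top_n=10)
        cm, _ = simulate_counts(params)
        phi = estimate_dispersion(cm, params.design(), library_size_factors(cm))
        assert 0.08 <= phi.attrs["common"] <= 0.12

    def test_constant_counts_floor_at_zero(self):
        counts = pd.DataFrame(
            {"s1": [100, 50], "s2": [100, 50], "s3": [100, 50]},
            index=["g1", "g2"],
        )
        cm = CountMatrix(counts)
        design = make_design(["s1", "s2", "s3"], ["x", "x", "x"])
        phi = estimate_dispersion(cm, design, library_size_factors(cm), prior_df=0.0)
        assert (phi >= 0).all()
        assert phi.attrs["common"] == 0.0

    def test_single_replicate_design_warns_and_uses_prior(self):
        counts = pd.DataFrame({"s1": [10], "s2": [20]}, index=["g1"])
        cm = CountMatrix(counts)
        design = make_design(["s1", "s2"], ["x", "y"])
        with pytest.warns(UserWarning, match="prior"):
            phi = estimate_dispersion(cm, design, library_size_factors(cm), default_phi=0.2)
        assert (phi == 0.2).all()


def oracle_exact_p(counts_a, counts_b, factors_a, factors_b, phi):
    """Independent enumeration of the conditional NB two-sided p-value.

    Written with explicit lgamma arithmetic (no scipy distributions) so it
    shares no code with the implementation under test.
    """
    fa, fb = np.asarray(factors_a, float), np.asarray(factors_b, float)
    s_a = round(float(np.sum(counts_a)))
    s_b = round(float(np.sum(counts_b)))
    total = s_a + s_b
    mu = total / (fa.sum() + fb.sum())

    def log_nb(k, size, mean):
        if phi <= 0:
            return k * math.log(mean) - mean - math.lgamma(k + 1)
        logp = math.log(size / (size + mean))
        log1mp = math.log(mean / (size + mean))
        return (
            math.lgamma(k + size)
            - math.lgamma(size)
            - math.lgamma(k + 1)
            + size * logp
            + k * log1mp
        )

    size_a = fa.sum() ** 2 / (phi * (fa**2).sum()) if phi > 0 else 0
    size_b = fb.sum() ** 2 / (phi * (fb**2).sum()) if phi > 0 else 0
    joint = np.array(
        [
            log_nb(k, size_a, mu * fa.sum())
            + log_nb(total - k, size_b, mu * fb.sum())
            for k in range(total + 1)
        ]
    )
    probs = np.exp(joint - joint.max())
    probs /= probs.sum()
    return min(1.0, float(probs[probs <= probs[s_a] * (1 + 1e-10)].sum()))


class TestNbExactTest:
    def test_symmetric_identical_sums_give_p_one(self):
        assert nb_exact_test([10, 10], [10, 10], phi=0.1) == pytest.approx(1.0)

    def test_poisson_limit_reduces_to_binomial(self):
        # groups of one, phi=0: conditional distribution is exactly binomial
        for a, b, fa, fb in [(3, 12, 1.0, 1.0), (7, 2, 1.0, 2.0), (0, 9, 2.0, 1.0)]:
            p = nb_exact_test([a], [b], [fa], [fb], phi=0.0)
            # scale-invariant null proportion: relative effective depths
            expected = stats.binomtest(a, a + b, p=fa / (fa + fb)).pvalue
            assert p == pytest.approx(expected, abs=1e-10)

    def test_small_case_matches_enumeration_oracle(self):
        p = nb_exact_test([5, 7], [21, 19], [1, 1], [1, 1], phi=0.05)
        p_oracle = oracle_exact_p([5, 7], [21, 19], [1, 1], [1, 1], 0.05)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_random_cases_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n_a, n_b = rng.integers(1, 4, size=2)
            a = rng.integers(0, 30, size=n_a)
            b = rng.integers(0, 30, size=n_b)
            if a.sum() + b.sum() == 0:
                continue
            phi = float(rng.choice([0.0, 0.01, 0.05, 0.2]))
            fa = rng.uniform(0.5, 2.0, size=n_a)
            fb = rng.uniform(0.5, 2.0, size=n_b)
            p = nb_exact_test(a, b, fa, fb, phi=phi)
            p_oracle = oracle_exact_p(a, b, fa, fb, phi)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_label_swap_symmetry(self):
        p1 = nb_exact_test([5, 7], [21, 19], phi=0.05)
        p2 = nb_exact_test([21, 19], [5, 7], phi=0.05)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [1], phi=-0.1)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDe:
    def stats_frame(self, log2fc, p):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(log2fc))],
                "log2fc": log2fc,
                "avg_abundance": 5.0,
                "p_value": p,
            }
        ).set_index("gene_id", drop=False)

    def test_inclusive_lfc_boundary(self):
        df = self.stats_frame([-1.0], [1e-6])
        out = call_de(df, lfc_threshold=1.0)
        assert out["status"].iloc[0] == "depleted"

    def test_strict_fdr_boundary(self):
        # single p-value: fdr == p; 0.05 exactly is not significant
        df = self.stats_frame([-3.0], [0.05])
        out = call_de(df, lfc_threshold=1.0, fdr_threshold=0.05)
        assert out["status"].iloc[0] == "unchanged"

    def test_sign_mirror(self):
        rng = np.random.default_rng(5)
        lfc = rng.normal(0, 2, 50)
        p = rng.random(50) * 0.1
        up = call_de(self.stats_frame(lfc, p), lfc_threshold=1.0)
        down = call_de(self.stats_frame(-lfc, p), lfc_threshold=1.0)
        swap = {"depleted": "enriched", "enriched": "depleted", "unchanged": "unchanged"}
        assert [swap[s] for s in up["status"]] == list(down["status"])

    def test_excluded_genes_flagged_and_neutralized(self):
        df = self.stats_frame([-3.0, -3.0], [1e-9, 1e-9])
        out = call_de(df, lfc_threshold=1.0, exclude={"g0", "not_present"})
        assert bool(out.loc["g0", "excluded"]) is True
        assert out.loc["g0", "status"] == "unchanged"
        assert out.loc["g1", "status"] == "depleted"

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_de(self.stats_frame([1.0], [0.01]), lfc_threshold=0.0)
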