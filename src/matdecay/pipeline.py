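"""End-to-end orchestration: simulate and/or analyze from a single config.

A run executes simulate (optional) -> differential expression per contrast ->
motif scanning -> resampling enrichment -> pool partition and overlap
analysis, writing TSV artifacts, a JSON summary and a manifest (config hash,
seed, versions) sufficient to re-execute the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import CountMatrix, de_contrast
from .enrichment import GeneSet, density_compare, presence_enrichment_trials
from .motifs import MotifPattern, density_table, read_utrs_fasta
from .pools import (
    assign_pools,
    decay_class_crosstab,
    overlap_fraction,
    reexpression_enrichment,
    restrict_to_common,
)
from .simulate import SimParams, StageParams, write_dataset

log = logging.getLogger(__name__)

#: Default degenerate pattern library (config-overridable, never biology
#: hard-coded): the modified NRE with +4 in {U, A}, its four +4 variants and
#: the canonical Pum element.
DEFAULT_PATTERNS = {
    "NRE_modified": "UAUAUAUGUW",
    "+4A": "UAUAUAUGUA",
    "+4U": "UAUAUAUGUU",
    "+4G": "UAUAUAUGUG",
    "+4C": "UAUAUAUGUC",
    "PRE": "UGUANAUA",
}


@dataclass
class RunConfig:
    """Everything a run needs; loadable from one YAML file."""

    mode: str = "both"  # simulate | analyze | both
    seed: int = 1
    outdir: str = "matdecay_run"
    paths: dict[str, str] = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    patterns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PATTERNS))
    genotypes: dict[str, str] = field(
        default_factory=lambda: {
            "chimera": "upf1nos",
            "reference": "wt",
            "nosnull": "nosnull",
            "upf1": "upf1",
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "patterns" not in raw:
            cfg.patterns = dict(DEFAULT_PATTERNS)
        return cfg

    def threshold(self, name: str, default):
        return self.thresholds.get(name, default)

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze", "both"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == "analyze":
            required = ("counts", "design", "utrs")
            missing = [
                k
                for k in required
                if k not in self.paths or not Path(self.paths[k]).exists()
            ]
            if missing:
                raise ValueError(
                    f"analyze mode requires existing input paths for: {missing}"
                )

    def sim_params(self) -> SimParams:
        return SimParams(seed=self.seed, **self.sim)

    def pattern_library(self) -> list[MotifPattern]:
        return [MotifPattern(name=k, iupac=v) for k, v in self.patterns.items()]

    def canonical(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "mode": config.mode}

    # ---- stage: simulate -------------------------------------------------
    truth = None
    if config.mode in ("simulate", "both"):
        params = config.sim_params()
        paths = write_dataset(outdir / "data", params, StageParams())
        config.paths = {**paths, **config.paths}
        truth = pd.read_csv(paths["truth"], sep="\t").set_index("gene_id", drop=False)
        truth.index.name = None
    if config.mode == "simulate":
        _write_manifest(config, outdir, summary)
        return summary

    # ---- stage: differential expression ---------------------------------
    cm = CountMatrix.from_tsv(config.paths["counts"])
    design = pd.read_csv(config.paths["design"], sep="\t")
    geno = config.genotypes
    fdr = config.threshold("fdr", 0.05)
    kw = dict(
        min_count=config.threshold("min_count", 30),
        min_total=config.threshold("min_total", 30),
        fdr_threshold=fdr,
    )
    try:
        de_upf1 = de_contrast(
            cm,
            design,
            geno["upf1"],
            geno["reference"],
            normalization="library_size",
            lfc_threshold=config.threshold("lfc_chimera", 1.0),
            **kw,
        )
        upf1_altered = set(de_upf1.loc[de_upf1["status"] != "unchanged", "gene_id"])
        de_chimera = de_contrast(
            cm,
            design,
            geno["chimera"],
            geno["reference"],
            normalization="anchor",
            lfc_threshold=config.threshold("lfc_chimera", 1.0),
            n_anchor=config.threshold("n_anchor", 20),
            pool_size=config.threshold("pool_size", 60),
            exclude=upf1_altered,
            **kw,
        )
        # anchor normalization for the nos-null contrast too: ~19% of the
        # transcriptome stabilized 1.6-fold still shifts composition enough
        # to bias library-size fold changes by ~ -0.15 log2 units
        de_nosnull = de_contrast(
            cm,
            design,
            geno["nosnull"],
            geno["reference"],
            normalization="anchor",
            lfc_threshold=config.threshold("lfc_nosnull", 0.5),
            n_anchor=config.threshold("n_anchor", 20),
            pool_size=config.threshold("pool_size", 60),
            **kw,
        )
    except Exception as err:  # noqa: BLE001 - stage-tagged abort
        raise RuntimeError(f"stage 'de' failed: {err}") from err
    for name, de in (("upf1", de_upf1), ("chimera", de_chimera), ("nosnull", de_nosnull)):
        de.drop(columns=["gene_id"]).to_csv(
            outdir / f"de_{name}.tsv", sep="\t", index_label="gene_id"
        )
        summary[f"de_{name}"] = {
            "tested": int(len(de)),
            "depleted": int((de["status"] == "depleted").sum()),
            "enriched": int((de["status"] == "enriched").sum()),
        }

    targets = set(de_chimera.loc[de_chimera["status"] == "depleted", "gene_id"])

    # ---- stage: motif scan ----------------------------------------------
    try:
        utrs = read_utrs_fasta(config.paths["utrs"])
        patterns = config.pattern_library()
        stats_table = density_table(utrs, patterns)
        stats_table.to_csv(outdir / "motif_stats.tsv", sep="\t", index=False)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage 'motifs' failed: {err}") from err

    # ---- stage: enrichment ----------------------------------------------
    try:
        tested = set(de_chimera.loc[~de_chimera["excluded"], "gene_id"])
        targeted_utrs = [u for u in utrs if u.gene_id in targets]
        nontargeted_utrs = [
            u for u in utrs if u.gene_id in tested and u.gene_id not in targets
        ]
        trial_n = min(
            config.threshold("trial_n", 300),
            len(targeted_utrs),
            len(nontargeted_utrs),
        )
        trials = presence_enrichment_trials(
            targeted_utrs,
            nontargeted_utrs,
            patterns,
            n_trials=config.threshold("n_trials", 1000),
            n=trial_n,
            n_bins=config.threshold("n_bins", 10),
            seed=np.random.SeedSequence([config.seed, 9041]),
        )
        trials.summary().to_csv(outdir / "enrichment_trials.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            row["pattern"]: row["median_adjusted_p"]
            for row in trials.summary().to_dict("records")
        }
        dens_rows = []
        for pat in patterns:
            sub = stats_table[stats_table["pattern"] == pat.name]
            d_t = sub.loc[sub["gene_id"].isin(targets), "density"]
            d_n = sub.loc[
                sub["gene_id"].isin(tested) & ~sub["gene_id"].isin(targets), "density"
            ]
            if len(d_t) >= 2 and len(d_n) >= 2:
                dens_rows.append(density_compare(d_t, d_n, pattern=pat.name))
        pd.DataFrame(dens_rows).to_csv(
            outdir / "density_compare.tsv", sep="\t", index=False
        )
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage 'enrich' failed: {err}") from err

    # ---- stage: pools ----------------------------------------------------
    try:
        common = restrict_to_common(de_chimera, de_nosnull)
        pools = assign_pools(de_chimera, de_nosnull, common)
        pools.drop(columns=["gene_id"]).to_csv(
            outdir / "pools.tsv", sep="\t", index_label="gene_id"
        )
        stabilized = set(pools.loc[pools["nos_stabilized"], "gene_id"])
        depleted = set(pools.loc[pools["upf1nos_target"], "gene_id"])
        if stabilized:
            ov = overlap_fraction(depleted, stabilized)
            summary["stabilized_also_depleted_pct"] = ov["percent"]
        pool_sizes = pools["pool"].value_counts().to_dict()
        summary["pool_sizes"] = {p: int(pool_sizes.get(p, 0)) for p in "ABC"} | {
            "nos_only": int(pool_sizes.get("nos_only", 0))
        }
        if "gene_sets" in config.paths and Path(config.paths["gene_sets"]).exists():
            sets_df = pd.read_csv(config.paths["gene_sets"], sep="\t")
            zyg = sets_df.loc[
                sets_df["set_name"] == "zygotically_reexpressed", "gene_id"
            ]
            if len(zyg):
                frac, pairs = reexpression_enrichment(
                    pools, GeneSet("zygotically_reexpressed", zyg)
                )
                frac.to_csv(outdir / "reexpression.tsv", sep="\t", index=False)
                pairs.to_csv(outdir / "reexpression_tests.tsv", sep="\t", index=False)
        if truth is not None:
            decay = truth.set_index("gene_id")["decay_class"]
            xt = decay_class_crosstab(pools, decay)
            xt["crosstab"].to_csv(outdir / "decay_crosstab.tsv", sep="\t")
            summary["percent_targets_degraded"] = xt["percent_targets_degraded"]
            planted = truth.loc[pools["gene_id"], "pool"]
            recovery = 100.0 * float((planted.to_numpy() == pools["pool"].to_numpy()).mean())
            summary["pool_label_recovery_pct"] = recovery
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage 'pools' failed: {err}") from err

    _write_manifest(config, outdir, summary)
    return summary


def _write_manifest(config: RunConfig, outdir: Path, summary: dict) -> None:
    canonical = config.canonical()
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "matdecay_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "config.yaml").write_text(canonical)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
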