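"""Shared fixtures: the default synthetic study, computed once per session."""

import numpy as np
import pandas as pd
import pytest

from matdecay.de import de_contrast
from matdecay.simulate import SimParams, simulate_counts, simulate_utrs


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions, seed 1: counts plus ground truth."""
    params = SimParams(seed=1)
    cm, truth = simulate_counts(params)
    return params, cm, truth


@pytest.fixture(scope="session")
def chimera_anchor_de(default_sim):
    """Anchor-normalized chimera-vs-wt DE on the default simulation."""
    params, cm, truth = default_sim
    return de_contrast(
        cm,
        params.design(),
        params.chimera_genotype,
        params.reference_genotype,
        normalization="anchor",
        lfc_threshold=1.0,
        pool_size=60,
    )


@pytest.fixture(scope="session")
def chimera_libsize_de(default_sim):
    """Library-size-normalized chimera-vs-wt DE on the default simulation."""
    params, cm, truth = default_sim
    return de_contrast(
        cm,
        params.design(),
        params.chimera_genotype,
        params.reference_genotype,
        normalization="library_size",
        lfc_threshold=1.0,
    )


@pytest.fixture(scope="session")
def default_utrs(default_sim):
    """UTRs for the default simulation, with planting recorded in truth."""
    params, cm, truth = default_sim
    truth = truth.copy()
    utrs = simulate_utrs(params, truth)
    return utrs, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full mode=both pipeline run at seed 1 with default config."""
    from matdecay.pipeline import RunConfig, run

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = RunConfig(mode="both", seed=1, outdir=str(outdir))
    summary = run(cfg)
    return cfg, summary, outdir
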