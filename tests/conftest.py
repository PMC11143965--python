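import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cocomix.containers import SecretomePanel
from cocomix.mixnull import build_virtual_cohort
from cocomix.secretome import build_virtual_secretome
from cocomix.synthdata import SimulationConfig, simulate_coculture_experiment

# large FASTQ scratch lives inside the repository tree (not /tmp, which may be
# memory-backed); removed at session end.
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "test_fastq"


@pytest.fixture(scope="session")
def fastq_scratch():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    yield SCRATCH
    shutil.rmtree(SCRATCH, ignore_errors=True)


@pytest.fixture(scope="session")
def small_experiment():
    """A small matched-pair cohort with known interaction genes."""
    cfg = SimulationConfig(
        n_genes=1200,
        n_sc_cultures=8,
        n_fb_cultures=8,
        pairing="matched",
        interaction_fraction=0.05,
        interaction_log2fc=1.5,
        library_size_range=(400_000, 600_000),
        seed=42,
    )
    matrix, compositions, truth = simulate_coculture_experiment(cfg)
    return cfg, matrix, compositions, truth


@pytest.fixture(scope="session")
def small_cohort(small_experiment):
    """Real + virtual columns ready for DE."""
    _, matrix, compositions, _ = small_experiment
    singles = matrix.subset_samples(
        matrix.samples_with_role("sc_single") + matrix.samples_with_role("fb_single")
    )
    real = matrix.subset_samples(matrix.samples_with_role("real"))
    virtual = build_virtual_cohort(
        singles, compositions, total=int(real.counts.sum(axis=0).mean()), seed=42
    )
    return real.concat(virtual)


def make_matched_secretome(frac, lfc, seed, n_pairs=16, cv=0.2):
    """Panel with real and virtual columns side by side, plus truth."""
    from cocomix.synthdata import simulate_secretome

    cfg = SimulationConfig(
        n_analytes=20, n_sc_cultures=n_pairs, n_fb_cultures=n_pairs,
        pairing="matched", interaction_fraction=frac, interaction_log2fc=lfc,
        secretome_cv=cv, seed=seed,
    )
    panel, truth = simulate_secretome(cfg)
    sids = panel.samples_with_role("sc_single") + panel.samples_with_role("fb_single")
    singles = SecretomePanel(panel.values[sids], panel.samples.loc[sids])
    virt = build_virtual_secretome(singles, truth.compositions)
    rids = panel.samples_with_role("real")
    full = SecretomePanel(
        panel.values[rids].join(virt.values),
        pd.concat([panel.samples.loc[rids], virt.samples]),
    )
    return full, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
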