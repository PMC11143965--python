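"""Generator contracts: determinism, shapes, moments, injected effects."""

import numpy as np
import pandas as pd
import pytest

from cocomix.errors import ConfigError, GenerationError
from cocomix.mixnull import count_reads_per_gene
from cocomix.synthdata import (
    SimulationConfig,
    simulate_coculture_experiment,
    simulate_read_pool,
    simulate_secretome,
    simulate_single_profiles,
    simulate_spheroid_image,
)


class TestSingleProfiles:
    def test_shape_and_dtype(self):
        cfg = SimulationConfig(n_genes=100, library_size_range=(50_000, 60_000), seed=1)
        m = simulate_single_profiles(cfg)
        assert m.counts.shape == (100, 8)
        assert (m.counts.to_numpy() >= 0).all()
        assert np.issubdtype(m.counts.to_numpy().dtype, np.integer)
        assert m.samples_with_role("sc_single") == [f"SC{i}" for i in range(1, 5)]

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_genes=200, seed=7)
        a = simulate_single_profiles(cfg)
        b = simulate_single_profiles(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_library_size_exact(self):
        cfg = SimulationConfig(n_genes=100, library_size_range=(50_000, 50_000), seed=2)
        m = simulate_single_profiles(cfg)
        assert (m.counts.sum(axis=0) == 50_000).all()

    def test_poisson_limit_variance_matches_mean(self):
        # a0 = a1 = 0: multinomial at fixed depth, per-gene variance ~ mean.
        cfg = SimulationConfig(
            n_genes=100, n_sc_cultures=200, n_fb_cultures=1,
            dispersion_a0=0.0, dispersion_a1=0.0,
            library_size_range=(100_000, 100_000), seed=3,
        )
        m = simulate_single_profiles(cfg)
        sc = m.counts[[f"SC{i}" for i in range(1, 201)]].to_numpy(dtype=float)
        mean = sc.mean(axis=1)
        var = sc.var(axis=1, ddof=1)
        # SE of the sample variance of a Poisson at 200 replicates
        se = np.sqrt((2 * mean**2 + mean) / 200)
        z = (var - mean) / np.maximum(se, 1e-9)
        assert np.abs(z).max() < 4.0
        assert np.abs(np.median(z)) < 0.5

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_genes=0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(composition_range=(0.8, 0.2)).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(dispersion_a0=-1.0).validate()


class TestCocultureExperiment:
    def test_design_contract_4x4(self):
        cfg = SimulationConfig(n_genes=300, seed=4)
        matrix, comp, truth = simulate_coculture_experiment(cfg)
        assert len(comp) == 16  # all SC x FB pairings
        assert comp["sc_fraction"].between(0.6, 0.7).all()
        assert len(matrix.samples_with_role("real")) == 16
        assert set(truth.interaction_genes) <= set(matrix.gene_ids)
        assert (truth.log2fc[~truth.log2fc.index.isin(truth.interaction_genes)] == 0).all()

    def test_null_construction_matches_mixture(self):
        # no interaction genes: expected proportions are the p-weighted mixture
        cfg = SimulationConfig(n_genes=300, interaction_fraction=0.0, seed=5)
        _, _, truth = simulate_coculture_experiment(cfg)
        assert truth.interaction_genes == []
        assert (truth.log2fc == 0).all()

    def test_injected_effect_doubles_mixture_expectation(self):
        # one coculture design repeated many times; compare the interaction
        # gene's mean count to the analytic mixture expectation
        reps = 200
        totals = []
        expected = []
        for r in range(reps):
            cfg = SimulationConfig(
                n_genes=50, n_sc_cultures=1, n_fb_cultures=1, pairing="matched",
                interaction_fraction=0.02, interaction_log2fc=1.0,
                signed_effects=False, celltype_diff_fraction=0.0,
                composition_range=(0.65, 0.65),
                library_size_range=(100_000, 100_000), seed=10_000 + r,
            )
            matrix, comp, truth = simulate_coculture_experiment(cfg)
            (gene,) = truth.interaction_genes
            real = matrix.counts.loc[gene, matrix.samples_with_role("real")[0]]
            totals.append(real)
            # mixture expectation from the cell-type profiles: approximate it
            # by the observed singles' pooled proportion at p = 0.65
            sc = matrix.counts[matrix.samples_with_role("sc_single")[0]]
            fb = matrix.counts[matrix.samples_with_role("fb_single")[0]]
            q = 0.65 * sc[gene] / sc.sum() + 0.35 * fb[gene] / fb.sum()
            # doubling one gene renormalises the multinomial by (1 + q)
            expected.append(2.0 * q / (1.0 + q) * 100_000)
        totals = np.asarray(totals, dtype=float)
        expected = np.asarray(expected, dtype=float)
        se = totals.std(ddof=1) / np.sqrt(reps)
        assert abs(totals.mean() - expected.mean()) < 3 * se + 0.02 * expected.mean()

    def test_matched_pairing_counts(self):
        cfg = SimulationConfig(n_genes=100, n_sc_cultures=8, n_fb_cultures=8,
                               pairing="matched", seed=6)
        matrix, comp, _ = simulate_coculture_experiment(cfg)
        assert len(comp) == 8
        assert comp["sc_culture_id"].is_unique and comp["fb_culture_id"].is_unique


class TestReadPool:
    def test_single_gene_profile(self, fastq_scratch):
        prof = pd.Series([0, 10, 0], index=["a", "b", "c"])
        path = fastq_scratch / "single.fastq"
        simulate_read_pool(prof, 500, seed=1, path=path)
        counts = count_reads_per_gene(path)
        assert counts == {"b": 500}

    def test_binomial_bound(self, fastq_scratch):
        prof = pd.Series([25, 75], index=["g1", "g2"])
        path = fastq_scratch / "binom.fastq"
        simulate_read_pool(prof, 10_000, seed=2, path=path)
        counts = count_reads_per_gene(path)
        assert abs(counts["g1"] - 2500) < 4 * np.sqrt(10_000 * 0.25 * 0.75)

    def test_byte_identical_given_seed(self, fastq_scratch):
        prof = pd.Series([1, 2, 3], index=["x", "y", "z"])
        p1, p2 = fastq_scratch / "d1.fastq", fastq_scratch / "d2.fastq"
        simulate_read_pool(prof, 1000, seed=3, path=p1)
        simulate_read_pool(prof, 1000, seed=3, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rejects_nonpositive_reads(self, fastq_scratch):
        with pytest.raises(ConfigError):
            simulate_read_pool(pd.Series([1.0]), 0, 1, fastq_scratch / "no.fastq")


class TestSecretome:
    def test_no_effect_no_noise_equals_mixture(self):
        cfg = SimulationConfig(
            n_analytes=5, interaction_fraction=0.0, secretome_cv=0.0, seed=8
        )
        panel, truth = simulate_secretome(cfg)
        row = truth.compositions.iloc[0]
        p = row.sc_fraction
        mix = (
            p * panel.values[row.sc_culture_id]
            + (1 - p) * panel.values[row.fb_culture_id]
        )
        np.testing.assert_allclose(panel.values[row.coculture_id], mix, rtol=1e-12)

    def test_interaction_analyte_shifts_up(self):
        diffs = []
        for s in range(50):
            cfg = SimulationConfig(
                n_analytes=10, interaction_fraction=0.1, interaction_log2fc=1.0,
                secretome_cv=0.2, seed=900 + s,
            )
            panel, truth = simulate_secretome(cfg)
            a = truth.interaction_genes[0]
            for row in truth.compositions.itertuples(index=False):
                mix = (
                    row.sc_fraction * panel.values.loc[a, row.sc_culture_id]
                    + (1 - row.sc_fraction) * panel.values.loc[a, row.fb_culture_id]
                )
                diffs.append(panel.values.loc[a, row.coculture_id] - mix)
        assert np.mean(diffs) > 0

    def test_deterministic(self):
        cfg = SimulationConfig(seed=9)
        a, _ = simulate_secretome(cfg)
        b, _ = simulate_secretome(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestSpheroidImage:
    def test_no_fragments_truth_di_zero(self):
        _, truth = simulate_spheroid_image(40, [], 1.0, seed=1)
        assert truth["disaggregation_index"] == 0.0
        assert truth["fragment_area_px"] == 0

    def test_constructed_geometry_di(self):
        # main disk r=56 (~9852 px), fragments totalling ~1478 px -> DI ~ 0.15
        _, truth = simulate_spheroid_image(56, [300, 500, 678], 1.0, seed=2)
        assert truth["main_area_px"] == pytest.approx(np.pi * 56**2, rel=0.02)
        assert truth["disaggregation_index"] == pytest.approx(0.150, abs=0.01)

    def test_equal_gains_equal_channel_sums(self):
        _, truth = simulate_spheroid_image(30, [100], 1.0, seed=3)
        assert truth["channel_sums"]["live"] == truth["channel_sums"]["dead"]

    def test_unplaceable_fragments_raise(self):
        with pytest.raises(GenerationError):
            simulate_spheroid_image(
                100, [40_000] * 8, 1.0, seed=4, shape=(256, 256), max_tries=5
            )


class TestSinglesAnchoring:
    def test_expectation_is_mixture_of_observed_singles(self):
        # expected-mode virtual equals the anchored real expectation exactly,
        # so under the null the paired difference has mean zero by construction
        cfg = SimulationConfig(
            n_genes=400, interaction_fraction=0.0, anchor="singles", seed=21,
            library_size_range=(200_000, 200_000),
        )
        matrix, comp, _ = simulate_coculture_experiment(cfg)
        from cocomix.mixnull import mix_counts

        row = comp.iloc[0]
        sc = matrix.counts[row.sc_culture_id].to_numpy()
        fb = matrix.counts[row.fb_culture_id].to_numpy()
        virt = mix_counts(sc, fb, row.sc_fraction, 200_000, mode="expected")
        real = matrix.counts[row.coculture_id].to_numpy()
        # real is one NB draw around the same expectation
        resid = (real - virt) / np.sqrt(virt + 0.03 * virt.astype(float) ** 2 + 1)
        assert np.abs(resid.mean()) < 0.2

    def test_null_yields_no_discoveries(self):
        from cocomix.de import run_de
        from cocomix.mixnull import build_virtual_cohort

        cfg = SimulationConfig(n_genes=1500, interaction_fraction=0.0,
                               anchor="singles", seed=22)
        m, comp, _ = simulate_coculture_experiment(cfg)
        singles = m.subset_samples(
            m.samples_with_role("sc_single") + m.samples_with_role("fb_single")
        )
        real = m.subset_samples(m.samples_with_role("real"))
        virt = build_virtual_cohort(
            singles, comp, total=int(real.counts.sum(axis=0).mean()), seed=22
        )
        table, sig, _ = run_de(real.concat(virt))
        assert len(sig.genes) == 0

    def test_rejects_unknown_anchor(self):
        with pytest.raises(ConfigError):
            SimulationConfig(anchor="nonsense").validate()
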