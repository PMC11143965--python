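"""Filtering, normalization, dispersion estimation and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocomix.containers import ExpressionMatrix
from cocomix.de import (
    adjust_bh,
    estimate_dispersions,
    extract_signature,
    filter_low_counts,
    run_de,
    size_factors_median_of_ratios,
)
from cocomix.de import test_real_vs_virtual as wald_real_vs_virtual
from cocomix.errors import NormalizationError, ValidationError


def _matrix(counts: dict, roles=None, pairs=None) -> ExpressionMatrix:
    df = pd.DataFrame(counts)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene_id")
    samples = pd.DataFrame(index=pd.Index(df.columns, name="sample_id"))
    if roles:
        samples["role"] = roles
    if pairs:
        samples["pair_id"] = pairs
    return ExpressionMatrix(df.astype(np.int64), samples)


class TestFilterLowCounts:
    def test_rule_hand_enumeration(self):
        # 3 of 4 samples below 5 -> more than 2 failures -> removed
        m = _matrix({"a": [0, 9], "b": [1, 9], "c": [2, 9], "d": [100, 9]})
        kept = filter_low_counts(m, min_count=5, max_fail_samples=2)
        assert list(kept.gene_ids) == ["g1"]

    def test_exactly_two_failures_kept(self):
        m = _matrix({"a": [0], "b": [1], "c": [50], "d": [100]})
        kept = filter_low_counts(m)
        assert list(kept.gene_ids) == ["g0"]

    def test_identity_when_all_pass(self):
        m = _matrix({"a": [5, 8], "b": [6, 9], "c": [7, 10]})
        kept = filter_low_counts(m)
        pd.testing.assert_frame_equal(kept.counts, m.counts)

    def test_rejects_negative_counts(self):
        df = pd.DataFrame({"a": [-1]}, index=pd.Index(["g0"], name="gene_id"))
        m = ExpressionMatrix(df, pd.DataFrame(index=pd.Index(["a"], name="sample_id")))
        with pytest.raises(ValidationError):
            filter_low_counts(m)


class TestSizeFactors:
    def test_doubling_forced_ratio(self):
        m = _matrix({"a": [10, 20, 30], "b": [20, 40, 60]})
        s = size_factors_median_of_ratios(m)
        np.testing.assert_allclose(s.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_unit_factors(self):
        m = _matrix({"a": [5, 7, 9], "b": [5, 7, 9], "c": [5, 7, 9]})
        np.testing.assert_allclose(size_factors_median_of_ratios(m).to_numpy(), 1.0)

    def test_against_bruteforce_oracle(self, rng):
        K = rng.integers(1, 500, size=(50, 6)).astype(float)
        m = _matrix({f"s{j}": K[:, j].astype(int) for j in range(6)})
        s = size_factors_median_of_ratios(m).to_numpy()
        # brute force: literal definition, then rescale to geometric mean 1
        geo = np.exp(np.log(K).mean(axis=1))
        raw = np.array([np.median(K[:, j] / geo) for j in range(6)])
        oracle = raw / np.exp(np.log(raw).mean())
        np.testing.assert_allclose(s, oracle, rtol=1e-12)

    def test_no_common_gene_errors(self):
        m = _matrix({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(NormalizationError):
            size_factors_median_of_ratios(m)


class TestDispersions:
    @staticmethod
    def _nb_matrix(alpha, mu, n, rng, roles=True):
        lam = rng.gamma(1 / alpha, alpha * mu, size=(200, n)) if alpha > 0 else mu
        Y = rng.poisson(lam * np.ones((200, n)))
        m = _matrix({f"s{j}": Y[:, j] for j in range(n)})
        m.samples["role"] = ["real"] * (n // 2) + ["virtual"] * (n - n // 2)
        return m

    def test_poisson_data_dispersion_near_zero(self, rng):
        m = self._nb_matrix(0.0, 100.0, 100, rng)
        s = size_factors_median_of_ratios(m)
        fit = estimate_dispersions(m, s)
        assert np.median(fit.genewise) <= 0.01

    def test_constant_gene_zero_before_shrinkage(self):
        m = _matrix({"a": [7, 50], "b": [7, 60], "c": [7, 70], "d": [7, 80]})
        m.samples["role"] = ["real", "real", "virtual", "virtual"]
        s = pd.Series(1.0, index=m.sample_ids)
        fit = estimate_dispersions(m, s)
        assert fit.genewise["g0"] == 0.0

    def test_trend_recovery_alpha_0p1(self, rng):
        m = self._nb_matrix(0.1, 1000.0, 100, rng)
        s = size_factors_median_of_ratios(m)
        fit = estimate_dispersions(m, s)
        assert fit.trend_a1 == pytest.approx(0.1, rel=0.2)


class TestWaldTest:
    def test_identical_conditions_null_stats(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, size=40)
        counts = {}
        roles, pairs = [], []
        for i in range(4):
            counts[f"r{i}"] = base
            counts[f"v{i}"] = base
            roles += ["real", "virtual"]
            pairs += [f"p{i}", f"p{i}"]
        order = [f"r{i}" for i in range(4)] + [f"v{i}" for i in range(4)]
        m = _matrix({k: counts[k] for k in order},
                    roles=["real"] * 4 + ["virtual"] * 4,
                    pairs=[f"p{i}" for i in range(4)] * 2)
        s = pd.Series(1.0, index=m.sample_ids)
        fit = estimate_dispersions(m, s)
        table = wald_real_vs_virtual(m, fit)
        assert np.nanmax(np.abs(table["stat"])) < 1e-4
        assert np.nanmin(table["pvalue"]) > 0.999

    def test_plugin_log_ratio_oracle_two_samples(self):
        # one pair, dispersion ~0, no blocking beyond the intercept:
        # the Wald log2fc must equal the plug-in log-ratio of normalized means
        m = _matrix({"r": [120, 45, 600], "v": [60, 90, 600]},
                    roles=["real", "virtual"], pairs=["p1", "p1"])
        s = pd.Series([1.0, 1.0], index=m.sample_ids)
        fit = estimate_dispersions(
            _matrix({"r": [120, 45, 600], "v": [60, 90, 600], "r2": [120, 45, 600],
                     "v2": [60, 90, 600]},
                    roles=["real", "virtual", "real", "virtual"],
                    pairs=["p1", "p1", "p2", "p2"]),
            pd.Series(1.0, index=["r", "v", "r2", "v2"]),
        )
        fit.size_factors = s
        fit.dispersions = pd.Series(1e-12, index=m.gene_ids)
        table = wald_real_vs_virtual(m, fit, paired=True)
        plugin = np.log2(m.counts["r"].to_numpy() / m.counts["v"].to_numpy())
        np.testing.assert_allclose(table["log2fc"].to_numpy(), plugin, atol=1e-6)

    def test_scaling_invariance_of_log2fc(self, small_cohort):
        table1, _, _ = run_de(small_cohort)
        scaled = small_cohort.subset_samples(small_cohort.sample_ids)
        first = scaled.counts.columns[0]
        scaled.counts[first] = scaled.counts[first] * 3
        table2, _, _ = run_de(scaled)
        common = table1.index.intersection(table2.index)
        corr = np.corrcoef(table1.loc[common, "log2fc"], table2.loc[common, "log2fc"])[0, 1]
        assert corr > 0.99
        assert np.abs(table1.loc[common, "log2fc"] - table2.loc[common, "log2fc"]).median() < 0.05


class TestAdjustBH:
    def test_hand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagation_excluded_from_m(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_bh([1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_dominates_raw_p_and_monotone(self, ps):
        adj = adjust_bh(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSignature:
    def test_empty_and_single_gene(self):
        table = pd.DataFrame(
            {"log2fc": [2.0], "padj": [0.01], "pvalue": [0.001],
             "base_mean": [10.0], "se": [0.1], "stat": [5.0]},
            index=pd.Index(["gA"], name="gene_id"),
        )
        sig = extract_signature(table)
        assert sig.up_genes == ["gA"] and sig.down_genes == []
        empty = extract_signature(table[table["padj"] < 0])
        assert empty.genes == []

    def test_recovery_on_simulated_cohort(self, small_experiment, small_cohort):
        _, _, _, truth = small_experiment
        table, sig, _ = run_de(small_cohort)
        found = set(sig.genes)
        true = set(truth.interaction_genes)
        jacc = len(found & true) / len(found | true)
        assert jacc >= 0.8
        for g in found & true:
            assert np.sign(table.loc[g, "log2fc"]) == np.sign(truth.log2fc[g])


def test_pairing_increases_power(small_experiment, small_cohort):
    """Breaking the pair matching should not increase discoveries."""
    _, _, _, truth = small_experiment
    _, sig_paired, _ = run_de(small_cohort, paired=True)
    _, sig_unpaired, _ = run_de(small_cohort, paired=False)
    true = set(truth.interaction_genes)
    tp_paired = len(set(sig_paired.genes) & true)
    tp_unpaired = len(set(sig_unpaired.genes) & true)
    assert tp_paired >= tp_unpaired


def test_wald_agrees_with_independent_nb_implementation():
    """Cross-check the paired NB Wald analysis against an independently
    developed negative-binomial DE implementation on one simulated cohort:
    fold-change estimates should be nearly collinear and the significant-gene
    calls should largely coincide (exact numerical identity is not expected —
    dispersion shrinkage differs)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    from cocomix.mixnull import build_virtual_cohort
    from cocomix.synthdata import SimulationConfig, simulate_coculture_experiment

    cfg = SimulationConfig(
        n_genes=400, n_sc_cultures=8, n_fb_cultures=8, pairing="matched",
        interaction_fraction=0.1, interaction_log2fc=1.5,
        library_size_range=(300_000, 400_000), seed=77,
    )
    m, comp, _ = simulate_coculture_experiment(cfg)
    singles = m.subset_samples(
        m.samples_with_role("sc_single") + m.samples_with_role("fb_single")
    )
    real = m.subset_samples(m.samples_with_role("real"))
    virt = build_virtual_cohort(
        singles, comp, total=int(real.counts.sum(axis=0).mean()), seed=77
    )
    cohort = real.concat(virt)
    table, _, _ = run_de(cohort)

    meta = cohort.samples.copy()
    meta["condition"] = meta["role"]
    dds = DeseqDataSet(
        counts=cohort.counts.T, metadata=meta, design="~pair_id + condition", quiet=True
    )
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "real", "virtual"], quiet=True)
    stats.summary()
    res = stats.results_df
    common = table.index.intersection(res.index)
    lfc_corr = np.corrcoef(
        table.loc[common, "log2fc"], res.loc[common, "log2FoldChange"]
    )[0, 1]
    assert lfc_corr > 0.99
    ours = set(table.index[table["padj"] <= 0.05])
    theirs = set(res.index[res["padj"] <= 0.05])
    assert len(ours & theirs) / max(1, len(ours | theirs)) > 0.8
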