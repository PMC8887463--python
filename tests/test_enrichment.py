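"""Enrichment-module tests: aggregation, filtering, normalization oracles, NB test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import haloseq as h
from haloseq.enrichment import bh_adjust, sense_gene_counts


def _counts(data, samples=None):
    df = pd.DataFrame(data).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


class TestAggregateToGenes:
    def test_feature_sums(self):
        counts = _counts({"f1": [3, 1], "f2": [7, 2]})
        out = h.aggregate_to_genes(counts, {"f1": "g1", "f2": "g1"})
        assert out.loc["g1"].tolist() == [10, 3]

    def test_identity_map(self):
        counts = _counts({"f1": [3, 1], "f2": [7, 2]})
        out = h.aggregate_to_genes(counts, {"f1": "f1", "f2": "f2"})
        pd.testing.assert_frame_equal(out, counts.rename_axis("gene_id"))

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(30, 4)),
            index=[f"f{i}" for i in range(30)],
        )
        fmap = {f"f{i}": f"g{i % 7}" for i in range(30)}
        out = h.aggregate_to_genes(counts, fmap)
        assert (out.sum(axis=0) == counts.sum(axis=0)).all()

    def test_unmapped_feature_raises(self):
        counts = _counts({"f1": [1, 1]})
        with pytest.raises(KeyError, match="annotation mismatch"):
            h.aggregate_to_genes(counts, {})

    def test_sense_gene_counts_drops_antisense(self):
        counts = _counts({"g1|spliced": [4, 4], "g1|unspliced": [1, 0], "g1|ua": [9, 9]})
        out = sense_gene_counts(counts)
        assert out.loc["g1"].tolist() == [5, 4]


class TestFilterMinCounts:
    def test_boundary_gene_retained(self):
        counts = _counts({"g1": [5, 5, 5, 5]})
        assert "g1" in h.filter_min_counts(counts, 5).index

    def test_single_low_sample_removes_gene(self):
        counts = _counts({"g1": [100, 100, 100, 4]})
        assert h.filter_min_counts(counts, 5).empty

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 9, size=(20, 3)))
        pd.testing.assert_frame_equal(h.filter_min_counts(counts, 0), counts)

    @given(st.integers(0, 30))
    def test_retained_iff_all_samples_reach_threshold(self, min_count):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(0, 25, size=(40, 4)))
        kept = h.filter_min_counts(counts, min_count)
        expected = [i for i in counts.index if (counts.loc[i] >= min_count).all()]
        assert list(kept.index) == expected


def median_of_ratios_oracle(counts):
    """Direct re-computation of median-of-ratios factors, median-normalized."""
    mat = counts.to_numpy(dtype=float)
    mat = mat[(mat > 0).all(axis=1)]
    geo = np.exp(np.mean(np.log(mat), axis=1))
    s = np.array([np.median(mat[:, j] / geo) for j in range(mat.shape[1])])
    return s / np.median(s)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _counts({"g1": [10, 10], "g2": [3, 3]})
        assert h.estimate_size_factors(counts).tolist() == [1.0, 1.0]

    def test_doubled_sample_factor_ratio_is_two(self):
        counts = _counts({f"g{i}": [c, 2 * c] for i, c in enumerate([10, 20, 7, 3])})
        sf = h.estimate_size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(0, 200, size=(50, 4)))
        sf = h.estimate_size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), median_of_ratios_oracle(counts), atol=1e-12)

    def test_degenerate_matrix_rejected(self):
        counts = _counts({"g1": [0, 5], "g2": [5, 0]})
        with pytest.raises(ValueError, match="degenerate"):
            h.estimate_size_factors(counts)


def bh_oracle(p):
    """Independent BH step-up transform."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_adjusted_never_below_raw(self, p):
        adj = bh_adjust(np.array(p))
        assert (adj >= np.array(p) - 1e-12).all()

    def test_nan_passthrough(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and np.isfinite(adj[0])


def _simulated_gene_counts(seed=0, n_genes=300, effect=None):
    cfg = h.SimulationConfig(
        n_genes=n_genes, seed=seed,
        class_proportions={"protein_coding": 1.0},
        planted_fraction_enriched=0.0,
        enrichment_effects={"protein_coding": effect or 0.0},
        shift_target_fraction=0.0,
    )
    data = h.simulate_dataset(cfg, conditions=("c",))
    counts = h.filter_min_counts(sense_gene_counts(data["counts"]), 5)
    return counts, data["design"]


class TestNBEnrichmentTest:
    def test_swapping_fraction_labels_negates_log2fc(self):
        counts, design = _simulated_gene_counts(seed=21, n_genes=120)
        res = h.nb_enrichment_test(counts, design)
        flipped = design.assign(
            fraction=design["fraction"].map({"input": "pulldown", "pulldown": "input"})
        )
        res_flip = h.nb_enrichment_test(counts, flipped)
        ok = res["log2FC"].notna() & res_flip["log2FC"].notna()
        np.testing.assert_allclose(
            res.loc[ok, "log2FC"], -res_flip.loc[ok, "log2FC"], atol=1e-6
        )
        np.testing.assert_allclose(
            res.loc[ok, "pvalue"], res_flip.loc[ok, "pvalue"], atol=1e-6
        )

    def test_scaling_one_sample_rescales_its_size_factor_and_keeps_log2fc_stable(self):
        """Library-depth changes are absorbed by the size factor.

        The scaled sample's factor picks up the constant exactly.  The NB
        Wald log2FCs are only asymptotically invariant (the dispersion
        estimate and IRLS weights see the rescaled counts), so they are
        checked for stability, not bitwise equality.
        """
        counts, design = _simulated_gene_counts(seed=22, n_genes=150)
        res = h.nb_enrichment_test(counts, design)
        scaled = counts.copy()
        scaled[scaled.columns[0]] = scaled[scaled.columns[0]] * 4
        res_scaled = h.nb_enrichment_test(scaled, design)
        sf_ratio = (
            pd.Series(res_scaled.attrs["size_factors"]).iloc[0]
            / pd.Series(res.attrs["size_factors"]).iloc[0]
        )
        renorm = pd.Series(res_scaled.attrs["size_factors"]) / pd.Series(res.attrs["size_factors"])
        assert sf_ratio / np.median(renorm) == pytest.approx(4.0, rel=1e-9)
        ok = res["log2FC"].notna() & res_scaled["log2FC"].notna()
        np.testing.assert_allclose(
            res.loc[ok, "log2FC"], res_scaled.loc[ok, "log2FC"], atol=0.15
        )

    def test_global_depth_change_shifts_only_the_intercept(self):
        """Scaling every sample by c (offsets tracking it) leaves the
        contrast coefficient untouched; only the intercept absorbs c."""
        from haloseq.glm import _irls

        rng = np.random.default_rng(11)
        Y = rng.poisson(300.0, size=(40, 6)).astype(float)
        X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        alpha = np.full(40, 1e-8)
        beta, *_ = _irls(Y, X, np.zeros(6), alpha)
        beta2, *_ = _irls(Y * 4, X, np.full(6, np.log(4.0)), alpha)
        np.testing.assert_allclose(beta[:, 1], beta2[:, 1], atol=1e-7)

    def test_stat_is_coefficient_over_se(self):
        counts, design = _simulated_gene_counts(seed=23, n_genes=80)
        res = h.nb_enrichment_test(counts, design).dropna(subset=["stat"])
        np.testing.assert_allclose(res["stat"], res["log2FC"] / res["se"], rtol=1e-9)

    def test_call_thresholds(self):
        """Planted +-2 log2 effects on 30% of genes get the matching call."""
        cfg = h.SimulationConfig(
            n_genes=300, seed=24, class_proportions={"protein_coding": 1.0},
            planted_fraction_enriched=0.3, planted_effect_size=2.0,
            enrichment_effects={"protein_coding": 0.0}, shift_target_fraction=0.0,
        )
        data = h.simulate_dataset(cfg, conditions=("c",))
        counts = h.filter_min_counts(sense_gene_counts(data["counts"]), 5)
        res = h.nb_enrichment_test(counts, data["design"])
        truth = data["truth"].set_index("gene_id")
        planted = truth.index[truth["planted_enriched"]].intersection(res.index)
        assert len(planted) > 50
        calls = res.loc[planted, "call"]
        want = truth.loc[planted, "planted_log2_effect"].map(
            lambda v: "enriched" if v > 0 else "depleted"
        )
        assert (calls == want).mean() > 0.9
        called = res[res["call"] == "enriched"]
        assert (called["padj"] < 0.05).all() and (called["log2FC"] >= 0.5).all()
        ns = res[res["call"] == "ns"]
        assert ((ns["padj"] >= 0.05) | (ns["log2FC"].abs() < 0.5)).all()


class TestAgainstStatsmodelsOracle:
    def test_coefficients_match_statsmodels_at_fixed_dispersion(self):
        """Cross-check the IRLS core against statsmodels GLM, alpha fixed."""
        import statsmodels.api as sm

        from haloseq.glm import _irls

        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        alpha = 0.08
        mean = 150 * np.exp(X[:, 1] * 0.7)
        Y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mean), size=(5, 8)).astype(float)
        offset = np.log(np.linspace(0.8, 1.2, 8))
        beta, _, se, ok = _irls(Y, X, offset, np.full(5, alpha))
        for i in range(5):
            ref = sm.GLM(
                Y[i], X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            np.testing.assert_allclose(beta[i], ref.params, rtol=1e-6, atol=1e-8)
            np.testing.assert_allclose(se[i], ref.bse, rtol=1e-4)
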