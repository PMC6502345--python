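"""Expression filtering, detection, concordance, coverage and GC diagnostics."""

import numpy as np
import pytest

from ffpeqc import (
    ExpressionConfig,
    ExpressionMatrix,
    GCProfile,
    GeneBodyProfile,
    filter_low_expression,
    gc_anomaly_flags,
    gene_body_bias,
    genes_detected,
    replicate_correlation,
    replicate_pca,
    signature_concordance,
    simulate_expression,
)


def _matrix(counts, tpm=None, genes=None, samples=None):
    counts = np.asarray(counts)
    g, s = counts.shape
    genes = genes or [f"g{i}" for i in range(g)]
    samples = samples or [f"s{j}" for j in range(s)]
    tpm = np.asarray(tpm) if tpm is not None else counts.astype(float)
    return ExpressionMatrix(genes, samples, counts, tpm)


class TestFilterLowExpression:
    def test_gene_below_both_thresholds_everywhere_removed(self):
        m = _matrix([[0, 3]], tpm=[[0.2, 0.8]])
        assert filter_low_expression(m).gene_ids == []

    def test_boundary_values_retained(self):
        m = _matrix([[5, 0]], tpm=[[1.0, 0.0]])
        assert filter_low_expression(m).gene_ids == ["g0"]

    def test_ten_gene_toy_matrix_matches_hand_enumeration(self):
        counts = np.array(
            [
                [10, 0], [4, 4], [5, 0], [0, 5], [100, 100],
                [0, 0], [5, 5], [2, 6], [7, 1], [3, 3],
            ]
        )
        tpm = np.array(
            [
                [2.0, 0.0], [0.9, 0.9], [1.0, 0.0], [0.0, 0.5], [50.0, 50.0],
                [0.0, 0.0], [0.5, 0.5], [0.2, 3.0], [1.5, 0.1], [0.9, 0.9],
            ]
        )
        # survivors need count>=5 AND tpm>=1 in at least one sample:
        # g0 (10,2.0), g2 (5,1.0), g4, g7 (6,3.0), g8 (7,1.5)
        m = _matrix(counts, tpm)
        assert filter_low_expression(m).gene_ids == ["g0", "g2", "g4", "g7", "g8"]

    def test_idempotent_and_gene_order_invariant(self, rng):
        counts = rng.poisson(3.0, size=(40, 4))
        tpm = rng.gamma(1.0, 2.0, size=(40, 4))
        m = _matrix(counts, tpm)
        once = filter_low_expression(m)
        twice = filter_low_expression(once)
        assert once.gene_ids == twice.gene_ids
        perm = rng.permutation(40)
        mp = _matrix(counts[perm], tpm[perm], genes=[f"g{i}" for i in perm])
        assert set(filter_low_expression(mp).gene_ids) == set(once.gene_ids)


class TestGenesDetected:
    def test_strictly_greater_than_cutoff(self):
        assert genes_detected(np.array([6, 5, 0, 100])) == 2

    def test_all_zero_column(self):
        assert genes_detected(np.zeros(10)) == 0

    def test_monotone_nonincreasing_in_min_reads(self, rng):
        counts = rng.poisson(10, size=500)
        vals = [genes_detected(counts, k) for k in range(0, 40)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_generator_ground_truth(self):
        m, _, _ = simulate_expression(ExpressionConfig(seed=0, n_samples=6))
        for j, sid in enumerate(m.sample_ids):
            assert genes_detected(m.raw_counts[:, j]) == int(
                (m.raw_counts[:, j] > 5).sum()
            )


class TestReplicateCorrelation:
    def test_identical_columns_give_unit_correlation(self, rng):
        col = rng.gamma(2.0, 10.0, size=50)
        counts = np.tile(rng.poisson(20, 50)[:, None], (1, 2))
        m = _matrix(counts, np.tile(col[:, None], (1, 2)))
        assert replicate_correlation(m, [("s0", "s1")])[("s0", "s1")] == pytest.approx(
            1.0
        )

    def test_absent_pair_member_named_in_error(self):
        m = _matrix(np.ones((5, 2), dtype=int) * 10)
        with pytest.raises(KeyError, match="nope"):
            replicate_correlation(m, [("s0", "nope")])

    def test_concordant_pairs_near_target_and_discordant_low(self):
        rs_c, rs_d = [], []
        for seed in range(5):
            cfg = ExpressionConfig(
                seed=seed, n_samples=16, concordant_pairs=3, discordant_pairs=2
            )
            m, _, truth = simulate_expression(cfg)
            rc = replicate_correlation(m, truth.pairs_concordant)
            rd = replicate_correlation(m, truth.pairs_discordant)
            rs_c += list(rc.values())
            rs_d += list(rd.values())
        assert abs(np.mean(rs_c) - 0.75) < 0.05
        assert max(rs_d) < 0.22


class TestSignatureConcordance:
    def test_sample_equal_to_reference_tops_the_classes(self, rng):
        g = 30
        ref_tpm = rng.gamma(2.0, 50.0, size=g)
        ref = np.log2(ref_tpm + 1)
        cols = [ref_tpm]
        for _ in range(5):
            noise = np.exp(rng.normal(0, 1.5, g))
            cols.append(ref_tpm * noise)
        tpm = np.column_stack(cols)
        counts = np.maximum(tpm.astype(int), 6)
        m = _matrix(counts, tpm)
        res = signature_concordance(m, m.gene_ids, ref)
        j = res.sample_ids.index("s0")
        assert res.concordance[j] == pytest.approx(1.0, abs=1e-6)
        assert res.labels[j] == "B"

    def test_sample_with_all_signature_genes_below_cutoff_excluded(self, rng):
        tpm = rng.gamma(2.0, 20.0, size=(20, 4))
        counts = np.maximum(tpm.astype(int), 10)
        counts[:, 3] = 2  # starved sample
        m = _matrix(counts, tpm)
        res = signature_concordance(m, m.gene_ids, np.log2(tpm[:, 0] + 1))
        assert "s3" in res.excluded
        assert np.isnan(res.concordance[3])
        assert res.labels[3] == "D"

    def test_signature_not_represented_raises(self):
        m = _matrix(np.ones((5, 3), dtype=int) * 10)
        with pytest.raises(ValueError, match="signature not represented"):
            signature_concordance(m, ["absent1", "absent2", "absent3"], np.ones(3))

    def test_planted_three_tier_recovery(self):
        agreements = []
        for seed in range(10):
            m, _, truth = simulate_expression(
                ExpressionConfig(seed=seed, n_samples=24)
            )
            res = signature_concordance(
                m, truth.signature_genes, truth.reference_log2tpm
            )
            tiers = truth.samples.set_index("sample_id")["tier"]
            agreements.append(
                np.mean([res.label_of(s) == tiers[s] for s in m.sample_ids])
            )
        assert np.mean(agreements) >= 0.9

    def test_class_medians_ordered(self):
        m, _, truth = simulate_expression(ExpressionConfig(seed=4, n_samples=24))
        res = signature_concordance(m, truth.signature_genes, truth.reference_log2tpm)
        by = {}
        for lab, c in zip(res.labels, res.concordance):
            by.setdefault(lab, []).append(c)
        med_b = np.nanmedian(by["B"])
        med_c = np.nanmedian(by["C"])
        assert med_b > med_c


class TestGeneBodyBias:
    def test_flat_profile_unbiased(self):
        rep = gene_body_bias([GeneBodyProfile("s", np.ones(100), 20.0)])
        row = rep.per_sample.iloc[0]
        assert row.bias5 == pytest.approx(1.0)
        assert row.bias3 == pytest.approx(1.0)
        assert not row.flag_3prime and not row.flag_5prime

    def test_exponential_3prime_ramp_flagged(self):
        curve = 1.0 + 3.0 * np.exp((np.arange(100) - 99) / 20.0)
        rep = gene_body_bias([GeneBodyProfile("s", curve, 5.0)])
        assert bool(rep.per_sample.iloc[0].flag_3prime)

    def test_scale_invariance(self, rng):
        curve = rng.gamma(5.0, 1.0, size=100)
        a = gene_body_bias([GeneBodyProfile("s", curve, 5.0)]).per_sample.iloc[0]
        b = gene_body_bias([GeneBodyProfile("s", curve * 37.0, 5.0)]).per_sample.iloc[0]
        assert a.bias3 == pytest.approx(b.bias3)
        assert a.bias5 == pytest.approx(b.bias5)

    def test_zero_coverage_excluded_with_reason(self):
        rep = gene_body_bias([GeneBodyProfile("dead", np.zeros(100), 1.0)])
        assert rep.excluded == {"dead": "zero coverage"}
        assert rep.per_sample.empty

    def test_high_mrna_stratum_flatter_on_synthetic_cohort(self):
        _, profs, _ = simulate_expression(ExpressionConfig(seed=7, n_samples=24))
        rep = gene_body_bias(profs["gene_body"])
        hi = rep.strata_curves["high_mrna"]
        lo = rep.strata_curves["low_mrna"]
        assert hi.max() / hi.min() < lo.max() / lo.min()

    def test_wrong_bin_count_rejected(self):
        with pytest.raises(ValueError, match="100"):
            GeneBodyProfile("s", np.ones(50), 5.0)


class TestGCAnomalies:
    def test_centred_gaussian_profile_unflagged(self):
        centers = np.arange(100) + 0.5
        reads = np.exp(-((centers - 50) ** 2) / (2 * 8.0**2))
        f = gc_anomaly_flags(GCProfile("s", reads))
        assert not f.low_gc_flag and not f.high_gc_flag
        assert f.bulk_in_normal_band

    def test_high_gc_mass_flagged(self):
        reads = np.zeros(100)
        reads[45:55] = 8.0
        reads[85:90] = 4.0  # 20% of reads at >=80% GC
        f = gc_anomaly_flags(GCProfile("s", reads))
        assert f.high_gc_flag and not f.low_gc_flag
        assert f.frac_high_gc == pytest.approx(0.2)

    def test_empty_profile_reports_zero_fractions(self):
        f = gc_anomaly_flags(GCProfile("s", np.zeros(100)))
        assert f.frac_low_gc == f.frac_high_gc == f.frac_normal_band == 0.0
        assert not (f.low_gc_flag or f.high_gc_flag or f.bulk_in_normal_band)


class TestReplicatePCA:
    def test_identical_samples_project_identically(self, rng):
        tpm = rng.gamma(2.0, 20.0, size=(50, 4))
        tpm[:, 1] = tpm[:, 0]
        counts = np.maximum(tpm.astype(int), 6)
        proj = replicate_pca(_matrix(counts, tpm))
        np.testing.assert_allclose(
            proj.loc["s0", ["PC1", "PC2"]].to_numpy(dtype=float),
            proj.loc["s1", ["PC1", "PC2"]].to_numpy(dtype=float),
            atol=1e-8,
        )

    def test_gene_reordering_leaves_projection_distances(self, rng):
        tpm = rng.gamma(2.0, 20.0, size=(60, 5))
        counts = np.maximum(tpm.astype(int), 6)
        m = _matrix(counts, tpm)
        perm = rng.permutation(60)
        mp = _matrix(counts[perm], tpm[perm], genes=[m.gene_ids[i] for i in perm])
        d1 = replicate_pca(m)[["PC1", "PC2"]].to_numpy()
        d2 = replicate_pca(mp)[["PC1", "PC2"]].to_numpy()
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(d1), pdist(d2), atol=1e-6)

    def test_planted_outlier_is_farthest_from_centroid(self):
        cfg = ExpressionConfig(
            seed=3, n_samples=12, concordant_pairs=2, discordant_pairs=1,
            tier_proportions=(0.8, 0.1, 0.1),
        )
        m, _, truth = simulate_expression(cfg)
        proj = replicate_pca(m)
        xy = proj[["PC1", "PC2"]].to_numpy()
        d = np.linalg.norm(xy - xy.mean(axis=0), axis=1)
        farthest = proj.index[int(np.argmax(d))]
        tiers = truth.samples.set_index("sample_id")["tier"]
        assert tiers[farthest] == "D"

    def test_fewer_than_three_samples_rejected(self):
        m = _matrix(np.ones((5, 2), dtype=int) * 10)
        with pytest.raises(ValueError, match="3 samples"):
            replicate_pca(m)


def test_from_counts_tpm_columns_sum_to_one_million(rng):
    counts = rng.poisson(30.0, size=(100, 3))
    lengths = rng.uniform(500, 3000, size=100)
    m = ExpressionMatrix.from_counts(
        [f"g{i}" for i in range(100)], ["a", "b", "c"], counts, lengths
    )
    np.testing.assert_allclose(m.tpm.sum(axis=0), 1e6, rtol=1e-3)
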