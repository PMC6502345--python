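"""The ground-truthed generator: determinism, invariants, parameter recovery."""

import numpy as np
import pytest

from ffpeqc import (
    CohortConfig,
    ExpressionConfig,
    dv_from_trace,
    read_qc_table,
    render_trace,
    signature_concordance,
    simulate_cohort,
    simulate_expression,
    write_qc_table,
)
from ffpeqc.synthetic_cohort import lognormal_size_distribution


class TestSimulateCohort:
    def test_fixed_seed_reproduces_identically(self):
        a, ta = simulate_cohort(CohortConfig(seed=7))
        b, tb = simulate_cohort(CohortConfig(seed=7))
        assert a == b
        assert ta.samples.equals(tb.samples)

    def test_different_seeds_differ(self):
        a, _ = simulate_cohort(CohortConfig(seed=1))
        b, _ = simulate_cohort(CohortConfig(seed=2))
        assert a != b

    def test_emitted_records_pass_table_validation_roundtrip(self, tmp_path):
        records, _ = simulate_cohort(CohortConfig(seed=3))
        p = tmp_path / "synthetic.tsv"
        write_qc_table(records, p)
        assert read_qc_table(p) == records  # read re-validates everything

    def test_dv_monotone_by_construction(self):
        records, truth = simulate_cohort(CohortConfig(seed=5, n_samples=120))
        for r in records:
            if r.dv50 is not None:
                assert r.dv50 >= r.dv100 >= r.dv200
        t = truth.samples
        assert (t.dv50_true >= t.dv100_true).all()
        assert (t.dv100_true >= t.dv200_true).all()

    def test_missingness_rates_near_configured(self):
        records, _ = simulate_cohort(CohortConfig(seed=9, n_samples=500))
        frac_dv = np.mean([r.dv100 is None for r in records])
        frac_rin = np.mean([r.rin is None for r in records])
        assert abs(frac_dv - 14 / 67) < 0.06
        assert abs(frac_rin - 6 / 67) < 0.04

    def test_contamination_mixture_is_bimodal(self):
        records, truth = simulate_cohort(CohortConfig(seed=13, n_samples=400))
        pct = np.array([r.contamination_pct for r in records])
        clean = ~truth.samples.contaminated.to_numpy()
        assert pct[clean].max() <= 1.0
        assert np.mean(pct > 5.0) > 0.4  # heavy contaminated tail

    def test_mapping_model_directions(self):
        _, truth = simulate_cohort(CohortConfig(seed=17, n_samples=300))
        t = truth.samples
        assert t[["dv100_true", "mapped_pct"]].corr().iloc[0, 1] > 0.3
        assert t[["contamination_pct", "mapped_pct"]].corr().iloc[0, 1] < 0

    def test_monte_carlo_storage_dv100_recovery(self):
        vals = [
            simulate_cohort(CohortConfig(seed=s))[1].achieved_correlations[
                "storage_dv100"
            ]
            for s in range(40)
        ]
        assert abs(np.mean(vals) - (-0.4)) < 0.1

    def test_zero_noise_monotone_limit_is_rank_perfect(self):
        from scipy.stats import spearmanr

        cfg = CohortConfig(
            seed=2, n_samples=40, size_jitter_sd=0.0,
            target_corr_storage_dv100=-1.0, missing_dv_rate=0.0,
            missing_storage_rate=0.0, n_replicate_pairs=0,
        )
        _, truth = simulate_cohort(cfg)
        t = truth.samples
        rho = spearmanr(t.storage_years, t.mean_fragment_size_nt).statistic
        assert rho == pytest.approx(-1.0)

    def test_infeasible_targets_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cohort(
                CohortConfig(target_corr_storage_dv100=-0.99, size_jitter_sd=0.3)
            )
        with pytest.raises(ValueError):
            CohortConfig(n_samples=1).validate()
        with pytest.raises(ValueError):
            CohortConfig(tier_proportions=(0.5, 0.5, 0.5)).validate()


class TestRenderTrace:
    def test_noiseless_render_recovers_dv_within_half_point(self, rng):
        for mean in (60.0, 120.0, 250.0):
            dist = lognormal_size_distribution(mean, 0.9)
            trace, true_dv = render_trace(dist, noise_sd=0.0, marker=True)
            prof = dv_from_trace(trace)
            np.testing.assert_allclose(prof.dv, true_dv.dv, atol=0.5)

    def test_marker_off_yields_failed_profile(self):
        trace, _ = render_trace(lognormal_size_distribution(150, 0.9), marker=False)
        assert dv_from_trace(trace).failed

    def test_bad_grid_step_rejected(self):
        with pytest.raises(ValueError, match="grid step"):
            render_trace(lognormal_size_distribution(100, 0.9), grid_step_nt=0.0)

    def test_noise_degrades_recovery_monotonically_in_expectation(self):
        mean_err = []
        for noise in (0.0, 0.05, 0.15):
            errs = []
            for seed in range(12):
                r = np.random.default_rng(seed)
                dist = lognormal_size_distribution(120, 0.9)
                trace, true_dv = render_trace(dist, noise_sd=noise, rng=r)
                prof = dv_from_trace(trace)
                if not prof.failed:
                    errs.append(float(np.max(np.abs(prof.dv - true_dv.dv))))
            mean_err.append(np.mean(errs))
        assert mean_err[0] < mean_err[1] < mean_err[2]


class TestSimulateExpression:
    def test_fixed_seed_reproduces_identically(self):
        m1, p1, t1 = simulate_expression(ExpressionConfig(seed=4))
        m2, p2, t2 = simulate_expression(ExpressionConfig(seed=4))
        assert np.array_equal(m1.raw_counts, m2.raw_counts)
        assert t1.samples.equals(t2.samples)

    def test_tpm_consistent_with_counts_and_lengths(self):
        m, _, _ = simulate_expression(ExpressionConfig(seed=1, n_samples=6))
        np.testing.assert_allclose(m.tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_bad_tier_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_expression(ExpressionConfig(tier_proportions=(0.5, 0.2, 0.2)))

    def test_all_top_tier_cohort_one_dominant_cluster_no_anomalies(self):
        cfg = ExpressionConfig(
            seed=6, n_samples=15, tier_proportions=(1.0, 0.0, 0.0),
            gc_anomaly_rate=0.0,
        )
        m, profs, truth = simulate_expression(cfg)
        res = signature_concordance(m, truth.signature_genes, truth.reference_log2tpm)
        counts = {lab: res.labels.count(lab) for lab in set(res.labels)}
        assert max(counts.values()) >= 0.8 * len(m.sample_ids)
        assert not truth.samples.planted_gc_anomaly.any()
        assert not truth.samples.planted_3prime_bias.any()

    def test_planted_profiles_match_truth_flags(self):
        from ffpeqc import gc_anomaly_flags, gene_body_bias

        cfg = ExpressionConfig(seed=2, n_samples=24, gc_anomaly_rate=0.3)
        m, profs, truth = simulate_expression(cfg)
        t = truth.samples.set_index("sample_id")
        flags = {
            f.sample_id: (f.low_gc_flag or f.high_gc_flag)
            for f in (gc_anomaly_flags(p) for p in profs["gc"])
        }
        assert np.mean(
            [flags[s] == t.loc[s, "planted_gc_anomaly"] for s in m.sample_ids]
        ) >= 0.9
        rep = gene_body_bias(profs["gene_body"]).per_sample.set_index("sample_id")
        agree = np.mean(
            [
                bool(rep.loc[s, "flag_3prime"]) == bool(t.loc[s, "planted_3prime_bias"])
                for s in rep.index
            ]
        )
        assert agree >= 0.85
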