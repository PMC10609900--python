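"""Generators: reproducibility, closed-form expectations, phenotype formulas."""

import math

import numpy as np
import pytest

from caffmr import (
    CompensationConfig,
    Locus,
    SummaryGenConfig,
    ValidationError,
    cohort_gwas,
    derive_phenotypes,
    expected_mr_estimates,
    gen_summary_stats,
    run_mr,
    simulate_cohort,
    simulate_ivw_replicates,
)


class TestGenSummaryStats:
    def test_reproducible_from_seed(self):
        cfg = SummaryGenConfig(seed=42)
        e1, o1, t1 = gen_summary_stats(cfg)
        e2, o2, t2 = gen_summary_stats(cfg)
        assert [r.beta for r in e1] == [r.beta for r in e2]
        assert [r.beta for r in o1] == [r.beta for r in o2]
        assert t1 == t2

    def test_tables_share_rsids_and_orientation(self):
        e, o, _ = gen_summary_stats(SummaryGenConfig(k=5, seed=0))
        assert e.rsids == o.rsids
        assert all(a.alleles == b.alleles for a, b in zip(e, o))

    def test_se_follows_single_snp_approximation(self):
        cfg = SummaryGenConfig(k=3, seed=1)
        e, o, truth = gen_summary_stats(cfg)
        for rec, f in zip(e, truth["eaf"]):
            assert rec.se == pytest.approx(
                math.sqrt(1.0 / (2 * f * (1 - f) * cfg.n_exposure)), rel=1e-9
            )

    def test_degenerate_eaf_rejected(self):
        with pytest.raises(ValidationError):
            SummaryGenConfig(eaf_range=(0.0, 0.5))

    def test_replicate_driver_matches_single_table_path(self):
        """The vectorized replicate driver and gen_summary_stats->run_mr
        produce bit-identical fixed-effect results from the same substream."""
        cfg = SummaryGenConfig(theta=0.3, seed=9, n_exposure=50_000, n_outcome=400_000)
        e, o, _ = gen_summary_stats(cfg)
        table_res, _ = run_mr(e, o, method="fixed")
        rep = simulate_ivw_replicates(cfg, n_reps=1)
        assert rep["beta_fixed"][0] == table_res.beta
        assert rep["se_fixed"][0] == table_res.se
        assert rep["q"][0] == table_res.q

    def test_null_mean_estimate_near_zero(self):
        rep = simulate_ivw_replicates(SummaryGenConfig(theta=0.0, seed=5), 2000)
        mc_se = rep["beta_fixed"].std(ddof=1) / math.sqrt(2000)
        assert abs(rep["beta_fixed"].mean()) < 3 * mc_se


class TestSimulateCohort:
    def test_plasma_identity_exact(self):
        sim = simulate_cohort(CompensationConfig(n=500, seed=0))
        np.testing.assert_array_equal(
            sim.log_plasma, sim.log_intake - sim.log_clearance
        )

    def test_reproducible_and_genotypes_valid(self):
        cfg = CompensationConfig(n=300, seed=3)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.outcome, b.outcome)
        assert set(np.unique(a.genotypes)) <= {0, 1, 2}

    def test_full_compensation_decouples_plasma_from_genotype(self):
        """kappa=1: plasma = mu + e_I, so genotype-plasma covariance vanishes."""
        cfg = CompensationConfig(n=100_000, kappa=1.0, sd_i=0.01, seed=2)
        sim = simulate_cohort(cfg)
        for l in range(sim.n_loci):
            cov = np.cov(sim.genotypes[:, l], sim.log_plasma)[0, 1]
            assert abs(cov) < 0.005

    def test_no_compensation_decouples_intake_from_genotype(self):
        cfg = CompensationConfig(n=100_000, kappa=0.0, sd_i=0.01, seed=2)
        sim = simulate_cohort(cfg)
        for l in range(sim.n_loci):
            cov = np.cov(sim.genotypes[:, l], sim.log_intake)[0, 1]
            assert abs(cov) < 0.005

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            CompensationConfig(kappa=1.5)
        with pytest.raises(ValidationError):
            CompensationConfig(loci=(Locus(0.0, 0.3),))
        with pytest.raises(ValidationError):
            CompensationConfig(sd_y=0.0)


class TestCohortGWAS:
    def test_expected_signs_under_partial_compensation(self):
        """delta > 0, kappa = 0.5: clearance alleles lower plasma, raise intake."""
        sim = simulate_cohort(CompensationConfig(n=50_000, seed=4))
        idx = np.arange(25_000)
        plasma = cohort_gwas(sim, "log_plasma", idx)
        intake = cohort_gwas(sim, "log_intake", idx)
        assert all(rec.beta < 0 for rec in plasma)
        assert all(rec.beta > 0 for rec in intake)

    def test_estimates_match_closed_form_slopes(self):
        cfg = CompensationConfig(n=200_000, seed=8)
        sim = simulate_cohort(cfg)
        table = cohort_gwas(sim, "log_plasma", np.arange(100_000))
        for rec, locus in zip(table, cfg.loci):
            slope = locus.delta * (cfg.kappa - 1.0)
            assert abs(rec.beta - slope) < 3 * rec.se

    def test_monomorphic_locus_dropped_with_note(self):
        cfg = CompensationConfig(n=2_000, loci=(Locus(0.001, 0.3), Locus(0.5, 0.2)), seed=1)
        sim = simulate_cohort(cfg)
        # a tiny subsample of a near-fixed locus is typically monomorphic
        sub = np.flatnonzero(sim.genotypes[:, 0] == 0)[:200]
        table = cohort_gwas(sim, "log_plasma", sub)
        assert table.dropped_loci == ["rs_sim1"]
        assert table.rsids == ["rs_sim2"]

    def test_empty_subsample_rejected(self):
        sim = simulate_cohort(CompensationConfig(n=100, seed=0))
        with pytest.raises(ValidationError):
            cohort_gwas(sim, "log_plasma", [])
        with pytest.raises(ValidationError):
            cohort_gwas(sim, "height", [0, 1])


class TestExpectedMREstimates:
    def test_pure_plasma_effect(self):
        cfg = CompensationConfig(gamma_p=-0.2, gamma_i=0.0, kappa=0.3)
        exp = expected_mr_estimates(cfg)
        assert exp.plasma_mr == pytest.approx(-0.2)

    def test_sign_discrepancy_at_half_compensation(self):
        """gamma_p=-0.2, gamma_i=0, kappa=0.5: (kappa-1)/kappa = -1, so the
        intake-instrumented analysis sees +0.2 — opposite sign to plasma."""
        exp = expected_mr_estimates(
            CompensationConfig(gamma_p=-0.2, gamma_i=0.0, kappa=0.5)
        )
        assert exp.plasma_mr == pytest.approx(-0.2)
        assert exp.intake_mr == pytest.approx(+0.2)

    def test_pure_intake_effect_mirrors(self):
        exp = expected_mr_estimates(
            CompensationConfig(gamma_p=0.0, gamma_i=0.1, kappa=0.5)
        )
        assert exp.plasma_mr == pytest.approx(-0.1)
        assert exp.intake_mr == pytest.approx(+0.1)

    def test_boundary_kappa_flagged_undefined(self):
        with pytest.warns(UserWarning, match="kappa = 1"):
            exp = expected_mr_estimates(CompensationConfig(kappa=1.0))
        assert math.isnan(exp.plasma_mr)
        with pytest.warns(UserWarning, match="kappa = 0"):
            exp = expected_mr_estimates(CompensationConfig(kappa=0.0))
        assert math.isnan(exp.intake_mr)


class TestDerivePhenotypes:
    def test_formulas_on_spot_values(self):
        out = derive_phenotypes(10.0, 30.0, 100.0, 90.0)
        assert out.bun == pytest.approx(28.0)
        assert out.uacr == pytest.approx(30.0)
        assert out.log_egfr_winsorized == pytest.approx(math.log(90.0))

    def test_winsorization_boundaries(self):
        high = derive_phenotypes(10.0, 30.0, 100.0, 250.0)
        assert high.log_egfr_winsorized == pytest.approx(5.298317366548036)
        low = derive_phenotypes(10.0, 30.0, 100.0, 5.0)
        assert low.log_egfr_winsorized == pytest.approx(math.log(15.0))

    def test_vectorized(self):
        out = derive_phenotypes(
            np.array([10.0, 20.0]), np.array([30.0, 60.0]),
            np.array([100.0, 50.0]), np.array([90.0, 300.0]),
        )
        np.testing.assert_allclose(out.bun, [28.0, 56.0])
        np.testing.assert_allclose(out.uacr, [30.0, 120.0])
        np.testing.assert_allclose(out.log_egfr_winsorized, [math.log(90), math.log(200)])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            derive_phenotypes(0.0, 30.0, 100.0, 90.0)
        with pytest.raises(ValidationError):
            derive_phenotypes(10.0, 30.0, -1.0, 90.0)
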