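"""Wald-ratio and IVW estimators against hand-computed and regression oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caffmr import (
    AssociationTable,
    HarmonizedPair,
    NoInstrumentsError,
    UndefinedRatioError,
    ValidationError,
    WaldEstimate,
    WeakInstrumentWarning,
    finalize,
    ivw_fixed,
    ivw_random,
    load_table1_fixture,
    run_mr,
    wald_ratio,
)
from caffmr.mr import MRResult
from conftest import va


def hp(beta_exp, se_exp, beta_out, se_out, rsid="rs1"):
    return HarmonizedPair(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta_exposure=beta_exp, se_exposure=se_exp,
        beta_outcome=beta_out, se_outcome=se_out, action="none",
    )


class TestWaldRatio:
    def test_zero_numerator(self):
        est = wald_ratio(hp(0.109, 0.015, 0.0, 0.005))
        assert est.theta == 0.0
        assert est.se_theta == pytest.approx(0.045871559633027525, rel=1e-12)

    def test_unit_ratio_first_order(self):
        est = wald_ratio(hp(0.5, 0.01, 0.5, 0.1))
        assert est.theta == pytest.approx(1.0)
        assert est.se_theta == pytest.approx(0.2)

    def test_first_and_second_order_se(self):
        pair = hp(0.109, 0.015, -0.002, 0.0005)
        first = wald_ratio(pair, se_method="first_order")
        assert first.theta == pytest.approx(-0.018348623853211, rel=1e-12)
        assert first.se_theta == pytest.approx(0.0045871559633027525, rel=1e-12)
        second = wald_ratio(pair, se_method="second_order")
        # sqrt(0.0005^2/0.109^2 + 0.002^2 * 0.015^2 / 0.109^4)
        assert second.se_theta == pytest.approx(0.005236203465417551, rel=1e-12)
        assert second.se_theta > first.se_theta

    def test_zero_exposure_beta_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(hp(0.0, 0.015, 0.01, 0.005))
        with pytest.raises(UndefinedRatioError):
            wald_ratio(hp(1e-13, 0.015, 0.01, 0.005))

    def test_weak_instrument_warning(self):
        with pytest.warns(WeakInstrumentWarning):
            wald_ratio(hp(0.02, 0.015, 0.01, 0.005))

    def test_dropped_pair_rejected(self):
        pair = HarmonizedPair(
            rsid="rs1", effect_allele="A", other_allele="G",
            beta_exposure=0.1, se_exposure=0.01, beta_outcome=0.1,
            se_outcome=0.01, action="dropped", drop_reason="allele_mismatch",
        )
        with pytest.raises(ValidationError):
            wald_ratio(pair)


class TestIVWFixed:
    def test_single_estimate_identity(self):
        res = ivw_fixed([WaldEstimate("rs1", 2.0, 0.3)])
        assert (res.beta, res.se, res.q, res.k, res.df) == (2.0, 0.3, 0.0, 1, 0)

    def test_hand_meta_analysis(self):
        res = ivw_fixed(
            [WaldEstimate("a", 1.0, 0.5), WaldEstimate("b", 3.0, 0.5)]
        )
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.35355339059327373, rel=1e-12)
        assert res.q == pytest.approx(8.0)

    def test_homogeneous_estimates_zero_q(self):
        res = ivw_fixed([WaldEstimate("a", 2.0, 0.1), WaldEstimate("b", 2.0, 0.4)])
        assert res.beta == pytest.approx(2.0)
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_is_usage_error(self):
        with pytest.raises(NoInstrumentsError):
            ivw_fixed([])

    @given(
        st.lists(
            st.tuples(
                st.floats(0.05, 0.5),   # beta_exposure
                st.floats(-0.2, 0.2),   # beta_outcome
                st.floats(0.001, 0.05), # se_outcome
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_precision_weighted_regression_through_origin(self, triples):
        """First-order IVW equals the WLS slope through the origin of
        beta_outcome on beta_exposure with weights 1/se_outcome^2 — an
        independent regression route to the same estimand."""
        import statsmodels.api as sm

        estimates = [
            WaldEstimate(f"rs{i}", by / bx, sy / abs(bx))
            for i, (bx, by, sy) in enumerate(triples)
        ]
        res = ivw_fixed(estimates)
        bx = np.array([t[0] for t in triples])
        by = np.array([t[1] for t in triples])
        sy = np.array([t[2] for t in triples])
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert res.beta == pytest.approx(float(fit.params[0]), rel=1e-10, abs=1e-12)
        assert res.se == pytest.approx(
            float(np.sqrt(1.0 / np.sum(bx**2 / sy**2))), rel=1e-10
        )


class TestIVWRandom:
    def test_two_estimate_hand_computation_both_flavors(self):
        ests = [WaldEstimate("a", 1.0, 0.5), WaldEstimate("b", 3.0, 0.5)]
        mult = ivw_random(ests, flavor="multiplicative")
        assert mult.beta == pytest.approx(2.0)
        assert mult.dispersion == pytest.approx(8.0)
        assert mult.se == pytest.approx(1.0, rel=1e-12)
        dl = ivw_random(ests, flavor="additive_dl")
        assert dl.tau2 == pytest.approx(1.75)
        assert dl.beta == pytest.approx(2.0)
        assert dl.se == pytest.approx(1.0, rel=1e-12)

    def test_identical_estimates_floor_to_fixed(self):
        ests = [WaldEstimate("a", 2.0, 0.3), WaldEstimate("b", 2.0, 0.3)]
        mult = ivw_random(ests, flavor="multiplicative")
        fixed = ivw_fixed(ests)
        assert mult.dispersion == 1.0
        assert mult.se == pytest.approx(fixed.se)
        assert mult.beta == pytest.approx(fixed.beta)

    def test_k1_reduces_to_wald_estimate(self):
        res = ivw_random([WaldEstimate("a", 2.0, 0.3)])
        assert (res.beta, res.se) == (2.0, 0.3)
        assert res.note is not None

    @given(
        theta1=st.floats(-2, 2), theta2=st.floats(-2, 2), se=st.floats(0.05, 1.0)
    )
    def test_equal_se_k2_flavors_coincide(self, theta1, theta2, se):
        """With two equal-SE estimates the multiplicative and additive
        random-effects standard errors are provably identical."""
        ests = [WaldEstimate("a", theta1, se), WaldEstimate("b", theta2, se)]
        mult = ivw_random(ests, flavor="multiplicative")
        dl = ivw_random(ests, flavor="additive_dl")
        assert mult.beta == pytest.approx(dl.beta, rel=1e-10, abs=1e-12)
        assert mult.se == pytest.approx(dl.se, rel=1e-10, abs=1e-12)

    def test_random_se_never_below_fixed(self):
        ests = [WaldEstimate("a", 1.9, 0.4), WaldEstimate("b", 2.2, 0.25)]
        assert ivw_random(ests, "multiplicative").se >= ivw_fixed(ests).se


class TestFinalize:
    def test_null_result_ci_and_p(self):
        res = finalize(MRResult(beta=0.0, se=1.0, method="fixed", k=1))
        assert res.ci_low == pytest.approx(-1.959963984540054, rel=1e-12)
        assert res.ci_high == pytest.approx(1.959963984540054, rel=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_binary_outcome_odds_ratio_view(self):
        res = finalize(
            MRResult(beta=-0.1744, se=0.0576, method="fixed", k=2),
            trait_type="binary",
        )
        assert res.or_ == pytest.approx(0.840, abs=5e-4)
        assert res.or_ci_low == pytest.approx(0.750, abs=5e-4)
        assert res.or_ci_high == pytest.approx(0.940, abs=5e-4)

    def test_normal_p_from_z(self):
        res = finalize(MRResult(beta=1.0, se=0.5, method="fixed", k=1))
        assert res.z == pytest.approx(2.0)
        assert res.pvalue == pytest.approx(0.04550026389635839, rel=1e-10)


class TestRunMR:
    def _outcome(self, records):
        return AssociationTable(records, trait_id="outcome")

    def test_exact_proportionality_recovers_theta(self):
        """Outcome betas built as exactly theta * beta_x give back theta with Q ~ 0."""
        theta = -0.23
        exposure = load_table1_fixture("plasma_caffeine")
        outcome = self._outcome(
            [
                va(rsid=r.rsid, ea=r.effect_allele, oa=r.other_allele,
                   beta=theta * r.beta, se=1e-6, eaf=r.eaf)
                for r in exposure
            ]
        )
        res, detail = run_mr(exposure, outcome, method="fixed")
        assert res.beta == pytest.approx(theta, rel=1e-9)
        assert res.q == pytest.approx(0.0, abs=1e-6)
        assert len(detail["per_variant"]) == 2

    def test_single_variant_equals_wald_ratio(self):
        exposure = AssociationTable([va(rsid="rs1", beta=0.2, se=0.01)])
        outcome = self._outcome([va(rsid="rs1", beta=0.05, se=0.004)])
        res, _ = run_mr(exposure, outcome)
        assert res.beta == pytest.approx(0.25)
        assert res.se == pytest.approx(0.02)

    def test_no_shared_variants_is_error(self):
        exposure = AssociationTable([va(rsid="rs1")])
        outcome = self._outcome([va(rsid="rs2")])
        with pytest.raises(NoInstrumentsError):
            run_mr(exposure, outcome)

    def test_binary_outcome_gets_or_view(self):
        exposure = AssociationTable([va(rsid="rs1", beta=0.2, se=0.01)])
        outcome = self._outcome(
            [va(rsid="rs1", beta=-0.05, se=0.01, trait_type="binary")]
        )
        res, _ = run_mr(exposure, outcome)
        assert res.trait_type == "binary"
        assert res.or_ == pytest.approx(np.exp(res.beta))

    @given(scale=st.floats(0.2, 5.0))
    def test_scale_equivariance(self, scale):
        """Multiplying exposure betas by c divides the pooled estimate by c."""
        exposure = AssociationTable(
            [va(rsid="rs1", beta=0.1, se=0.01), va(rsid="rs2", beta=0.15, se=0.02)]
        )
        scaled = AssociationTable(
            [r.replace(beta=r.beta * scale) for r in exposure], trait_id="x"
        )
        outcome = self._outcome(
            [va(rsid="rs1", beta=0.03, se=0.005), va(rsid="rs2", beta=0.05, se=0.004)]
        )
        base, _ = run_mr(exposure, outcome, method="fixed")
        res, _ = run_mr(scaled, outcome, method="fixed")
        assert res.beta * scale == pytest.approx(base.beta, rel=1e-9)

    def test_joint_sign_flip_invariance(self):
        """Negating both exposure and outcome betas (allele relabeling)
        leaves the pooled result unchanged."""
        exposure = AssociationTable(
            [va(rsid="rs1", beta=0.1, se=0.01), va(rsid="rs2", beta=0.15, se=0.02)]
        )
        outcome = self._outcome(
            [va(rsid="rs1", beta=0.03, se=0.005), va(rsid="rs2", beta=0.05, se=0.004)]
        )
        flipped_exp = AssociationTable(
            [r.replace(effect_allele=r.other_allele, other_allele=r.effect_allele,
                       beta=-r.beta) for r in exposure]
        )
        flipped_out = self._outcome(
            [r.replace(effect_allele=r.other_allele, other_allele=r.effect_allele,
                       beta=-r.beta) for r in outcome]
        )
        a, _ = run_mr(exposure, outcome)
        b, _ = run_mr(flipped_exp, flipped_out)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)
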