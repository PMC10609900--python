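"""Model/Results interface for two-sample MR analyses.

:class:`MRModel` is constructed from an exposure and an outcome
summary-statistics table (optionally with instrument selection applied
first); :meth:`MRModel.fit` harmonizes alleles, forms per-variant Wald
ratios, pools them by IVW, and returns an :class:`MRResults` carrying the
pooled estimate, its uncertainty, heterogeneity diagnostics, the
per-variant table, the harmonization audit, and a ``summary()`` report.

    >>> from caffmr import MRModel, load_table1_fixture
    >>> model = MRModel(load_table1_fixture("plasma_caffeine"), outcome_table)
    >>> res = model.fit(method="random_multiplicative")
    >>> print(res.summary())
"""

from __future__ import annotations

import json

import pandas as pd

from .harmonization import HarmonizationReport
from .mr import MRResult, run_mr
from .summary_stats import AssociationTable

__all__ = ["MRModel", "MRResults"]


class MRModel:
    """Two-sample Mendelian randomization model.

    Parameters
    ----------
    exposure : AssociationTable
        Variant-exposure associations (the instruments).
    outcome : AssociationTable
        Variant-outcome associations from a non-overlapping sample.
    trait_type : {"continuous", "binary"}, optional
        Outcome scale; inferred from the outcome table when omitted.
        Binary outcomes get an odds-ratio view on the fitted results.
    palindrome_policy : {"infer_by_eaf", "drop"}
    eaf_ambiguity_band : float
        See :func:`caffmr.harmonization.harmonize_pair`.
    """

    def __init__(
        self,
        exposure: AssociationTable,
        outcome: AssociationTable,
        trait_type: str | None = None,
        palindrome_policy: str = "infer_by_eaf",
        eaf_ambiguity_band: float = 0.08,
    ):
        self.exposure = exposure
        self.outcome = outcome
        self.trait_type = trait_type
        self.palindrome_policy = palindrome_policy
        self.eaf_ambiguity_band = eaf_ambiguity_band

    @classmethod
    def from_files(
        cls,
        exposure_path,
        outcome_path,
        exposure_column_map=None,
        outcome_column_map=None,
        delimiter: str = "\t",
        **kwargs,
    ) -> "MRModel":
        """Build a model directly from two summary-statistics files."""
        from .summary_stats import read_associations

        exposure = read_associations(
            exposure_path, column_map=exposure_column_map, delimiter=delimiter
        )
        outcome = read_associations(
            outcome_path, column_map=outcome_column_map, delimiter=delimiter
        )
        return cls(exposure, outcome, **kwargs)

    def fit(
        self,
        method: str = "random_multiplicative",
        se_method: str = "first_order",
        alpha: float = 0.05,
    ) -> "MRResults":
        """Run the pipeline and return fitted results.

        ``method``: ``fixed``, ``random_multiplicative`` (default; the
        fixed-effect estimate with SE inflated by the heterogeneity
        overdispersion, floored at 1), or ``random_dl`` (additive
        DerSimonian-Laird). ``se_method``: ``first_order`` or
        ``second_order`` Wald-ratio SEs.
        """
        result, detail = run_mr(
            self.exposure,
            self.outcome,
            method=method,
            se_method=se_method,
            alpha=alpha,
            trait_type=self.trait_type,
            palindrome_policy=self.palindrome_policy,
            eaf_ambiguity_band=self.eaf_ambiguity_band,
        )
        return MRResults(self, result, detail)


class MRResults:
    """Fitted results of a two-sample MR analysis.

    Attributes
    ----------
    result : MRResult
        Pooled estimate with CI, p, Q, and method metadata.
    per_variant : pandas.DataFrame
        One row per shared variant: harmonization action and Wald estimate.
    harmonization : HarmonizationReport
        Counts of actions, drops, and missing instruments.
    """

    def __init__(self, model: MRModel, result: MRResult, detail: dict):
        self.model = model
        self.result = result
        self.per_variant = pd.DataFrame(detail["per_variant"])
        self.harmonization: HarmonizationReport = detail["harmonization"]

    # convenience pass-throughs, statsmodels-style
    @property
    def params(self) -> float:
        return self.result.beta

    @property
    def bse(self) -> float:
        return self.result.se

    @property
    def pvalue(self) -> float:
        return self.result.pvalue

    def conf_int(self) -> tuple[float, float]:
        return (self.result.ci_low, self.result.ci_high)

    def to_dict(self) -> dict:
        r = self.result
        d = {
            "beta": r.beta,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "z": r.z,
            "pvalue": r.pvalue,
            "q": r.q,
            "df": r.df,
            "q_pvalue": r.q_pvalue,
            "tau2": r.tau2,
            "dispersion": r.dispersion,
            "method": r.method,
            "k": r.k,
            "alpha": r.alpha,
            "trait_type": r.trait_type,
        }
        if r.trait_type == "binary":
            d.update(odds_ratio=r.or_, or_ci_low=r.or_ci_low, or_ci_high=r.or_ci_high)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        """Human-readable fit report."""
        r = self.result
        width = 64
        lines = [
            "Two-Sample Mendelian Randomization Results".center(width),
            "=" * width,
            f"Exposure: {self.model.exposure.trait_id or '(unnamed)':<30}"
            f"Method: {r.method}",
            f"Outcome:  {self.model.outcome.trait_id or '(unnamed)':<30}"
            f"Instruments (k): {r.k}",
            "-" * width,
            f"beta      {r.beta: .6f}    se       {r.se:.6f}",
            f"{(1 - r.alpha) * 100:.0f}% CI    [{r.ci_low: .6f}, {r.ci_high: .6f}]",
            f"z         {r.z: .4f}      p        {r.pvalue:.3g}",
            f"Cochran Q {r.q: .4f}      df {r.df}    p(Q) "
            + (f"{r.q_pvalue:.3g}" if r.q_pvalue is not None else "n/a"),
        ]
        if r.dispersion is not None:
            lines.append(f"overdispersion (floored at 1): {r.dispersion:.4f}")
        if r.tau2 is not None:
            lines.append(f"tau^2 (DerSimonian-Laird): {r.tau2:.6f}")
        if r.trait_type == "binary":
            lines.append(
                f"OR        {r.or_:.3f}      "
                f"{(1 - r.alpha) * 100:.0f}% CI [{r.or_ci_low:.3f}, {r.or_ci_high:.3f}]"
            )
        if r.note:
            lines.append(f"note: {r.note}")
        lines.append("-" * width)
        lines.append("Per-variant Wald estimates")
        for _, row in self.per_variant.iterrows():
            if row["theta"] is not None and not pd.isna(row["theta"]):
                lines.append(
                    f"  {row['rsid']:<12} theta {row['theta']: .6f} "
                    f"(se {row['se_theta']:.6f})  [{row['action']}]"
                )
            else:
                lines.append(
                    f"  {row['rsid']:<12} dropped ({row['drop_reason']})"
                )
        lines.append("=" * width)
        return "\n".join(lines)

    def __repr__(self) -> str:
        r = self.result
        return (
            f"<MRResults {r.method} k={r.k} beta={r.beta:.4f} "
            f"({r.ci_low:.4f}, {r.ci_high:.4f}) p={r.pvalue:.3g}>"
        )
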