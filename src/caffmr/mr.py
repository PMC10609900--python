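"""Wald-ratio and inverse-variance-weighted (IVW) two-sample MR estimators.

For a variant j with harmonized exposure association (beta_xj, se_xj) and
outcome association (beta_yj, se_yj), the per-variant causal estimate is
the Wald ratio

    theta_j = beta_yj / beta_xj,

with standard error, to first order, se_yj / |beta_xj| (the delta-method
term from the outcome association only), or to second order
sqrt(se_yj^2/beta_xj^2 + beta_yj^2 se_xj^2 / beta_xj^4), which adds the
uncertainty of the exposure association.

Wald ratios are pooled by inverse-variance weighting, w_j = 1/se_j^2:

    beta_IVW = sum(w theta) / sum(w),   se_IVW = sqrt(1 / sum(w)),

with heterogeneity measured by Cochran's Q = sum(w (theta - beta_IVW)^2)
on k-1 degrees of freedom. Two random-effects flavors are provided:

* multiplicative: the fixed-effect point estimate with its SE inflated by
  sqrt(max(1, Q/(k-1))) — the overdispersion factor is floored at 1, so
  the random-effects SE never undercuts the fixed-effect SE;
* additive (DerSimonian-Laird): a between-variant variance tau^2 estimated
  by the method of moments, added to each variance before re-weighting.

With only two instruments — the situation for cis-instrumented molecular
exposures like plasma caffeine — the flavors can differ; both are exposed.
Confidence intervals and p-values use the normal reference distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import (
    NoInstrumentsError,
    UndefinedRatioError,
    ValidationError,
    WeakInstrumentWarning,
)
from .harmonization import HarmonizedPair, harmonize_tables
from .summary_stats import AssociationTable

__all__ = [
    "WaldEstimate",
    "MRResult",
    "wald_ratio",
    "ivw_fixed",
    "ivw_random",
    "finalize",
    "run_mr",
]

#: |beta_exposure| below this is treated as exactly zero (undefined ratio).
ZERO_BETA_GUARD = 1e-12

#: Default instrument-strength threshold: warn when |beta_x|/se_x falls
#: below this z-score.
WEAK_INSTRUMENT_Z = 3.0


@dataclass(frozen=True)
class WaldEstimate:
    """Per-variant ratio estimate of the causal effect."""

    rsid: str
    theta: float
    se_theta: float
    se_method: str = "first_order"

    def __post_init__(self) -> None:
        if not (self.se_theta > 0):
            raise ValidationError(f"{self.rsid}: se_theta must be > 0")
        if self.se_method not in ("first_order", "second_order"):
            raise ValidationError(f"unknown se_method {self.se_method!r}")


@dataclass(frozen=True)
class MRResult:
    """Pooled MR estimate with uncertainty, heterogeneity, and metadata.

    ``beta``/``se`` are on the outcome scale per unit of the exposure GWAS
    scale (log-odds for binary outcomes). ``q`` is Cochran's Q on ``df``
    = k-1 degrees of freedom; ``tau2`` is the additive between-variant
    variance (additive model only); ``dispersion`` the multiplicative
    overdispersion factor Q/(k-1) floored at 1 (multiplicative model
    only). The odds-ratio view (``or_``, ``or_ci_low``, ``or_ci_high``)
    is populated by :func:`finalize` for binary outcomes.
    """

    beta: float
    se: float
    method: str
    k: int
    q: float = 0.0
    df: int = 0
    tau2: float | None = None
    dispersion: float | None = None
    alpha: float = 0.05
    ci_low: float | None = None
    ci_high: float | None = None
    z: float | None = None
    pvalue: float | None = None
    trait_type: str = "continuous"
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError("pooled se must be > 0")
        if self.q < -1e-12:
            raise ValidationError("Cochran's Q must be >= 0")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValidationError("tau2 must be >= 0")
        if self.dispersion is not None and self.dispersion < 1:
            raise ValidationError("dispersion is floored at 1")

    @property
    def q_pvalue(self) -> float | None:
        """Heterogeneity p-value from the chi-square(df) tail, if df >= 1."""
        if self.df < 1:
            return None
        return float(stats.chi2.sf(self.q, self.df))


def wald_ratio(
    pair: HarmonizedPair,
    se_method: str = "first_order",
    weak_z_threshold: float = WEAK_INSTRUMENT_Z,
) -> WaldEstimate:
    """Per-variant causal estimate: outcome beta over exposure beta.

    ``first_order`` SE is se_outcome/|beta_exposure|; ``second_order``
    additionally propagates the exposure association's uncertainty.
    A :class:`WeakInstrumentWarning` is emitted when the exposure
    association's z-score falls below ``weak_z_threshold``.
    """
    if not pair.retained:
        raise ValidationError(f"{pair.rsid}: cannot form a Wald ratio from a dropped pair")
    bx, sx = pair.beta_exposure, pair.se_exposure
    by, sy = pair.beta_outcome, pair.se_outcome
    if abs(bx) < ZERO_BETA_GUARD:
        raise UndefinedRatioError(
            f"{pair.rsid}: variant-exposure effect is zero; Wald ratio undefined"
        )
    if abs(bx) / sx < weak_z_threshold:
        warnings.warn(
            f"{pair.rsid}: weak instrument (|beta_x|/se_x = {abs(bx) / sx:.2f} "
            f"< {weak_z_threshold:g})",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    theta = by / bx
    if se_method == "first_order":
        se = sy / abs(bx)
    elif se_method == "second_order":
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise ValidationError(f"unknown se_method {se_method!r}")
    return WaldEstimate(rsid=pair.rsid, theta=theta, se_theta=se, se_method=se_method)


def _ivw_fixed_arrays(theta: np.ndarray, se: np.ndarray):
    """Vectorized fixed-effect IVW kernel shared by scalar and replicate paths.

    ``theta`` and ``se`` have shape (..., k); the reduction is over the
    trailing (variant) axis. Returns (beta, se_pooled, q).
    """
    theta = np.asarray(theta, dtype=float)
    w = 1.0 / np.square(np.asarray(se, dtype=float))
    sw = w.sum(axis=-1)
    beta = (w * theta).sum(axis=-1) / sw
    se_pooled = np.sqrt(1.0 / sw)
    q = (w * np.square(theta - np.asarray(beta)[..., None])).sum(axis=-1)
    return beta, se_pooled, q


def ivw_fixed(estimates: list[WaldEstimate], alpha: float = 0.05) -> MRResult:
    """Fixed-effect inverse-variance-weighted pooling of Wald ratios."""
    if not estimates:
        raise NoInstrumentsError("IVW pooling requires at least one Wald estimate")
    theta = np.array([e.theta for e in estimates])
    se = np.array([e.se_theta for e in estimates])
    beta, se_pooled, q = _ivw_fixed_arrays(theta, se)
    k = len(estimates)
    return finalize(
        MRResult(
            beta=float(beta),
            se=float(se_pooled),
            method="fixed",
            k=k,
            q=float(q),
            df=k - 1,
            alpha=alpha,
        )
    )


def ivw_random(
    estimates: list[WaldEstimate],
    flavor: str = "multiplicative",
    alpha: float = 0.05,
) -> MRResult:
    """Random-effects IVW pooling (multiplicative or additive DL flavor).

    With a single estimate the Wald ratio is returned unchanged, annotated
    with a note — there is no heterogeneity to model at k=1.
    """
    if flavor not in ("multiplicative", "additive_dl"):
        raise ValidationError(f"unknown random-effects flavor {flavor!r}")
    fixed = ivw_fixed(estimates, alpha=alpha)
    k = fixed.k
    if k == 1:
        return finalize(
            replace(
                fixed,
                method=f"random_{'multiplicative' if flavor == 'multiplicative' else 'additive'}",
                note="single instrument: random-effects pooling reduces to the Wald ratio",
            )
        )
    if flavor == "multiplicative":
        dispersion = max(1.0, fixed.q / (k - 1))
        return finalize(
            replace(
                fixed,
                se=fixed.se * math.sqrt(dispersion),
                method="random_multiplicative",
                dispersion=dispersion,
            )
        )
    # Additive DerSimonian-Laird: moment estimator of between-variant variance.
    theta = np.array([e.theta for e in estimates])
    se = np.array([e.se_theta for e in estimates])
    w = 1.0 / se**2
    sw = w.sum()
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (fixed.q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    beta = float((w_star * theta).sum() / w_star.sum())
    se_pooled = float(math.sqrt(1.0 / w_star.sum()))
    return finalize(
        MRResult(
            beta=beta,
            se=se_pooled,
            method="random_additive",
            k=k,
            q=fixed.q,
            df=k - 1,
            tau2=tau2,
            alpha=alpha,
        )
    )


def finalize(
    result: MRResult, trait_type: str | None = None, alpha: float | None = None
) -> MRResult:
    """Attach normal-theory CI, z, p — and the odds-ratio view for binary traits."""
    if alpha is None:
        alpha = result.alpha
    if trait_type is None:
        trait_type = result.trait_type
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    ci_low = result.beta - zcrit * result.se
    ci_high = result.beta + zcrit * result.se
    z = result.beta / result.se
    pvalue = float(2 * stats.norm.sf(abs(z)))
    updates = dict(
        alpha=alpha,
        trait_type=trait_type,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        pvalue=pvalue,
    )
    if trait_type == "binary":
        updates.update(
            or_=math.exp(result.beta),
            or_ci_low=math.exp(ci_low),
            or_ci_high=math.exp(ci_high),
        )
    return replace(result, **updates)


def run_mr(
    exposure_table: AssociationTable,
    outcome_table: AssociationTable,
    method: str = "random_multiplicative",
    se_method: str = "first_order",
    alpha: float = 0.05,
    trait_type: str | None = None,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
):
    """End-to-end two-sample MR: harmonize, Wald ratios, pool, finalize.

    Returns ``(MRResult, per_variant)`` where ``per_variant`` is a list of
    dicts recording, for every shared variant, the harmonization action
    and (when retained) its Wald estimate.

    ``method`` is one of ``fixed``, ``random_multiplicative``,
    ``random_dl``. ``trait_type`` defaults to the outcome table's records'
    type.
    """
    pairs, report = harmonize_tables(
        exposure_table,
        outcome_table,
        palindrome_policy=palindrome_policy,
        eaf_ambiguity_band=eaf_ambiguity_band,
    )
    if trait_type is None:
        types = {rec.trait_type for rec in outcome_table}
        trait_type = types.pop() if len(types) == 1 else "continuous"

    per_variant: list[dict] = []
    estimates: list[WaldEstimate] = []
    for pair in pairs:
        entry = {
            "rsid": pair.rsid,
            "action": pair.action,
            "drop_reason": pair.drop_reason,
            "beta_exposure": pair.beta_exposure,
            "se_exposure": pair.se_exposure,
            "beta_outcome": pair.beta_outcome,
            "se_outcome": pair.se_outcome,
            "theta": None,
            "se_theta": None,
        }
        if pair.retained:
            est = wald_ratio(pair, se_method=se_method)
            estimates.append(est)
            entry["theta"] = est.theta
            entry["se_theta"] = est.se_theta
        per_variant.append(entry)

    if not estimates:
        raise NoInstrumentsError(
            "no instruments retained after harmonization: " + str(report)
        )

    if method == "fixed":
        result = ivw_fixed(estimates, alpha=alpha)
    elif method == "random_multiplicative":
        result = ivw_random(estimates, flavor="multiplicative", alpha=alpha)
    elif method in ("random_dl", "random_additive"):
        result = ivw_random(estimates, flavor="additive_dl", alpha=alpha)
    else:
        raise ValidationError(f"unknown MR method {method!r}")
    result = finalize(result, trait_type=trait_type, alpha=alpha)
    return result, {"per_variant": per_variant, "harmonization": report}
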