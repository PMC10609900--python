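"""Synthetic data generators: summary-level MR, a metabolizer-compensation
cohort, and kidney phenotype derivations.

Three generators make every pipeline stage testable without downloading
consortium GWAS:

1. :func:`gen_summary_stats` draws two-sample summary statistics under the
   standard MR generative model — per-variant exposure effects beta_xj,
   a known causal effect theta, optional per-variant direct (pleiotropic)
   effects alpha_j, and sampling noise with single-SNP regression SEs
   se^2 ~ var(trait) / (2 f (1-f) n) — so estimator calibration and
   parameter recovery can be measured against known truth.

2. :func:`simulate_cohort` implements a mechanistic formalization of
   behavioral titration in caffeine consumers: genotype raises caffeine
   clearance, fast metabolizers drink more to reach the same stimulant
   effect, and steady-state plasma level is intake over clearance (a
   difference on the log scale). With compensation strength kappa, the
   same clearance-raising allele has effect delta*kappa on log intake but
   delta*(kappa-1) on log plasma — opposite signs for 0 < kappa < 1. MR
   analyses instrumenting plasma level versus intake then converge to
   different (sign-discordant) estimands, with closed forms given by
   :func:`expected_mr_estimates`. This reproduces, from an explicit
   mechanism, the qualitative discrepancy between plasma-caffeine and
   caffeine-intake MR estimates on kidney traits.

3. :func:`derive_phenotypes` applies the kidney-trait derivations used by
   the outcome GWAS: BUN = 2.8 x blood urea (mg/dL); UACR (mg/g) =
   100 x urinary albumin (mg/L) / urinary creatinine (mg/dL); eGFR
   winsorized to [15, 200] mL/min/1.73m^2 then natural-log transformed.

All generators run from a single master seed with deterministic
per-component substreams, so adding a component never perturbs earlier
draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .mr import _ivw_fixed_arrays
from .summary_stats import AssociationTable, VariantAssociation

__all__ = [
    "SummaryGenConfig",
    "CompensationConfig",
    "CohortSim",
    "gen_summary_stats",
    "simulate_ivw_replicates",
    "simulate_cohort",
    "cohort_gwas",
    "expected_mr_estimates",
    "MechanismExpectation",
    "run_mechanism_mr",
    "derive_phenotypes",
]

# fixed spawn keys for per-component RNG substreams
_COMPONENT_KEYS = {"summary": 1, "cohort": 2}


def _substream(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_COMPONENT_KEYS[component],))
    )


@dataclass(frozen=True)
class SummaryGenConfig:
    """Configuration of the summary-level two-sample MR generator.

    Defaults mirror the caffeine analyses: two cis-instruments with
    exposure effects and allele frequencies on the scale of the plasma
    caffeine / caffeine intake instruments, an exposure GWAS of 9876
    individuals (the plasma caffeine meta-analysis) and an outcome GWAS of
    one million (the creatinine eGFR meta-analysis), valid instruments
    (no direct effects), and a standardized (unit-variance) trait scale.
    """

    k: int = 2
    theta: float = 0.0
    beta_x_range: tuple[float, float] = (0.10, 0.15)
    n_exposure: int = 9876
    n_outcome: int = 1_000_000
    pleiotropy_sd: float = 0.0
    eaf_range: tuple[float, float] = (0.31, 0.73)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValidationError("sample sizes must be >= 2")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be >= 0")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("eaf_range must lie strictly inside (0, 1)")


def _draw_summary_arrays(config: SummaryGenConfig, rng: np.random.Generator, n_reps: int):
    """Draw the generative model's latents and observables.

    All arrays have shape (n_reps, k). The draw order (eaf, true exposure
    effects, pleiotropic effects, exposure noise, outcome noise) is fixed:
    single-table generation and vectorized replicate runs with the same
    substream produce bit-identical values.
    """
    shape = (n_reps, config.k)
    f = rng.uniform(*config.eaf_range, size=shape)
    beta_x_true = rng.uniform(*config.beta_x_range, size=shape)
    alpha = (
        rng.normal(0.0, config.pleiotropy_sd, size=shape)
        if config.pleiotropy_sd > 0
        else np.zeros(shape)
    )
    # single-SNP regression SE approximation, unit trait variance
    se_x = np.sqrt(1.0 / (2.0 * f * (1.0 - f) * config.n_exposure))
    se_y = np.sqrt(1.0 / (2.0 * f * (1.0 - f) * config.n_outcome))
    bx_obs = beta_x_true + rng.normal(0.0, 1.0, size=shape) * se_x
    by_obs = config.theta * beta_x_true + alpha + rng.normal(0.0, 1.0, size=shape) * se_y
    return {
        "f": f,
        "beta_x_true": beta_x_true,
        "alpha": alpha,
        "se_x": se_x,
        "se_y": se_y,
        "bx_obs": bx_obs,
        "by_obs": by_obs,
    }


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)


def gen_summary_stats(
    config: SummaryGenConfig,
) -> tuple[AssociationTable, AssociationTable, dict]:
    """Generate one pair of two-sample summary-statistics tables.

    Returns ``(exposure_table, outcome_table, truth)`` where ``truth``
    records theta and every latent (true exposure effects, pleiotropic
    effects, frequencies, SEs). Tables share rsids and allele orientation.
    """
    rng = _substream(config.seed, "summary")
    d = _draw_summary_arrays(config, rng, n_reps=1)
    f = d["f"][0]
    se_x, se_y = d["se_x"][0], d["se_y"][0]
    bx, by = d["bx_obs"][0], d["by_obs"][0]
    px = _pvalue(bx, se_x)
    py = _pvalue(by, se_y)

    exp_records, out_records = [], []
    for j in range(config.k):
        rsid = f"rs{1_000_001 + j}"
        common = dict(rsid=rsid, effect_allele="A", other_allele="G", eaf=float(f[j]))
        exp_records.append(
            VariantAssociation(
                beta=float(bx[j]),
                se=float(se_x[j]),
                pvalue=float(px[j]),
                n=config.n_exposure,
                trait_id="synthetic_exposure",
                gene_label=f"LOCUS{j + 1}",
                **common,
            )
        )
        out_records.append(
            VariantAssociation(
                beta=float(by[j]),
                se=float(se_y[j]),
                pvalue=float(py[j]),
                n=config.n_outcome,
                trait_id="synthetic_outcome",
                **common,
            )
        )
    truth = {
        "theta": config.theta,
        "beta_x_true": d["beta_x_true"][0].tolist(),
        "alpha": d["alpha"][0].tolist(),
        "eaf": f.tolist(),
        "se_x": se_x.tolist(),
        "se_y": se_y.tolist(),
        "seed": config.seed,
    }
    exposure = AssociationTable(
        exp_records, trait_id="synthetic_exposure", provenance="gen_summary_stats"
    )
    outcome = AssociationTable(
        out_records, trait_id="synthetic_outcome", provenance="gen_summary_stats"
    )
    return exposure, outcome, truth


def simulate_ivw_replicates(
    config: SummaryGenConfig, n_reps: int, se_method: str = "first_order"
) -> dict:
    """Vectorized Monte Carlo replicates of the generate-then-pool pipeline.

    Each replicate draws a fresh summary-statistics pair under ``config``,
    forms Wald ratios (``se_method``: ``first_order`` uses only the
    outcome-side SE; ``second_order`` also propagates the exposure-side
    sampling variance, which matters whenever theta != 0 and the exposure
    GWAS is not enormous), and pools them by fixed-effect IVW and by
    multiplicative random-effects IVW. Shares its arithmetic kernels
    with :func:`caffmr.mr.ivw_fixed` / :func:`caffmr.mr.ivw_random`, and
    its draw stream with :func:`gen_summary_stats` (replicate ``i`` of an
    ``n_reps`` run equals a single run with the same substream advanced
    identically — checked in the test suite).

    Returns arrays: ``beta_fixed``, ``se_fixed``, ``q``, ``se_random``
    (multiplicative), plus coverage indicators ``covered_fixed`` /
    ``covered_random`` of the true theta by the 95% CI.
    """
    if se_method not in ("first_order", "second_order"):
        raise ValidationError(f"unknown se_method {se_method!r}")
    rng = _substream(config.seed, "summary")
    d = _draw_summary_arrays(config, rng, n_reps=n_reps)
    theta_hat = d["by_obs"] / d["bx_obs"]
    if se_method == "first_order":
        se_theta = d["se_y"] / np.abs(d["bx_obs"])
    else:
        se_theta = np.sqrt(
            d["se_y"] ** 2 / d["bx_obs"] ** 2
            + d["by_obs"] ** 2 * d["se_x"] ** 2 / d["bx_obs"] ** 4
        )
    beta, se_fixed, q = _ivw_fixed_arrays(theta_hat, se_theta)
    dfree = max(config.k - 1, 1)
    dispersion = np.maximum(1.0, q / dfree) if config.k > 1 else np.ones_like(q)
    se_random = se_fixed * np.sqrt(dispersion)
    zcrit = float(stats.norm.ppf(0.975))
    covered_fixed = np.abs(beta - config.theta) <= zcrit * se_fixed
    covered_random = np.abs(beta - config.theta) <= zcrit * se_random
    return {
        "beta_fixed": beta,
        "se_fixed": se_fixed,
        "q": q,
        "se_random": se_random,
        "covered_fixed": covered_fixed,
        "covered_random": covered_random,
    }


class Locus(NamedTuple):
    """One clearance locus: effect-allele frequency and per-allele effect
    on log clearance."""

    eaf: float
    delta: float


@dataclass(frozen=True)
class CompensationConfig:
    """Configuration of the metabolizer-compensation cohort simulator.

    Defaults: two clearance loci at the caffeine instruments' allele
    frequencies (0.36, 0.73) with per-allele log-clearance effects 0.30
    and 0.25; half-strength behavioral compensation (kappa = 0.5); a
    harmful plasma effect (gamma_p = -0.2 per unit log plasma, on an
    outcome oriented so that negative means worse kidney function) and no
    direct intake effect; unit-scale noise.
    """

    n: int = 200_000
    loci: tuple[Locus, ...] = (Locus(0.36, 0.30), Locus(0.73, 0.25))
    kappa: float = 0.5
    gamma_p: float = -0.2
    gamma_i: float = 0.0
    mu: float = 1.0
    sd_c: float = 0.5
    sd_i: float = 0.5
    sd_y: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "loci", tuple(Locus(float(f), float(d)) for f, d in self.loci)
        )
        if not (0 <= self.kappa <= 1):
            raise ValidationError("kappa must lie in [0, 1]")
        for loc in self.loci:
            if not (0 < loc.eaf < 1):
                raise ValidationError("locus eaf must lie strictly in (0, 1)")
        if min(self.sd_c, self.sd_i, self.sd_y) <= 0:
            raise ValidationError("noise SDs must be > 0")
        if self.n < 2:
            raise ValidationError("cohort size must be >= 2")


@dataclass
class CohortSim:
    """A simulated cohort with its generating parameters retained.

    ``log_plasma = log_intake - log_clearance`` holds exactly row-wise:
    steady-state plasma level is intake over clearance.
    """

    genotypes: np.ndarray  # (n, L) dosages in {0, 1, 2}
    log_clearance: np.ndarray
    log_intake: np.ndarray
    log_plasma: np.ndarray
    outcome: np.ndarray
    config: CompensationConfig

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


def simulate_cohort(config: CompensationConfig) -> CohortSim:
    """Simulate genotype -> clearance -> titrated intake -> plasma -> outcome.

    Model (log scale throughout): clearance c = sum_l delta_l g_l + e_c;
    intake I = mu + kappa*c + e_I (fast metabolizers titrate intake up);
    plasma P = I - c; outcome Y = gamma_p*P + gamma_i*I + e_Y.
    """
    rng = _substream(config.seed, "cohort")
    n, L = config.n, len(config.loci)
    eafs = np.array([loc.eaf for loc in config.loci])
    deltas = np.array([loc.delta for loc in config.loci])
    genotypes = rng.binomial(2, eafs, size=(n, L)).astype(np.int8)
    log_clearance = genotypes @ deltas + rng.normal(0.0, config.sd_c, size=n)
    log_intake = config.mu + config.kappa * log_clearance + rng.normal(
        0.0, config.sd_i, size=n
    )
    log_plasma = log_intake - log_clearance
    outcome = (
        config.gamma_p * log_plasma
        + config.gamma_i * log_intake
        + rng.normal(0.0, config.sd_y, size=n)
    )
    return CohortSim(
        genotypes=genotypes,
        log_clearance=log_clearance,
        log_intake=log_intake,
        log_plasma=log_plasma,
        outcome=outcome,
        config=config,
    )


_COHORT_TRAITS = ("log_clearance", "log_intake", "log_plasma", "outcome")


def cohort_gwas(
    sim: CohortSim, trait: str, subsample: Sequence[int] | np.ndarray
) -> AssociationTable:
    """Per-locus simple regression of a cohort trait on allele dosage.

    Emulates a GWAS of the subsample: for each locus, OLS of the trait on
    dosage gives beta, SE, and p; EAF and n are taken from the subsample.
    Disjoint subsamples of one cohort emulate the two-sample design.
    Monomorphic loci are dropped (recorded on the returned table's
    ``dropped_loci`` attribute).
    """
    if trait not in _COHORT_TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {_COHORT_TRAITS}")
    idx = np.asarray(subsample, dtype=int)
    if idx.size == 0:
        raise ValidationError("subsample must be nonempty")
    y = getattr(sim, trait)[idx]
    g = sim.genotypes[idx].astype(float)
    n = idx.size

    records = []
    dropped: list[str] = []
    for l in range(sim.n_loci):
        rsid = f"rs_sim{l + 1}"
        gl = g[:, l]
        var_g = gl.var()
        if var_g == 0.0:
            dropped.append(rsid)
            continue
        beta = float(np.cov(gl, y, ddof=1)[0, 1] / gl.var(ddof=1))
        resid = y - y.mean() - beta * (gl - gl.mean())
        sigma2 = float(resid @ resid) / (n - 2)
        se = float(np.sqrt(sigma2 / (gl.var(ddof=1) * (n - 1))))
        p = float(max(2 * stats.norm.sf(abs(beta) / se), np.finfo(float).tiny))
        records.append(
            VariantAssociation(
                rsid=rsid,
                effect_allele="A",
                other_allele="G",
                beta=beta,
                se=se,
                pvalue=p,
                eaf=float(gl.mean() / 2.0),
                n=n,
                trait_id=trait,
                gene_label=f"LOCUS{l + 1}",
            )
        )
    table = AssociationTable(
        records, trait_id=trait, provenance=f"cohort_gwas(n={n}, trait={trait})"
    )
    table.dropped_loci = dropped  # type: ignore[attr-defined]
    return table


class MechanismExpectation(NamedTuple):
    """Closed-form large-sample MR estimands under the compensation model."""

    plasma_mr: float
    intake_mr: float


def expected_mr_estimates(config: CompensationConfig) -> MechanismExpectation:
    """Large-sample Wald-ratio estimands of the compensation model.

    A clearance allele with effect delta has genotype effects
    delta*(kappa-1) on log plasma, delta*kappa on log intake, and
    delta*(gamma_p*(kappa-1) + gamma_i*kappa) on the outcome, so the
    plasma-instrumented ratio converges to

        gamma_p + gamma_i * kappa/(kappa-1)

    and the intake-instrumented ratio to

        gamma_p * (kappa-1)/kappa + gamma_i,

    both independent of delta. At kappa = 1 the genotype no longer moves
    plasma (full compensation) and the plasma-instrumented ratio is
    undefined; at kappa = 0 likewise for intake. Undefined ratios are
    returned as NaN with a warning.
    """
    k, gp, gi = config.kappa, config.gamma_p, config.gamma_i
    if k == 1.0:
        warnings.warn(
            "kappa = 1: genotype effect on plasma is zero; plasma-instrumented "
            "MR is undefined (weak instrument)",
            UserWarning,
            stacklevel=2,
        )
        plasma = float("nan")
    else:
        plasma = gp + gi * k / (k - 1.0)
    if k == 0.0:
        warnings.warn(
            "kappa = 0: genotype effect on intake is zero; intake-instrumented "
            "MR is undefined (weak instrument)",
            UserWarning,
            stacklevel=2,
        )
        intake = float("nan")
    else:
        intake = gp * (k - 1.0) / k + gi
    return MechanismExpectation(plasma_mr=plasma, intake_mr=intake)


def run_mechanism_mr(config: CompensationConfig, method: str = "random_multiplicative"):
    """Simulate a cohort and run the two MR analyses the mechanism implies.

    The cohort is split into two disjoint halves: the exposure GWAS is run
    on the first half (for log plasma and log intake in turn) and the
    outcome GWAS on the second — emulating the two-sample design. Returns
    ``{"plasma": MRResult, "intake": MRResult, "expected":
    MechanismExpectation}``.
    """
    from .mr import run_mr

    sim = simulate_cohort(config)
    half = sim.n // 2
    first, second = np.arange(half), np.arange(half, sim.n)
    outcome_table = cohort_gwas(sim, "outcome", second)
    results = {}
    for label, trait in (("plasma", "log_plasma"), ("intake", "log_intake")):
        exposure_table = cohort_gwas(sim, trait, first)
        result, _ = run_mr(exposure_table, outcome_table, method=method)
        results[label] = result
    results["expected"] = expected_mr_estimates(config)
    return results


class DerivedPhenotypes(NamedTuple):
    bun: np.ndarray | float
    uacr: np.ndarray | float
    log_egfr_winsorized: np.ndarray | float


#: eGFR winsorization bounds, mL/min/1.73 m^2.
EGFR_BOUNDS = (15.0, 200.0)


def derive_phenotypes(urea_mgdl, albumin_mgL, creatinine_mgdl, egfr) -> DerivedPhenotypes:
    """Kidney phenotype derivations used by the outcome GWAS.

    BUN = 2.8 x blood urea (mg/dL); UACR (mg/g) = 100 x urinary albumin
    (mg/L) / urinary creatinine (mg/dL); eGFR winsorized to [15, 200]
    mL/min/1.73 m^2 then natural-log transformed. Inputs must be positive;
    scalars or arrays.
    """
    urea = np.asarray(urea_mgdl, dtype=float)
    alb = np.asarray(albumin_mgL, dtype=float)
    crea = np.asarray(creatinine_mgdl, dtype=float)
    gfr = np.asarray(egfr, dtype=float)
    for name, arr in (
        ("urea", urea),
        ("albumin", alb),
        ("creatinine", crea),
        ("egfr", gfr),
    ):
        if (arr <= 0).any():
            raise ValidationError(f"{name} values must be positive")
    bun = 2.8 * urea
    uacr = 100.0 * alb / crea
    log_egfr = np.log(np.clip(gfr, *EGFR_BOUNDS))
    if np.ndim(urea_mgdl) == 0 and np.ndim(egfr) == 0:
        return DerivedPhenotypes(float(bun), float(uacr), float(log_egfr))
    return DerivedPhenotypes(bun, uacr, log_egfr)
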