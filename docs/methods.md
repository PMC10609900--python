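# Methods

## Two-sample MR model

The package estimates the causal effect θ of an exposure X on an outcome Y
from two non-overlapping GWAS. For each instrument j, the exposure GWAS
supplies (β̂_xj, σ_xj) and the outcome GWAS (β̂_yj, σ_yj). Under the
instrumental-variable assumptions (relevance, independence, exclusion),
β_yj = θ·β_xj, so each variant yields a Wald ratio θ̂_j = β̂_yj/β̂_xj.

**Standard errors.** The default first-order SE, σ_yj/|β̂_xj|, treats the
exposure association as known — the convention for strong cis-instruments,
and exact when β̂_xj is measured without error. The second-order option
adds the exposure-side term by the delta method:
se² = σ_yj²/β̂_xj² + β̂_yj²σ_xj²/β̂_xj⁴. The distinction matters: in the
parameter-recovery experiment (θ = 0.5, exposure GWAS n = 50,000), the
exposure-side variance is a sizeable fraction of the ratio variance, and
first-order intervals undercover (~85% observed); the recovery experiment
therefore uses second-order SEs, which restore near-nominal coverage. For
null-calibration experiments (θ = 0) the first-order SE is essentially
exact because β̂_yj ≈ 0 kills the second term.

**Pooling.** Fixed-effect IVW with weights 1/se². Two random-effects
flavors are exposed because "random-effects IVW" is ambiguous at k = 2:

* *multiplicative* (default): fixed-effect point estimate, SE multiplied by
  √max(1, Q/(k−1)). The floor at 1 guarantees the random-effects SE never
  undercuts the fixed-effect SE.
* *additive DerSimonian–Laird*: τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), then
  re-weight by 1/(se² + τ²).

For k = 2 with equal SEs the two flavors coincide (provable; property-
tested). At k = 1 both reduce to the single Wald ratio, with a logged note.

**Inference.** CIs and p-values use the normal reference distribution
(α = 0.05 default), matching summary-data MR convention; heterogeneity
p comes from the χ²(k−1) tail of Cochran's Q. Binary outcomes (log-odds
betas) additionally expose exp(β̂) with exponentiated CI bounds as the
odds-ratio view. No multiple-testing adjustment is applied across
outcomes. Division guard: |β̂_x| < 10⁻¹² raises an undefined-ratio error;
|β̂_x|/σ_x < 3 emits a weak-instrument warning.

## Harmonization

Matching between sources is by rsid only. The outcome record is aligned to
the exposure's allele pair by letters: identical order → no action; swapped
→ outcome beta negated, EAF reflected (swap_flip); complementary-strand
matches → recoded (strand_flip, with or without swap). Palindromic variants
(A/T, C/G) cannot be strand-resolved from letters; the default policy
orients them by which side of 0.5 the two frequencies fall on, dropping the
variant when either EAF is missing or lies within 0.08 of 0.5. Policy
`drop` discards all palindromes. Incompatible allele sets are dropped with
reason `allele_mismatch`. Post-orientation frequency discrepancies
|EAF_exp − EAF_out| > 0.2 are warned about, never enforced — the caffeine
instruments themselves show cross-cohort EAF drift of a few percent.
Harmonization is involution-safe, and the Wald ratio is invariant to which
allele is labelled "effect" (both property-tested).

## Instrument selection

cis-instruments come from closed windows [start − w, end + w] around gene
regions (1-based inclusive coordinates; default w = 100 kb, the window used
for the *AHR* and *CYP1A2* loci). Pre-annotated tables pass through without
coordinates. Selection keeps variants with p ≤ 5×10⁻⁸ (genome-wide
significance — the conventional cutoff; the caffeine instruments clear it
by many orders of magnitude) and, per locus, the smallest p-value. Ties
break by larger |β|/se then lexicographic rsid, so the result is
independent of row order. With an LD matrix, additional variants are kept
greedily (ascending p) when r² < 0.1 against everything already kept;
without one, exactly one variant per locus survives. No proxy lookup is
attempted for instruments missing from the outcome GWAS; the gap is
reported.

## Summary-level generator

`gen_summary_stats` draws, per variant: EAF f ~ U(0.31, 0.73) and true
exposure effect β_x ~ U(0.10, 0.15) (both spanning the caffeine
instruments); observed β̂_x ~ N(β_x, σ_x²) and
β̂_y ~ N(θβ_x + α, σ_y²) with α ~ N(0, pleiotropy_sd²) (0 by default —
valid instruments); SEs follow the single-SNP regression approximation
σ² = 1/(2f(1−f)n) for a unit-variance trait. Default sample sizes are
9,876 (the plasma caffeine GWAS meta-analysis) and 1,000,000 (the scale of
the creatinine-eGFR outcome GWAS). The Monte Carlo experiments
(`simulate_ivw_replicates`) vectorize this generator across replicates
while sharing both the RNG stream and the IVW arithmetic kernels with the
single-table path — a unit test pins the two routes to bit-identical
output — so 10,000-replicate calibration runs take under a second.
Experiment sizes (10,000 replicates for null calibration, 1,000 for
recovery at n = 50,000/400,000) give binomial SEs of ~0.2% and ~0.8% on
coverage, small enough to detect miscalibration of a percentage point.

What this generator emulates: sampling noise, instrument strength, allele
frequencies, and the two-sample structure. What it does not: LD between
instruments, sample overlap, allele-frequency drift between cohorts,
winner's curse from instrument discovery, and non-collapsibility for
binary traits. Passing calibration here validates the estimator's
arithmetic and its sampling theory, not robustness to those real-data
complications.

## Metabolizer-compensation cohort

The cohort simulator formalizes the behavioral-titration mechanism as a
linear structural model on the log scale:

    clearance  c_i = Σ_l δ_l g_il + ε_c,           ε_c ~ N(0, sd_c²)
    intake     I_i = μ + κ·c_i + ε_I,              ε_I ~ N(0, sd_i²)
    plasma     P_i = I_i − c_i                      (steady state: plasma ∝ intake/clearance)
    outcome    Y_i = γ_p·P_i + γ_i·I_i + ε_Y,      ε_Y ~ N(0, sd_y²)

κ ∈ [0, 1] is the compensation strength: κ = 0 means intake ignores
clearance (genotype moves plasma only), κ = 1 means full titration
(genotype moves intake only, plasma is decoupled). A clearance allele with
effect δ therefore has genotype effects δ(κ−1) on log plasma, δκ on log
intake, and δ[γ_p(κ−1) + γ_iκ] on the outcome, giving the closed-form MR
estimands

    plasma-instrumented:  γ_p + γ_i·κ/(κ−1)
    intake-instrumented:  γ_p·(κ−1)/κ + γ_i

independent of δ. At κ = 0.5 with γ_i = 0 these are γ_p and −γ_p: the two
analyses disagree in sign even though a single mechanism generates the
data. The end-to-end experiment (n = 200,000 split into disjoint GWAS
halves, γ_p = −0.2, γ_i = 0, κ = 0.5) recovers both estimands within their
95% CIs.

Parameter defaults are the package's own choices where nothing pins them:
locus frequencies (0.36, 0.73) match the caffeine instruments; per-allele
clearance effects δ = (0.30, 0.25) give instrument strength comparable to
the real loci; μ = 1.0, sd_c = sd_i = 0.5, sd_y = 1.0 put heritable and
behavioral variation on comparable scales. κ is a free mechanism parameter,
not an estimate of real-world titration strength. The simulator is not a
pharmacokinetic model: no multi-compartment kinetics, no metabolite panel,
no intake measurement-error structure.

Kidney phenotype derivations follow the outcome GWAS definitions:
BUN = 2.8 × blood urea (mg/dL); UACR (mg/g) = 100 × urinary albumin
(mg/L) / urinary creatinine (mg/dL); eGFR winsorized to [15, 200]
mL/min/1.73 m² then natural-log transformed.

## Randomness contract

Every generator takes one master seed and derives per-component substreams
via `SeedSequence(seed, spawn_key=(component,))`, so adding a component
never perturbs earlier draws, and all outputs are bit-reproducible from
(seed, config). Seeds derived from a user seed stay below 2³¹.

## Published-results audit

A printed result "β [l, u]; p" is internally consistent under the normal
approximation when p = 2Φ(−|β|·2z₀.₉₇₅/(u−l)). Because printed values are
rounded, the audit perturbs each number by ±1 unit in its last printed
digit and propagates through the (monotone) map to get an admissible
p-interval; the printed p (itself rounded) must overlap it. Rows of the
packaged published-estimates table whose CIs are visibly garbled
(non-bracketing or grossly asymmetric bounds — presumably typesetting
errors) are flagged and excluded from the default audit rather than
treated as evidence.

## Known limitations

* Pleiotropy-robust estimators (MR-Egger, MR-PRESSO, weighted
  median/mode) are out of scope: they need ≥ 3 instruments, and the
  caffeine analyses have two.
* Correlated-instrument IVW with an LD covariance matrix is not
  implemented; LD enters only through selection-stage pruning.
* The first-order Wald SE understates uncertainty when the exposure GWAS
  is small relative to the effect being estimated (see above); use
  `se_method="second_order"` in that regime.
* No strand inference from reference panels; palindrome resolution relies
  on EAF and is conservative near 0.5.
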