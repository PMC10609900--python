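"""Allele harmonization between exposure and outcome summary statistics.

Two GWAS may report the same variant against opposite alleles: the caffeine
instrument rs4410790, for instance, is reported against T in the plasma
caffeine GWAS but against C in the caffeine-intake GWAS. Before a Wald
ratio can be formed, the exposure and outcome associations must refer to
the same effect allele. This module resolves:

* swapped effect/other alleles (negate the outcome beta, reflect the EAF);
* strand flips (the outcome GWAS reports the complementary strand);
* palindromic variants (A/T or C/G), where strand cannot be inferred from
  the alleles alone — resolved by allele-frequency comparison or dropped,
  per policy;
* incompatible allele sets, which are dropped with a reason.

Harmonization is an involution-safe, auditable transformation: harmonizing
an already-harmonized pair changes nothing, and every action and drop
reason is tallied in a :class:`HarmonizationReport`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .exceptions import HarmonizationError, ValidationError
from .summary_stats import AssociationTable, VariantAssociation

__all__ = [
    "HarmonizedPair",
    "HarmonizationReport",
    "normalize_variant",
    "harmonize_pair",
    "harmonize_tables",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = ({"A", "T"}, {"C", "G"})

#: Post-orientation |EAF difference| above which a cross-cohort frequency
#: discrepancy warning is recorded (cohorts legitimately drift; Table-scale
#: instruments show ~0.02-0.04 drift, so 0.2 flags only gross mismatches).
EAF_DISCREPANCY_THRESHOLD = 0.2


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations on a common effect allele.

    ``action`` records what was done to the outcome record: ``none``,
    ``swap_flip`` (alleles swapped: beta negated, EAF reflected),
    ``strand_flip`` (complementary-strand recode, beta unchanged),
    ``strand_flip_and_swap`` (both), or ``dropped`` (see ``drop_reason``).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    action: str
    drop_reason: str | None = None
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    def __post_init__(self) -> None:
        if self.action not in (
            "none",
            "swap_flip",
            "strand_flip",
            "strand_flip_and_swap",
            "dropped",
        ):
            raise ValidationError(f"unknown harmonization action {self.action!r}")
        if self.action == "dropped" and not self.drop_reason:
            raise ValidationError("dropped pair requires a drop_reason")
        if self.action != "dropped":
            if not (self.se_exposure > 0 and self.se_outcome > 0):
                raise ValidationError(f"{self.rsid}: retained pair requires positive SEs")

    @property
    def retained(self) -> bool:
        return self.action != "dropped"


def normalize_variant(assoc: VariantAssociation) -> VariantAssociation:
    """Uppercase alleles and re-validate; idempotent, order-preserving.

    VariantAssociation already uppercases on construction, so this is a
    re-validation pass-through that exists as the stable entry point for
    records built by other code paths.
    """
    return assoc.replace()


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMES


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
) -> HarmonizedPair:
    """Place one exposure/outcome pair on the exposure's effect allele.

    Parameters
    ----------
    palindrome_policy : {"infer_by_eaf", "drop"}
        For A/T and C/G variants strand is not inferable from alleles:
        ``drop`` discards them; ``infer_by_eaf`` orients by whether the two
        frequencies fall on the same side of 0.5, dropping when either lies
        within ``eaf_ambiguity_band`` of 0.5 (or is missing).
    eaf_ambiguity_band : float
        Half-width of the frequency window around 0.5 inside which a
        palindrome is considered unorientable.
    """
    if exposure.rsid != outcome.rsid:
        raise HarmonizationError(
            f"rsid mismatch: exposure {exposure.rsid} vs outcome {outcome.rsid}"
        )
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise HarmonizationError(f"unknown palindrome_policy {palindrome_policy!r}")

    exposure = normalize_variant(exposure)
    outcome = normalize_variant(outcome)
    e1, e2 = exposure.alleles
    o1, o2 = outcome.alleles

    def dropped(reason: str) -> HarmonizedPair:
        return HarmonizedPair(
            rsid=exposure.rsid,
            effect_allele=e1,
            other_allele=e2,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=outcome.beta,
            se_outcome=outcome.se,
            action="dropped",
            drop_reason=reason,
            eaf_exposure=exposure.eaf,
            eaf_outcome=outcome.eaf,
        )

    palindromic = _is_palindromic(e1, e2)

    # Step 1: align outcome alleles to the exposure's by letter.
    if (o1, o2) == (e1, e2):
        action = "none"
        beta_out, eaf_out = outcome.beta, outcome.eaf
    elif (o1, o2) == (e2, e1):
        action = "swap_flip"
        beta_out = -outcome.beta
        eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
    elif not palindromic and (_COMPLEMENT[o1], _COMPLEMENT[o2]) == (e1, e2):
        action = "strand_flip"
        beta_out, eaf_out = outcome.beta, outcome.eaf
    elif not palindromic and (_COMPLEMENT[o1], _COMPLEMENT[o2]) == (e2, e1):
        action = "strand_flip_and_swap"
        beta_out = -outcome.beta
        eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
    else:
        return dropped("allele_mismatch")

    # Step 2: palindromes — letter alignment cannot distinguish a swap from
    # a strand flip, so orientation must come from allele frequency.
    if palindromic:
        if palindrome_policy == "drop":
            return dropped("palindromic")
        if exposure.eaf is None or outcome.eaf is None:
            return dropped("palindromic_missing_eaf")
        if (
            abs(exposure.eaf - 0.5) <= eaf_ambiguity_band
            or abs(outcome.eaf - 0.5) <= eaf_ambiguity_band
        ):
            return dropped("palindromic_ambiguous_eaf")
        assert eaf_out is not None
        if (exposure.eaf - 0.5) * (eaf_out - 0.5) < 0:
            # Frequencies disagree after letter alignment: the outcome GWAS
            # reported the other strand. Recode: negate and reflect again.
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = "strand_flip" if action == "swap_flip" else "strand_flip_and_swap"

    return HarmonizedPair(
        rsid=exposure.rsid,
        effect_allele=e1,
        other_allele=e2,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        action=action,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
    )


@dataclass
class HarmonizationReport:
    """Audit trail for one harmonization run."""

    n_exposure: int = 0
    n_outcome: int = 0
    actions: Counter = field(default_factory=Counter)
    drop_reasons: Counter = field(default_factory=Counter)
    missing_from_outcome: list[str] = field(default_factory=list)
    eaf_discrepancies: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return sum(v for k, v in self.actions.items() if k != "dropped")

    def to_dict(self) -> dict:
        return {
            "n_exposure": self.n_exposure,
            "n_outcome": self.n_outcome,
            "n_retained": self.n_retained,
            "actions": dict(self.actions),
            "drop_reasons": dict(self.drop_reasons),
            "missing_from_outcome": list(self.missing_from_outcome),
            "eaf_discrepancies": list(self.eaf_discrepancies),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        lines = [
            f"harmonization: {self.n_retained}/{self.n_exposure} exposure "
            f"variants retained against {self.n_outcome} outcome variants"
        ]
        for action, count in sorted(self.actions.items()):
            lines.append(f"  action {action}: {count}")
        for reason, count in sorted(self.drop_reasons.items()):
            lines.append(f"  dropped ({reason}): {count}")
        if self.missing_from_outcome:
            lines.append(f"  missing from outcome: {', '.join(self.missing_from_outcome)}")
        for msg in self.eaf_discrepancies:
            lines.append(f"  EAF discrepancy: {msg}")
        return "\n".join(lines)


def harmonize_tables(
    exposure: AssociationTable,
    outcome: AssociationTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
) -> tuple[list[HarmonizedPair], HarmonizationReport]:
    """Harmonize every shared rsid; report actions, drops, and gaps.

    Instruments absent from the outcome table are reported as missing — no
    proxy or LD-surrogate search is attempted.
    """
    report = HarmonizationReport(n_exposure=len(exposure), n_outcome=len(outcome))
    pairs: list[HarmonizedPair] = []
    for exp_rec in exposure:
        if exp_rec.rsid not in outcome:
            report.missing_from_outcome.append(exp_rec.rsid)
            continue
        pair = harmonize_pair(
            exp_rec,
            outcome[exp_rec.rsid],
            palindrome_policy=palindrome_policy,
            eaf_ambiguity_band=eaf_ambiguity_band,
        )
        pairs.append(pair)
        report.actions[pair.action] += 1
        if pair.action == "dropped":
            report.drop_reasons[pair.drop_reason] += 1
        elif pair.eaf_exposure is not None and pair.eaf_outcome is not None:
            diff = abs(pair.eaf_exposure - pair.eaf_outcome)
            if diff > EAF_DISCREPANCY_THRESHOLD:
                report.eaf_discrepancies.append(
                    f"{pair.rsid}: |eaf_exposure - eaf_outcome| = {diff:.3f}"
                )
    return pairs, report
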