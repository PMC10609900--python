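"""GWAS summary-statistics data model and delimited-text I/O.

A :class:`VariantAssociation` is one variant's association with one trait:
the per-allele effect (``beta``) of the effect allele on the trait, its
standard error, two-sided p-value, and optionally the effect-allele
frequency (EAF) and sample size. An :class:`AssociationTable` is an ordered,
rsid-unique collection of such records for a single trait.

The canonical on-disk dialect is tab-separated text with the header
``rsid  effect_allele  other_allele  beta  se  pvalue  eaf  n`` (plus
optional ``gene_label``, ``chrom``, ``pos``, ``trait_type`` columns). Foreign
dialects — CKDGen or UK Biobank exports, for instance — are read through a
``column_map`` that renames their headers onto these fields, so no code
changes are needed per source.

The exposure instruments for the caffeine analyses (two variants per
exposure, at the *AHR* and *CYP1A2* loci) ship as packaged fixtures; see
:func:`load_table1_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "VariantAssociation",
    "AssociationTable",
    "RowError",
    "read_associations",
    "write_associations",
    "load_table1_fixture",
    "CANONICAL_COLUMNS",
]

_VALID_BASES = frozenset("ACGT")

#: Canonical column order for the TSV dialect.
CANONICAL_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
    "gene_label",
    "chrom",
    "pos",
    "trait_type",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    Parameters
    ----------
    rsid : str
        Variant identifier (matching between sources is by rsid only).
    effect_allele, other_allele : str
        Single bases in ``ACGT``; betas are per copy of the effect allele.
    beta : float
        Per-allele effect. For a continuous trait this is on the trait's
        GWAS scale (here, standardized exposure units); for a binary trait
        it is the per-allele log-odds.
    se : float
        Standard error of ``beta``; must be positive.
    pvalue : float
        Two-sided p-value in (0, 1].
    eaf : float, optional
        Effect-allele frequency in [0, 1].
    n : float, optional
        Sample size of the contributing GWAS.
    trait_id : str
        Trait the association refers to.
    trait_type : {"continuous", "binary"}
    gene_label : str, optional
        Gene/locus assignment (e.g. ``AHR``, ``CYP1A2``).
    chrom, pos : optional
        Genomic coordinates (1-based); metadata only, never used for
        matching.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    trait_id: str = ""
    trait_type: str = "continuous"
    gene_label: str | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in _VALID_BASES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a "
                "single base in ACGT (indels and multi-base alleles are rejected)"
            )
        if self.other_allele not in _VALID_BASES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} is not a "
                "single base in ACGT"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are equal")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite, got {self.beta}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(
                f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}"
            )
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(
                f"{self.rsid}: trait_type must be continuous|binary, got {self.trait_type!r}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)

    def replace(self, **changes) -> "VariantAssociation":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass
class AssociationTable:
    """Ordered, rsid-unique collection of variant associations for one trait."""

    records: list[VariantAssociation] = field(default_factory=list)
    trait_id: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValidationError(f"duplicate rsid in table: {rec.rsid}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def __getitem__(self, rsid: str) -> VariantAssociation:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        raise KeyError(rsid)

    def __contains__(self, rsid: str) -> bool:
        return any(rec.rsid == rsid for rec in self.records)

    @property
    def rsids(self) -> list[str]:
        return [rec.rsid for rec in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        """Render as a DataFrame in canonical column order."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "rsid": rec.rsid,
                    "effect_allele": rec.effect_allele,
                    "other_allele": rec.other_allele,
                    "beta": rec.beta,
                    "se": rec.se,
                    "pvalue": rec.pvalue,
                    "eaf": rec.eaf,
                    "n": rec.n,
                    "gene_label": rec.gene_label,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "trait_type": rec.trait_type,
                }
            )
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class RowError:
    """Diagnostic for a rejected input row."""

    row: int
    rsid: str
    message: str


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_associations(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    trait_id: str = "",
    trait_type: str = "continuous",
    strict: bool = False,
    provenance: str | None = None,
) -> AssociationTable:
    """Read a delimited summary-statistics file into an AssociationTable.

    ``column_map`` maps canonical field names to the file's header names,
    e.g. ``{"rsid": "MarkerName", "beta": "Effect"}``; unmapped canonical
    names are looked up verbatim. Rows failing validation are collected as
    :class:`RowError` diagnostics on the returned table's ``row_errors``
    attribute; with ``strict=True`` the first bad row aborts the read.
    """
    column_map = dict(column_map or {})

    def col(name: str) -> str:
        return column_map.get(name, name)

    try:
        df = pd.read_csv(
            path, sep=delimiter, dtype={col("rsid"): str}, float_precision="round_trip"
        )
    except FileNotFoundError:
        raise ConfigurationError(f"summary-statistics file not found: {path}") from None

    required = ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    for name in required:
        if col(name) not in df.columns:
            raise ConfigurationError(
                f"mapped column {col(name)!r} (field {name!r}) absent from header "
                f"{list(df.columns)}"
            )

    records: list[VariantAssociation] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        rsid = str(row[col("rsid")])
        try:
            rec = VariantAssociation(
                rsid=rsid,
                effect_allele=str(row[col("effect_allele")]),
                other_allele=str(row[col("other_allele")]),
                beta=float(row[col("beta")]),
                se=float(row[col("se")]),
                pvalue=float(row[col("pvalue")]),
                eaf=_parse_optional_float(row[col("eaf")]) if col("eaf") in df.columns else None,
                n=_parse_optional_float(row[col("n")]) if col("n") in df.columns else None,
                trait_id=trait_id,
                trait_type=str(row[col("trait_type")])
                if col("trait_type") in df.columns
                else trait_type,
                gene_label=_opt_str(row, col("gene_label"), df.columns),
                chrom=_opt_str(row, col("chrom"), df.columns),
                pos=_opt_int(row, col("pos"), df.columns),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            err = RowError(row=int(i), rsid=rsid, message=str(exc))
            if strict:
                raise ValidationError(f"row {err.row} ({err.rsid}): {err.message}") from None
            errors.append(err)
            continue
        records.append(rec)

    table = AssociationTable(
        records=records,
        trait_id=trait_id,
        provenance=provenance if provenance is not None else str(path),
    )
    table.row_errors = errors  # type: ignore[attr-defined]
    return table


def _opt_str(row, name: str, columns) -> str | None:
    if name not in columns:
        return None
    v = row[name]
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
        return None
    return str(v)


def _opt_int(row, name: str, columns) -> int | None:
    v = _opt_str(row, name, columns)
    return None if v is None else int(float(v))


def write_associations(table: AssociationTable, path) -> None:
    """Write an AssociationTable as canonical tab-separated text.

    ``read_associations(write_associations(t))`` reproduces every populated
    field; missing optional values are written as empty fields. Floats are
    written with ``repr`` precision so round-trips are lossless.
    """
    df = table.to_dataframe()
    # repr-format floats so round-trips are bit-faithful
    for c in ("beta", "se", "pvalue", "eaf", "n"):
        df[c] = df[c].map(lambda v: "" if v is None or pd.isna(v) else repr(float(v)))
    df["pos"] = df["pos"].map(lambda v: "" if v is None or pd.isna(v) else str(int(v)))
    for c in ("gene_label", "chrom"):
        df[c] = df[c].map(lambda v: "" if v is None or pd.isna(v) else str(v))
    df.to_csv(path, sep="\t", index=False)


_FIXTURE_FILES = {
    "plasma_caffeine": "plasma_caffeine_instruments.tsv",
    "caffeine_intake": "caffeine_intake_instruments.tsv",
}


def load_table1_fixture(exposure: str) -> AssociationTable:
    """Load the packaged instrument table for one caffeine exposure.

    ``plasma_caffeine`` returns rs4410790 (*AHR*) and rs2472297 (*CYP1A2*);
    ``caffeine_intake`` returns rs4410790 (*AHR*) and rs2470893 (*CYP1A2*).
    Note rs4410790's effect allele differs between the two exposure GWAS
    (T for plasma caffeine, C for caffeine intake) — downstream
    harmonization must resolve this.
    """
    try:
        fname = _FIXTURE_FILES[exposure]
    except KeyError:
        raise ConfigurationError(
            f"unknown exposure {exposure!r}; expected one of {sorted(_FIXTURE_FILES)}"
        ) from None
    with resources.as_file(resources.files("caffmr.data").joinpath(fname)) as p:
        table = read_associations(
            p,
            trait_id=exposure,
            provenance=f"packaged instrument table: {exposure}",
        )
    return table
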