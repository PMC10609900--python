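"""cis-instrument selection: gene-region windows and strongest-signal-per-locus.

Instruments for a molecular exposure are drawn from windows around genes
with a known mechanistic link — here *CYP1A2* (the enzyme metabolizing
>95% of caffeine) and *AHR* (its transcriptional regulator), each with a
100 kb flank. Within a locus, candidate SNPs are typically in linkage
disequilibrium, so selection keeps the strongest association signal per
locus; an optional LD matrix allows additional, approximately independent
variants to be retained (greedy by ascending p-value, capped at a pairwise
r-squared threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AmbiguousLocusError, NoInstrumentsError, ValidationError
from .summary_stats import AssociationTable, VariantAssociation

__all__ = ["GeneRegion", "LDMatrix", "assign_loci", "select_instruments"]

#: Genome-wide significance, the conventional instrument inclusion cutoff.
GENOME_WIDE_P = 5e-8

#: Default flanking window around a gene region, in bases.
DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class GeneRegion:
    """A gene region with a symmetric flanking window (1-based, inclusive)."""

    gene_label: str
    chrom: str
    start: int
    end: int
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_label}: start > end")
        if self.window < 0:
            raise ValidationError(f"{self.gene_label}: window must be >= 0")

    def contains(self, chrom: str, pos: int) -> bool:
        """True when ``pos`` falls in the closed window [start-window, end+window]."""
        return (
            str(chrom) == self.chrom
            and self.start - self.window <= pos <= self.end + self.window
        )


class LDMatrix:
    """Symmetric matrix of squared allelic correlations between variants."""

    def __init__(self, rsids: list[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(rsids), len(rsids)):
            raise ValidationError("LD matrix shape does not match rsid count")
        if not np.allclose(r2, r2.T):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValidationError("LD matrix diagonal must be exactly 1")
        if (r2 < 0).any() or (r2 > 1 + 1e-12).any():
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        self.rsids = list(rsids)
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}
        if len(self._index) != len(self.rsids):
            raise ValidationError("duplicate rsid in LD matrix")
        self.r2 = r2

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, a: str, b: str) -> float:
        """r2 between two variants; raises KeyError for unknown rsids."""
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        """Read a square TSV with rsids as both header row and first column."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError("LD matrix row and column rsids differ")
        return cls(list(df.columns), df.to_numpy())


def assign_loci(
    table: AssociationTable, regions: list[GeneRegion]
) -> AssociationTable:
    """Label each variant with the gene region whose window contains it.

    Variants already carrying a ``gene_label`` but no coordinates pass
    through unchanged (pre-annotated tables). Variants with coordinates are
    assigned by position; a variant inside two windows is an error (the
    caffeine loci sit on different chromosomes, so overlap signals a
    misconfiguration). Unassigned variants get ``gene_label=None``.
    """
    records: list[VariantAssociation] = []
    for rec in table:
        if rec.pos is None or rec.chrom is None:
            if rec.gene_label is not None:
                records.append(rec)
                continue
            raise ValidationError(
                f"{rec.rsid}: no coordinates and no pre-assigned gene_label"
            )
        hits = [r for r in regions if r.contains(rec.chrom, rec.pos)]
        if len(hits) > 1:
            raise AmbiguousLocusError(
                f"{rec.rsid} falls in overlapping windows: "
                + ", ".join(r.gene_label for r in hits)
            )
        records.append(rec.replace(gene_label=hits[0].gene_label if hits else None))
    return AssociationTable(
        records=records, trait_id=table.trait_id, provenance=table.provenance
    )


def _selection_key(rec: VariantAssociation) -> tuple:
    # Order-free, deterministic: p ascending, then instrument strength
    # |beta|/se descending, then rsid lexicographic.
    return (rec.pvalue, -abs(rec.beta) / rec.se, rec.rsid)


def select_instruments(
    table: AssociationTable,
    p_threshold: float = GENOME_WIDE_P,
    ld: LDMatrix | None = None,
    r2_max: float = 0.1,
) -> AssociationTable:
    """Keep the strongest signal per locus, optionally LD-pruning for extras.

    Variants with ``pvalue > p_threshold`` are discarded. Within each locus
    (``gene_label``) the variant with smallest p-value is kept; when an LD
    matrix is supplied, further variants are retained greedily (ascending
    p) if their r-squared with every already-kept variant in the locus is
    below ``r2_max``. Without an LD matrix, exactly one variant per locus
    survives. Input row order never affects the result.
    """
    candidates = [
        rec
        for rec in table
        if rec.gene_label is not None and rec.pvalue <= p_threshold
    ]

    by_locus: dict[str, list[VariantAssociation]] = {}
    for rec in candidates:
        by_locus.setdefault(rec.gene_label, []).append(rec)

    kept: list[VariantAssociation] = []
    for locus in sorted(by_locus):
        ranked = sorted(by_locus[locus], key=_selection_key)
        locus_kept = [ranked[0]]
        if ld is not None:
            for rec in ranked[1:]:
                if rec.rsid not in ld:
                    continue
                if all(
                    k.rsid in ld and ld.get(rec.rsid, k.rsid) < r2_max
                    for k in locus_kept
                ):
                    locus_kept.append(rec)
        kept.extend(locus_kept)

    if not kept:
        raise NoInstrumentsError(
            f"no variants pass p <= {p_threshold:g} with a locus assignment"
        )

    # Preserve the input table's record order for the survivors.
    kept_ids = {rec.rsid for rec in kept}
    ordered = [rec for rec in table if rec.rsid in kept_ids]
    return AssociationTable(
        records=ordered, trait_id=table.trait_id, provenance=table.provenance
    )
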