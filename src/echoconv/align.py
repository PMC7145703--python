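"""Codon and protein multiple alignments, translation and hygiene filters.

Site coordinates are 1-based codon positions throughout, so a codon column
index equals the amino-acid site index reported downstream. Filtering
returns an original->filtered coordinate map so sites stay reportable in
original coordinates after gapped columns are removed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from echoconv.codons import (
    AMBIG_AA,
    AMINO_ACIDS,
    GAP_AA,
    STOP_CODONS,
    codons_of,
    translate_codon,
)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon alignment: equal-length nucleotide rows, len % 3 == 0."""

    gene_id: str
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"rows of unequal length in {self.gene_id}: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise AlignmentError(
                f"alignment length {next(iter(lengths))} of {self.gene_id} not divisible by 3"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def codon_rows(self) -> list[list[str]]:
        return [codons_of(s) for s in self.sequences]

    def codon_column(self, site: int) -> tuple[str, ...]:
        """Codon column at 1-based site."""
        i = 3 * (site - 1)
        return tuple(s[i:i + 3] for s in self.sequences)


@dataclass(frozen=True)
class ProteinAlignment:
    """An amino-acid alignment over the 20 states plus gap '-' / ambiguity 'X'."""

    gene_id: str
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    _VALID = frozenset(AMINO_ACIDS + GAP_AA + AMBIG_AA)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in number")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"rows of unequal length in {self.gene_id}")
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - self._VALID
            if bad:
                raise AlignmentError(
                    f"invalid residue symbol(s) {sorted(bad)} in {self.gene_id}/{taxon}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def column(self, site: int) -> tuple[str, ...]:
        """Residue column at 1-based site."""
        return tuple(s[site - 1] for s in self.sequences)


def translate(aln: CodonAlignment, code: str = "standard") -> ProteinAlignment:
    """Translate a codon alignment column-by-column under the standard code.

    Gap codons '---' map to '-', 'NNN' to 'X'. Any stop codon in frame is an
    error naming the taxon and 1-based codon position; mixed-gap or otherwise
    unrecognised triplets are errors too (never silently treated as missing).
    """
    if code != "standard":
        raise ValueError(f"unsupported genetic code {code!r}")
    rows = []
    for taxon, seq in zip(aln.taxa, aln.sequences):
        out = []
        for pos, codon in enumerate(codons_of(seq), start=1):
            if codon in STOP_CODONS:
                raise AlignmentError(
                    f"stop codon {codon} in {aln.gene_id}/{taxon} at codon {pos}"
                )
            try:
                out.append(translate_codon(codon))
            except KeyError:
                raise AlignmentError(
                    f"unrecognised codon {codon!r} in {aln.gene_id}/{taxon} at codon {pos}"
                ) from None
        rows.append("".join(out))
    return ProteinAlignment(gene_id=aln.gene_id, taxa=aln.taxa, sequences=tuple(rows))


@dataclass(frozen=True)
class FilterPolicy:
    """Column/length hygiene: drop codon columns containing any symbol in
    ``drop_columns_with`` (in any taxon), then flag genes shorter than
    ``min_cds_nt`` nucleotides as discarded."""

    min_cds_nt: int = 150
    drop_columns_with: frozenset[str] = frozenset({"-", "N"})


@dataclass(frozen=True)
class FilteredAlignment:
    """Filter output: the filtered alignment plus the coordinate map.

    ``kept_sites`` lists, for each filtered codon column (in order), its
    original 1-based coordinate; ``original_site(k)`` maps a 1-based filtered
    site back to original coordinates.
    """

    alignment: CodonAlignment
    kept_sites: tuple[int, ...]
    discarded: bool
    original_length_nt: int

    @property
    def filtered_length_nt(self) -> int:
        return self.alignment.length_nt

    def original_site(self, filtered_site: int) -> int:
        return self.kept_sites[filtered_site - 1]


def filter_alignment(aln: CodonAlignment, policy: FilterPolicy = FilterPolicy()) -> FilteredAlignment:
    """Apply the codon-column filter and the minimum-CDS-length rule."""
    drop = policy.drop_columns_with
    codon_rows = aln.codon_rows()
    kept: list[int] = []
    for site in range(1, aln.n_codons + 1):
        column = (row[site - 1] for row in codon_rows)
        if not any(set(codon) & drop for codon in column):
            kept.append(site)
    new_rows = tuple(
        "".join(row[s - 1] for s in kept) for row in codon_rows
    )
    filtered = CodonAlignment(gene_id=aln.gene_id, taxa=aln.taxa, sequences=new_rows)
    return FilteredAlignment(
        alignment=filtered,
        kept_sites=tuple(kept),
        discarded=filtered.length_nt < policy.min_cds_nt,
        original_length_nt=aln.length_nt,
    )


# -- FASTA I/O -----------------------------------------------------------

def read_codon_fasta(path: str, gene_id: str | None = None) -> CodonAlignment:
    """Read one gene's codon alignment from FASTA; gene id from filename."""
    records = list(SeqIO.parse(path, "fasta"))
    if gene_id is None:
        gene_id = os.path.splitext(os.path.basename(path))[0]
    return CodonAlignment(
        gene_id=gene_id,
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq).upper() for r in records),
    )


def write_fasta(aln: CodonAlignment | ProteinAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def filter_report_rows(results: Iterable[FilteredAlignment]) -> list[dict]:
    """TSV-ready filter report: gene, original/filtered length, discarded."""
    return [
        {
            "gene": r.alignment.gene_id,
            "original_length_nt": r.original_length_nt,
            "filtered_length_nt": r.filtered_length_nt,
            "discarded_flag": int(r.discarded),
        }
        for r in results
    ]
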