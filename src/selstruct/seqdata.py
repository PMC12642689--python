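"""Coding-sequence alignments, trees, and dataset-inclusion QC.

The central container is :class:`CodonAlignment`: equal-length in-frame
nucleotide sequences over ``{A, C, G, T, -}`` in which gaps occur only as
whole-codon ``---`` triplets and no non-gap codon is a stop.  All internal
coordinates are 0-based; user-facing reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from selstruct._codes import get_code, translate_cds

GAP_CODON = "---"


class AlignmentError(ValueError):
    """A coding alignment violates a frame, stop or shape invariant."""


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences on a shared codon coordinate system.

    Parameters
    ----------
    taxa
        Ordered, unique sequence identifiers.
    sequences
        Per-taxon nucleotide strings over ``{A, C, G, T, -}``; all the same
        length, divisible by 3.
    genetic_code
        NCBI translation-table id (1 = standard; the default).
    """

    taxa: list[str]
    sequences: list[str]
    genetic_code: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa / sequence count mismatch")
        if len(self.taxa) < 2:
            raise AlignmentError("alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate identifiers: {dup}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise AlignmentError(f"alignment length {length} not divisible by 3")
        code = get_code(self.genetic_code)
        allowed = set("ACGT-")
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - allowed
            if bad:
                raise AlignmentError(f"{taxon}: illegal characters {sorted(bad)}")
            for col in range(length // 3):
                codon = seq[3 * col : 3 * col + 3]
                if "-" in codon:
                    if codon != GAP_CODON:
                        raise AlignmentError(
                            f"{taxon}: frame-breaking gap in codon {col + 1}"
                        )
                elif code.is_stop(codon):
                    raise AlignmentError(
                        f"{taxon}: in-frame stop {codon} at codon {col + 1}"
                    )

    # -- basic queries -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def site_count(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, taxon_index: int, site: int) -> str:
        return self.sequences[taxon_index][3 * site : 3 * site + 3]

    def codon_column(self, site: int) -> list[str]:
        return [self.codon(i, site) for i in range(self.n_taxa)]

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonAlignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.sequences == other.sequences
            and self.genetic_code == other.genetic_code
        )


# ---------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------

def read_codon_fasta(path: str | Path, genetic_code: int = 1) -> CodonAlignment:
    """Read and validate an in-frame codon alignment from FASTA.

    Record order is preserved.  Frame violations, in-frame stops,
    duplicate identifiers and ragged lengths raise :class:`AlignmentError`
    naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return CodonAlignment(taxa, seqs, genetic_code=genetic_code)


def write_codon_fasta(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------
# Codon-guided back-translation
# ---------------------------------------------------------------------

def backtranslate(
    protein_alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    cds: Mapping[str, str],
    genetic_code: int = 1,
) -> CodonAlignment:
    """Thread unaligned CDSs through an amino-acid alignment.

    Each amino-acid column becomes one codon column; protein gaps become
    ``---``.  Every protein record must translate exactly from its paired
    CDS (terminal stop codons are stripped); a mismatch at residue *k*
    raises an error citing the taxon and 1-based position.
    """
    items = list(protein_alignment.items()) if isinstance(protein_alignment, Mapping) else list(protein_alignment)
    taxa: list[str] = []
    rows: list[str] = []
    for taxon, prot in items:
        if taxon not in cds:
            raise AlignmentError(f"no CDS provided for {taxon}")
        nt = cds[taxon].upper().replace("-", "")
        if len(nt) % 3:
            raise AlignmentError(f"{taxon}: CDS length not divisible by 3")
        translated = translate_cds(nt, genetic_code)
        if translated.endswith("*"):
            translated = translated[:-1]
            nt = nt[:-3]
        residues = prot.replace("-", "")
        if len(residues) != len(translated):
            raise AlignmentError(
                f"{taxon}: protein has {len(residues)} residues but CDS "
                f"translates to {len(translated)}"
            )
        codons = []
        k = 0
        for pos, aa in enumerate(prot):
            if aa == "-":
                codons.append(GAP_CODON)
                continue
            if translated[k] != aa.upper():
                raise AlignmentError(
                    f"{taxon}: translation mismatch at residue {k + 1} "
                    f"(protein {aa!r}, CDS encodes {translated[k]!r}, "
                    f"alignment column {pos + 1})"
                )
            codons.append(nt[3 * k : 3 * k + 3])
            k += 1
        taxa.append(taxon)
        rows.append("".join(codons))
    return CodonAlignment(taxa, rows, genetic_code=genetic_code)


# ---------------------------------------------------------------------
# Dataset-inclusion QC and gap handling
# ---------------------------------------------------------------------

@dataclass
class Exclusion:
    name: str
    reason: str


def qc_filter(
    alignments: Mapping[str, CodonAlignment], min_taxa: int = 5
) -> tuple[dict[str, CodonAlignment], list[Exclusion]]:
    """Exclude genes with fewer than ``min_taxa`` homologous sequences.

    Mirrors the dataset-inclusion rule used for robust site-model fitting:
    parameter estimation is unreliable below a handful of sequences.
    """
    kept: dict[str, CodonAlignment] = {}
    excluded: list[Exclusion] = []
    for name, aln in alignments.items():
        if aln.n_taxa < min_taxa:
            excluded.append(
                Exclusion(name, f"{aln.n_taxa} taxa < required {min_taxa}")
            )
        else:
            kept[name] = aln
    return kept, excluded


def write_exclusion_report(excluded: Iterable[Exclusion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\treason\n")
        for e in excluded:
            fh.write(f"{e.name}\t{e.reason}\n")


def strip_gapped_columns(
    aln: CodonAlignment, max_gap_fraction: float = 0.5
) -> tuple[CodonAlignment, dict[int, int]]:
    """Drop codon columns whose gap fraction exceeds ``max_gap_fraction``.

    A deterministic surrogate for manual alignment curation.  All-gap
    columns are always removed (they carry no signal).  Returns the
    filtered alignment and an old->new 0-based column map for coordinate
    bookkeeping.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n = aln.n_taxa
    keep: list[int] = []
    for col in range(aln.site_count):
        gaps = sum(1 for c in aln.codon_column(col) if c == GAP_CODON)
        if gaps < n and gaps / n <= max_gap_fraction:
            keep.append(col)
    if not keep:
        raise AlignmentError("gap filter removed every column")
    column_map = {old: new for new, old in enumerate(keep)}
    seqs = [
        "".join(seq[3 * col : 3 * col + 3] for col in keep)
        for seq in aln.sequences
    ]
    return CodonAlignment(list(aln.taxa), seqs, genetic_code=aln.genetic_code), column_map
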