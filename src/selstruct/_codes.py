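"""Genetic-code bookkeeping shared by the codon model and MK counting.

Sense codons are indexed 0..n-1 in lexicographic TCAG-free (plain ACGT)
order with stop codons removed; 61 sense codons for the standard code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

#: purine/pyrimidine classes; a transition stays within a class
_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


@dataclass(frozen=True)
class GeneticCode:
    """Sense-codon index for one NCBI translation table."""

    table_id: int
    codons: tuple[str, ...]
    aa: tuple[str, ...]
    stop_codons: frozenset[str]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def translate_codon(self, codon: str) -> str:
        if codon in self.stop_codons:
            return "*"
        return self.aa[self.index[codon]]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        a + b + c
        for a in NUCS
        for b in NUCS
        for c in NUCS
        if a + b + c not in stops
    )
    aa = tuple(table.forward_table[c] for c in codons)
    code = GeneticCode(
        table_id=table_id,
        codons=codons,
        aa=aa,
        stop_codons=stops,
        index={c: i for i, c in enumerate(codons)},
    )
    return code


@lru_cache(maxsize=None)
def single_step_table(table_id: int = 1):
    """Precompute the single-nucleotide neighbour graph over sense codons.

    Returns (pairs, kind) where pairs is an (m, 2) int array of codon-index
    pairs differing at exactly one position and kind is an (m,) int array
    encoding 0 syn transversion, 1 syn transition, 2 nonsyn transversion,
    3 nonsyn transition.
    """
    code = get_code(table_id)
    pairs = []
    kinds = []
    for i, ci in enumerate(code.codons):
        for j, cj in enumerate(code.codons):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ts = is_transition(ci[k], cj[k])
            syn = code.aa[i] == code.aa[j]
            kinds.append((0 if syn else 2) + (1 if ts else 0))
            pairs.append((i, j))
    return np.asarray(pairs, dtype=np.intp), np.asarray(kinds, dtype=np.intp)


def translate_cds(seq: str, table_id: int = 1) -> str:
    """Translate an in-frame, gap-free CDS; stops become '*'."""
    code = get_code(table_id)
    if len(seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(
        code.translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)
    )
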