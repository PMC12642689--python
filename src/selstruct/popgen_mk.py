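"""McDonald–Kreitman counting and the direction-of-selection statistic.

From a population sample of in-frame haplotypes plus a single aligned
outgroup sequence, each codon column contributes nucleotide changes to
one of four bins: nonsynonymous/synonymous polymorphism (PN, PS; variants
segregating within the ingroup) or divergence (DN, DS; positions at which
every ingroup allele differs from the outgroup).  The 2x2 contingency of
those counts is the MK test; the direction of selection summarizes it as

    DoS = DN/(DN+DS) - PN/(PN+PS),

positive for an adaptive excess of nonsynonymous divergence, negative for
segregating slightly-deleterious variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from selstruct._codes import get_code
from selstruct.seqdata import CodonAlignment, GAP_CODON


@dataclass
class MKCounts:
    """MK site counts; fractional values arise from averaging over
    minimal mutational paths at multi-hit codons."""

    DN: float = 0.0
    DS: float = 0.0
    PN: float = 0.0
    PS: float = 0.0
    n_codons_used: int = 0
    n_codons_skipped: int = 0
    skip_reasons: dict = field(default_factory=dict)

    def as_table(self) -> np.ndarray:
        return np.array([[self.DN, self.DS], [self.PN, self.PS]])


def _consensus(codons: list[str]) -> str:
    """Majority nucleotide per position; ties broken alphabetically."""
    out = []
    for p in range(3):
        col = [c[p] for c in codons]
        counts = {}
        for nt in col:
            counts[nt] = counts.get(nt, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append(best[0])
    return "".join(out)


def _path_average(start: str, end: str, positions: list[int], code) -> tuple[float, float] | None:
    """Average (nonsyn, syn) step counts over minimal stop-free paths.

    Paths apply the position changes in every order; any path passing
    through a stop codon is excluded.  Returns None when all paths are
    blocked by stops.
    """
    totals = []
    for order in permutations(positions):
        cur = start
        steps = []
        ok = True
        for p in order:
            nxt = cur[:p] + end[p] + cur[p + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            steps.append(
                (0.0, 1.0)
                if code.translate_codon(cur) == code.translate_codon(nxt)
                else (1.0, 0.0)
            )
            cur = nxt
        if ok:
            totals.append(
                (sum(s[0] for s in steps), sum(s[1] for s in steps))
            )
    if not totals:
        return None
    n = len(totals)
    return (
        sum(t[0] for t in totals) / n,
        sum(t[1] for t in totals) / n,
    )


def mk_counts(population: CodonAlignment, outgroup: str) -> MKCounts:
    """Count MK polymorphism and divergence per codon column.

    Polarization: segregating positions always count as polymorphism; a
    position counts as divergence only when every ingroup allele differs
    from the outgroup and the ingroup is monomorphic there.  Codons with
    multiple changes are resolved by uniform averaging over minimal
    stop-free mutational paths; codons with gaps, in-frame stops on a
    path, or no stop-free path are skipped and tallied with reasons.
    """
    code = get_code(population.genetic_code)
    outgroup = outgroup.upper().replace(" ", "")
    if len(outgroup) != len(population.sequences[0]):
        raise ValueError(
            f"outgroup length {len(outgroup)} != alignment length "
            f"{len(population.sequences[0])}"
        )
    counts = MKCounts()

    def skip(reason: str) -> None:
        counts.n_codons_skipped += 1
        counts.skip_reasons[reason] = counts.skip_reasons.get(reason, 0) + 1

    for col in range(population.site_count):
        ing = population.codon_column(col)
        out = outgroup[3 * col : 3 * col + 3]
        if GAP_CODON in ing or "-" in out:
            skip("gap")
            continue
        if any(nt not in "ACGT" for nt in out):
            skip("ambiguous_outgroup")
            continue
        if code.is_stop(out):
            skip("outgroup_stop")
            continue
        cons = _consensus(ing)
        poly_positions = [p for p in range(3) if len({c[p] for c in ing}) > 1]
        div_positions = [
            p
            for p in range(3)
            if len({c[p] for c in ing}) == 1 and ing[0][p] != out[p]
        ]
        used = False
        blocked = None
        # polymorphisms: each segregating allele against the consensus
        # background, with divergent positions already at their fixed state
        for p in poly_positions:
            alleles = sorted({c[p] for c in ing} - {cons[p]})
            for alt in alleles:
                res = _path_average(
                    cons, cons[:p] + alt + cons[p + 1 :], [p], code
                )
                if res is None:
                    blocked = "polymorphism_through_stop"
                    continue
                counts.PN += res[0]
                counts.PS += res[1]
                used = True
        # divergence: outgroup-context codon to the fixed ingroup state
        if div_positions:
            start = "".join(
                out[p] if p in div_positions else cons[p] for p in range(3)
            )
            res = _path_average(start, cons, div_positions, code)
            if res is None:
                blocked = "divergence_through_stop"
            else:
                counts.DN += res[0]
                counts.DS += res[1]
                used = True
        if used:
            counts.n_codons_used += 1
        elif blocked is not None:
            skip(blocked)
    return counts


@dataclass
class MKTestResult:
    p_value: float
    neutrality_index: float
    ni_defined: bool
    table_rounded: np.ndarray
    table_fractional: np.ndarray


def mk_test(counts: MKCounts) -> MKTestResult:
    """Two-sided Fisher exact test on [[DN, DS], [PN, PS]].

    Fractional counts are rounded to the nearest integer (ties to even)
    for the exact test; the fractional table is reported alongside.
    NI = (PN/PS)/(DN/DS), flagged undefined on zero denominators.
    """
    frac = counts.as_table()
    table = np.rint(frac).astype(int)
    if table.sum() == 0:
        return MKTestResult(float("nan"), float("nan"), False, table, frac)
    _, p = fisher_exact(table, alternative="two-sided")
    defined = counts.PS > 0 and counts.DS > 0 and counts.DN > 0
    ni = (
        (counts.PN / counts.PS) / (counts.DN / counts.DS)
        if defined
        else float("nan")
    )
    return MKTestResult(float(p), ni, defined, table, frac)


def dos(counts: MKCounts) -> float:
    """Direction of selection: DN/(DN+DS) - PN/(PN+PS).

    Requires both a divergence and a polymorphism denominator; NaN
    (undefined) otherwise.  Always in [-1, 1] when defined.
    """
    div = counts.DN + counts.DS
    poly = counts.PN + counts.PS
    if div <= 0 or poly <= 0:
        return float("nan")
    return counts.DN / div - counts.PN / poly


# ---------------------------------------------------------------------
# Per-region summaries (e.g. structured domains vs disordered linker)
# ---------------------------------------------------------------------

def mk_by_region(
    population: CodonAlignment,
    outgroup: str,
    regions: dict[str, list[tuple[int, int]]],
) -> pd.DataFrame:
    """MK counts, Fisher p, NI and DoS per named region.

    ``regions`` maps labels to lists of 1-based inclusive codon ranges.
    """
    rows = []
    for label, ranges in regions.items():
        sites: list[int] = []
        for lo, hi in ranges:
            if lo < 1 or hi > population.site_count or lo > hi:
                raise ValueError(f"region {label!r}: bad range ({lo}, {hi})")
            sites.extend(range(lo - 1, hi))
        sub = CodonAlignment(
            list(population.taxa),
            [
                "".join(s[3 * c : 3 * c + 3] for c in sites)
                for s in population.sequences
            ],
            genetic_code=population.genetic_code,
        )
        sub_out = "".join(outgroup[3 * c : 3 * c + 3] for c in sites)
        counts = mk_counts(sub, sub_out)
        test = mk_test(counts)
        rows.append(
            {
                "region": label,
                "n_codons": len(sites),
                "DN": counts.DN,
                "DS": counts.DS,
                "PN": counts.PN,
                "PS": counts.PS,
                "fisher_p": test.p_value,
                "NI": test.neutrality_index,
                "DoS": dos(counts),
                "codons_used": counts.n_codons_used,
                "codons_skipped": counts.n_codons_skipped,
            }
        )
    return pd.DataFrame(rows)
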