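"""Join per-site selection estimates onto structure residues.

The central object is the :class:`ResidueRecord`: one alignment column,
its reference-taxon residue, the per-site selection estimates (posterior
mean dN/dS and P(omega > 1)), and the residue's structural context.
Downstream summaries reproduce the category-enrichment comparisons
(burial x disorder fractions among all residues vs residues under
relaxed or positive selection) and export per-residue attributes for
molecular viewers with the display value capped at 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from selstruct._codes import get_code
from selstruct.codon_evo.posterior import SitePosteriorTrack, SIGNIFICANCE_THRESHOLD
from selstruct.seqdata import CodonAlignment, GAP_CODON
from selstruct.struct_context import ResidueContext, three_to_one

DISPLAY_CAP = 1.5


class JoinError(ValueError):
    pass


def column_residue_map(aln: CodonAlignment, reference_taxon: str) -> dict[int, int]:
    """Map 1-based alignment codon columns to 1-based reference residues.

    Gap codons in the reference yield no mapping; residue numbers
    increment only on non-gap reference codons, so the map is injective
    and strictly increasing over mapped columns.
    """
    idx = aln.taxon_index(reference_taxon)
    seq = aln.sequences[idx]
    mapping: dict[int, int] = {}
    residue = 0
    for col in range(aln.site_count):
        codon = seq[3 * col : 3 * col + 3]
        if codon == GAP_CODON:
            continue
        residue += 1
        mapping[col + 1] = residue
    return mapping


def reference_residue_aas(aln: CodonAlignment, reference_taxon: str) -> dict[int, str]:
    """1-based residue number -> one-letter amino acid of the reference."""
    code = get_code(aln.genetic_code)
    idx = aln.taxon_index(reference_taxon)
    seq = aln.sequences[idx]
    out: dict[int, str] = {}
    residue = 0
    for col in range(aln.site_count):
        codon = seq[3 * col : 3 * col + 3]
        if codon == GAP_CODON:
            continue
        residue += 1
        out[residue] = code.translate_codon(codon)
    return out


@dataclass
class ResidueRecord:
    """One reference residue with selection estimates and structural context."""

    alignment_column: int  # 1-based codon site
    reference_residue_number: int  # 1-based
    aa_type: str  # one-letter
    post_mean_omega: float
    prob_positive: float
    significant: bool
    chain: str
    structure_residue_number: int
    rel_sesa: float
    plddt: float
    disorder: bool | None
    burial_category: str
    flagged: bool = False  # amino-acid cross-check failed
    gene: str = ""
    lineage: str = ""


def join(
    track: SitePosteriorTrack,
    col_map: dict[int, int],
    reference_aa: dict[int, str],
    contexts: list[ResidueContext],
    numbering_offset: int = 0,
    gene: str = "",
    lineage: str = "",
    max_mismatch_fraction: float = 0.2,
) -> tuple[list[ResidueRecord], dict]:
    """Inner-join the posterior track to structure residues.

    Structure residue number = reference residue number + offset.  The
    amino-acid cross-check compares the translated reference codon to
    the structure residue type; mismatching records are flagged and
    excluded from summaries, and more than 20% mismatches aborts (wrong
    structure or wrong reference taxon).  Returns (records, report)
    where the report counts unmatched columns and residues.
    """
    by_number = {c.residue_number: c for c in contexts}
    records: list[ResidueRecord] = []
    unmatched_columns: list[int] = []
    matched_struct: set[int] = set()
    n_mismatch = 0
    for col, residue in col_map.items():
        if col - 1 >= track.n_sites:
            raise JoinError(f"column {col} outside posterior track")
        struct_num = residue + numbering_offset
        ctx = by_number.get(struct_num)
        if ctx is None:
            unmatched_columns.append(col)
            continue
        matched_struct.add(struct_num)
        ref_aa = reference_aa[residue]
        struct_aa = three_to_one(ctx.aa_type)
        flagged = struct_aa != "X" and ref_aa != struct_aa
        n_mismatch += flagged
        records.append(
            ResidueRecord(
                alignment_column=col,
                reference_residue_number=residue,
                aa_type=ref_aa,
                post_mean_omega=float(track.post_mean_omega[col - 1]),
                prob_positive=float(track.prob_positive[col - 1]),
                significant=bool(track.significant[col - 1]),
                chain=ctx.chain,
                structure_residue_number=struct_num,
                rel_sesa=ctx.rel_sesa,
                plddt=ctx.plddt,
                disorder=ctx.disorder,
                burial_category=ctx.burial_category,
                flagged=flagged,
                gene=gene,
                lineage=lineage,
            )
        )
    if records and n_mismatch / len(records) > max_mismatch_fraction:
        raise JoinError(
            f"{n_mismatch}/{len(records)} amino-acid mismatches between "
            "reference and structure; wrong structure or wrong taxon?"
        )
    report = {
        "n_records": len(records),
        "n_flagged": n_mismatch,
        "unmatched_columns": unmatched_columns,
        "unmatched_residues": sorted(
            set(by_number) - matched_struct
        ),
    }
    return records, report


def records_to_frame(records: list[ResidueRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------
# Enrichment summaries (burial x disorder, per selection subset)
# ---------------------------------------------------------------------

def enrichment_summary(
    records: list[ResidueRecord],
    significance_threshold: float = SIGNIFICANCE_THRESHOLD,
) -> pd.DataFrame:
    """Category fractions among all residues, residues with posterior
    mean omega > 1 (relaxed selection), and residues with
    P(omega > 1) above the significance threshold (positive selection).

    Flagged records are excluded.  Fractions within each non-empty
    subset sum to 1; empty subsets report NaN fractions.
    """
    clean = [r for r in records if not r.flagged]
    if not clean:
        raise ValueError("no records to summarize")
    subsets = {
        "all": clean,
        "post_mean_omega>1": [r for r in clean if r.post_mean_omega > 1.0],
        "prob_positive>0.9": [
            r for r in clean if r.prob_positive > significance_threshold
        ],
    }
    cats = ("buried", "surface", "contact")
    rows = []
    for name, subset in subsets.items():
        n = len(subset)
        for cat in cats:
            for dis in (False, True):
                count = sum(
                    1
                    for r in subset
                    if r.burial_category == cat and bool(r.disorder) == dis
                )
                rows.append(
                    {
                        "subset": name,
                        "category": cat,
                        "disorder": dis,
                        "count": count,
                        "fraction": count / n if n else float("nan"),
                        "subset_size": n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Viewer attribute export
# ---------------------------------------------------------------------

def export_attributes(
    records: list[ResidueRecord],
    attr_path: str | Path,
    tsv_path: str | Path | None = None,
    cap: float = DISPLAY_CAP,
) -> None:
    """Write per-residue viewer attributes and the full TSV.

    The attribute file (defattr dialect) carries the posterior mean
    omega capped at ``cap`` (a fixed color scale across structures) and
    the posterior probability of positive selection; the TSV keeps
    uncapped values.
    """
    with open(attr_path, "w") as fh:
        fh.write("attribute: postMeanOmega\nmatch mode: 1-to-1\nrecipient: residues\n")
        for r in records:
            fh.write(
                f"\t:{r.structure_residue_number}.{r.chain}\t"
                f"{min(r.post_mean_omega, cap):.4f}\n"
            )
        fh.write("\nattribute: probPositive\nmatch mode: 1-to-1\nrecipient: residues\n")
        for r in records:
            fh.write(
                f"\t:{r.structure_residue_number}.{r.chain}\t{r.prob_positive:.4f}\n"
            )
    if tsv_path is not None:
        records_to_frame(records).to_csv(tsv_path, sep="\t", index=False)


def parse_attributes(path: str | Path) -> dict[str, dict[tuple[int, str], float]]:
    """Parse a defattr-dialect attribute file back to value maps."""
    out: dict[str, dict[tuple[int, str], float]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("attribute:"):
                current = line.split(":", 1)[1].strip()
                out[current] = {}
            elif line.startswith("\t:") and current is not None:
                spec, value = line.strip().split("\t")
                resnum, chain = spec.lstrip(":").split(".")
                out[current][(int(resnum), chain)] = float(value)
    return out


# ---------------------------------------------------------------------
# Group comparisons (disorder / burial / contact)
# ---------------------------------------------------------------------

@dataclass
class GroupComparison:
    grouping: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sizes: tuple[int, int]
    t_statistic: float
    p_value: float


def group_compare(records: list[ResidueRecord], grouping: str) -> GroupComparison:
    """Welch two-sample t test of posterior mean omega between groups.

    ``disorder``: structured vs disordered; ``burial``: buried vs
    surface-exposed (surface + contact); ``category``: noncontact
    surface vs contact surface.  Two-sided, unequal variances.
    """
    clean = [r for r in records if not r.flagged]
    if grouping == "disorder":
        a = [r for r in clean if not r.disorder]
        b = [r for r in clean if r.disorder]
        names = ("structured", "disordered")
    elif grouping == "burial":
        a = [r for r in clean if r.burial_category == "buried"]
        b = [r for r in clean if r.burial_category != "buried"]
        names = ("buried", "surface")
    elif grouping == "category":
        a = [r for r in clean if r.burial_category == "surface"]
        b = [r for r in clean if r.burial_category == "contact"]
        names = ("surface", "contact")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 residues (got {len(a)} and {len(b)})"
        )
    xa = np.array([r.post_mean_omega for r in a])
    xb = np.array([r.post_mean_omega for r in b])
    if np.allclose(xa.var(), 0) and np.allclose(xb.var(), 0) and np.isclose(xa.mean(), xb.mean()):
        t, p = 0.0, 1.0
    else:
        import warnings

        with warnings.catch_warnings():
            # constant samples trigger a harmless precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return GroupComparison(
        grouping=grouping,
        group_names=names,
        means=(float(xa.mean()), float(xb.mean())),
        sizes=(len(a), len(b)),
        t_statistic=float(t),
        p_value=float(p),
    )
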