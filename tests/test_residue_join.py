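"""Joining posterior tracks to structural context and summaries."""

import numpy as np
import pytest

from selstruct.codon_evo.posterior import SitePosteriorTrack
from selstruct.residue_join import (
    JoinError,
    column_residue_map,
    enrichment_summary,
    export_attributes,
    group_compare,
    join,
    parse_attributes,
    reference_residue_aas,
)
from selstruct.seqdata import CodonAlignment
from selstruct.struct_context import ResidueContext


def _track(post_means, prob_pos=None):
    n = len(post_means)
    prob_pos = np.zeros(n) if prob_pos is None else np.asarray(prob_pos, float)
    return SitePosteriorTrack(
        class_posteriors=np.ones((n, 1)),
        class_omegas=np.array([1.0]),
        post_mean_omega=np.asarray(post_means, float),
        prob_positive=prob_pos,
        method="NEB",
        model_tag="M8",
    )


def _context(num, aa="MET", category="surface", disorder=False, rel=0.5):
    return ResidueContext(
        chain="A", residue_number=num, aa_type=aa, sasa_monomer=50.0,
        rel_sesa=rel, burial_category=category, plddt=90.0, disorder=disorder,
    )


class TestColumnResidueMap:
    def test_gap_skipping(self):
        aln = CodonAlignment(["r", "o"], ["ATG---GCT", "ATGAAAGCT"])
        assert column_residue_map(aln, "r") == {1: 1, 3: 2}

    def test_gap_free_identity(self):
        aln = CodonAlignment(["r", "o"], ["ATGAAAGCT", "ATGAAAGCA"])
        assert column_residue_map(aln, "r") == {1: 1, 2: 2, 3: 3}

    def test_strictly_increasing(self):
        aln = CodonAlignment(["r", "o"], ["ATG------GCTAAA", "ATGAAAGGGGCTAAA"])
        m = column_residue_map(aln, "r")
        cols = sorted(m)
        assert [m[c] for c in cols] == sorted(m.values())
        assert len(set(m.values())) == len(m)

    def test_missing_taxon(self):
        aln = CodonAlignment(["r", "o"], ["ATGGCT", "ATGGCA"])
        with pytest.raises(KeyError):
            column_residue_map(aln, "nope")


class TestJoin:
    def _inputs(self):
        aln = CodonAlignment(["r", "o"], ["ATGGCTAAA", "ATGGCAAAA"])
        cmap = column_residue_map(aln, "r")
        ref_aa = reference_residue_aas(aln, "r")  # M, A, K
        contexts = [_context(1, "MET"), _context(2, "ALA"), _context(3, "LYS")]
        return _track([0.2, 1.4, 2.0], [0.1, 0.5, 0.95]), cmap, ref_aa, contexts

    def test_lossless_on_matched_fixture(self):
        track, cmap, ref_aa, contexts = self._inputs()
        records, report = join(track, cmap, ref_aa, contexts)
        assert len(records) == 3 and report["n_flagged"] == 0
        assert [r.post_mean_omega for r in records] == [0.2, 1.4, 2.0]
        assert records[2].significant

    def test_offset_correction(self):
        track, cmap, ref_aa, _ = self._inputs()
        shifted = [_context(11, "MET"), _context(12, "ALA"), _context(13, "LYS")]
        records, _ = join(track, cmap, ref_aa, shifted, numbering_offset=10)
        assert [r.structure_residue_number for r in records] == [11, 12, 13]
        assert [r.reference_residue_number for r in records] == [1, 2, 3]

    def test_single_mismatch_flagged_not_fatal(self):
        aln = CodonAlignment(["r", "o"], ["ATG" * 10, "ATG" * 10])
        cmap = column_residue_map(aln, "r")
        ref_aa = reference_residue_aas(aln, "r")
        contexts = [_context(i, "MET") for i in range(1, 11)]
        contexts[4] = _context(5, "GLY")  # mutated residue in the structure
        records, report = join(_track([0.5] * 10), cmap, ref_aa, contexts)
        assert report["n_flagged"] == 1
        assert records[4].flagged and not records[0].flagged

    def test_many_mismatches_abort(self):
        track, cmap, ref_aa, _ = self._inputs()
        wrong = [_context(1, "GLY"), _context(2, "GLY"), _context(3, "GLY")]
        with pytest.raises(JoinError, match="mismatch"):
            join(track, cmap, ref_aa, wrong)


class TestEnrichment:
    def test_planted_fractions_exact(self):
        # 10 records: 6 buried+structured, 3 surface+disordered (high omega),
        # 1 contact+structured
        contexts = (
            [_context(i, category="buried") for i in range(1, 7)]
            + [_context(i, category="surface", disorder=True) for i in range(7, 10)]
            + [_context(10, category="contact")]
        )
        aln = CodonAlignment(["r", "o"], ["ATG" * 10, "ATG" * 10])
        track = _track(
            [0.2] * 6 + [2.0] * 3 + [0.5], [0.0] * 6 + [0.95] * 3 + [0.0]
        )
        records, _ = join(
            track, column_residue_map(aln, "r"), reference_residue_aas(aln, "r"),
            contexts,
        )
        summary = enrichment_summary(records)
        allsub = summary[summary.subset == "all"]
        assert np.isclose(allsub.fraction.sum(), 1.0)
        cell = allsub[(allsub.category == "buried") & (~allsub.disorder)]
        assert np.isclose(cell.fraction.iloc[0], 0.6)
        relaxed = summary[summary.subset == "post_mean_omega>1"]
        cell = relaxed[(relaxed.category == "surface") & (relaxed.disorder)]
        assert np.isclose(cell.fraction.iloc[0], 1.0)

    def test_all_one_cell(self):
        contexts = [_context(i, category="buried") for i in range(1, 4)]
        aln = CodonAlignment(["r", "o"], ["ATGATGATG", "ATGATGATG"])
        records, _ = join(
            _track([0.1, 0.2, 0.3]), column_residue_map(aln, "r"),
            reference_residue_aas(aln, "r"), contexts,
        )
        s = enrichment_summary(records)
        cell = s[(s.subset == "all") & (s.category == "buried") & (~s.disorder)]
        assert cell.fraction.iloc[0] == 1.0

    def test_order_invariant(self):
        contexts = [
            _context(1, "MET", "buried"), _context(2, "ALA", "surface"),
            _context(3, "LYS", "contact"),
        ]
        aln = CodonAlignment(["r", "o"], ["ATGGCTAAA", "ATGGCTAAA"])
        records, _ = join(
            _track([0.3, 1.2, 0.7]), column_residue_map(aln, "r"),
            reference_residue_aas(aln, "r"), contexts,
        )
        s1 = enrichment_summary(records)
        s2 = enrichment_summary(records[::-1])
        assert s1.equals(s2)


class TestExport:
    def test_cap_applies_to_attribute_not_tsv(self, tmp_path):
        contexts = [_context(1, "MET"), _context(2, "ALA")]
        aln = CodonAlignment(["r", "o"], ["ATGGCT", "ATGGCA"])
        records, _ = join(
            _track([2.7, 0.3]), column_residue_map(aln, "r"),
            reference_residue_aas(aln, "r"), contexts,
        )
        attr = tmp_path / "omega.defattr"
        tsv = tmp_path / "records.tsv"
        export_attributes(records, attr, tsv, cap=1.5)
        parsed = parse_attributes(attr)
        assert parsed["postMeanOmega"][(1, "A")] == 1.5
        assert parsed["postMeanOmega"][(2, "A")] == 0.3
        import pandas as pd

        assert pd.read_csv(tsv, sep="\t")["post_mean_omega"].iloc[0] == 2.7

    def test_round_trip(self, tmp_path):
        contexts = [_context(i, "MET") for i in (1, 2)]
        aln = CodonAlignment(["r", "o"], ["ATGATG", "ATGATG"])
        records, _ = join(
            _track([0.4, 1.1], [0.2, 0.8]), column_residue_map(aln, "r"),
            reference_residue_aas(aln, "r"), contexts,
        )
        attr = tmp_path / "a.defattr"
        export_attributes(records, attr)
        parsed = parse_attributes(attr)
        assert parsed["probPositive"] == {(1, "A"): 0.2, (2, "A"): 0.8}


class TestGroupCompare:
    def _records(self, means_a, means_b, disorder_b=True):
        aln_len = len(means_a) + len(means_b)
        contexts = [
            _context(i + 1, "MET", disorder=(i >= len(means_a)) and disorder_b)
            for i in range(aln_len)
        ]
        aln = CodonAlignment(["r", "o"], ["ATG" * aln_len] * 2)
        records, _ = join(
            _track(list(means_a) + list(means_b)),
            column_residue_map(aln, "r"), reference_residue_aas(aln, "r"),
            contexts,
        )
        return records

    def test_identical_groups_t_zero(self):
        records = self._records([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        res = group_compare(records, "disorder")
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_planted_difference_significant(self, rng):
        a = rng.normal(0.2, 0.1, 200)
        b = rng.normal(0.8, 0.1, 200)
        res = group_compare(self._records(a, b), "disorder")
        assert res.p_value < 1e-6
        assert res.t_statistic < 0  # structured mean below disordered mean
        assert res.sizes == (200, 200)

    def test_sign_matches_ordering(self):
        res = group_compare(self._records([0.9, 0.8, 0.7], [0.1, 0.2, 0.3]), "disorder")
        assert res.t_statistic > 0

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            group_compare(self._records([0.5, 0.5], [0.4]), "disorder")
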