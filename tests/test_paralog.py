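"""Superposition, residue matching and delta-omega comparison."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from selstruct.paralog_compare import (
    AlignmentQualityError,
    delta_omega_table,
    divergence_vs_time,
    kabsch,
    match_residues,
    percent_identity,
    read_residue_pairs,
    superpose,
    write_residue_pairs,
)
from selstruct.synthetic_data import (
    ToyStructureSpec,
    generate_paralog_pair,
    generate_toy_structure,
)


class TestKabsch:
    def test_exact_recovery_of_rigid_transform(self, rng):
        pts = rng.normal(size=(20, 3))
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        t = np.array([3.0, -2.0, 5.0])
        transform, rmsd = kabsch(pts @ R.T + t, pts)
        assert rmsd < 1e-9
        assert np.allclose(transform.rotation @ R, np.eye(3), atol=1e-9)

    def test_self_superposition_is_identity(self):
        spec = ToyStructureSpec(n_residues=10, geometry="helix")
        model = generate_toy_structure(spec)
        transform, rmsd = superpose(model, model)
        assert rmsd < 1e-9
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_three_point_toy_matches_grid_search(self, rng):
        """Coarse brute-force search over rotations approaches the Kabsch
        optimum from above."""
        fixed = np.array([[0.0, 0, 0], [2.0, 0.5, 0], [0.5, 2.0, 1.0]])
        moving = np.array([[0.1, 0, 0], [2.2, 0.4, 0.1], [0.4, 1.9, 1.2]])
        _, best_rmsd = kabsch(moving, fixed)
        mc = moving - moving.mean(axis=0)
        fc = fixed - fixed.mean(axis=0)

        def scan(centers, half_width, steps):
            best = (np.inf, None)
            axes = [np.linspace(c - half_width, c + half_width, steps) for c in centers]
            for a in axes[0]:
                for b in axes[1]:
                    for c in axes[2]:
                        R = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                        r = np.sqrt(np.mean(np.sum((mc @ R.T - fc) ** 2, axis=1)))
                        if r < best[0]:
                            best = (r, (a, b, c))
            return best

        # coarse global grid, then two nested refinements around the best
        rmsd_grid, center = scan((0.0, 0.0, 0.0), np.pi, 25)
        for width in (np.pi / 12, np.pi / 120):
            rmsd_grid, center = scan(center, width, 11)
        assert rmsd_grid >= best_rmsd - 1e-12
        assert rmsd_grid - best_rmsd < 1e-3

    def test_collinear_seed_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(line, line + 1.0)


class TestMatching:
    def test_transformed_duplicate_fully_matched(self):
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=25, geometry="helix", seed=3)
        )
        matches, quality = match_residues(pair["model_a"], pair["model_b"])
        assert len(matches) == 25
        assert quality.rmsd < 1e-6
        assert quality.tm_score > 0.999 and quality.usable
        assert all(m.residue_a == m.residue_b for m in matches)

    def test_deleted_residues_unmatched(self):
        deleted = (5, 6, 7, 11, 12, 13, 20, 21, 22, 23)
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=40, geometry="helix", seed=4),
            deleted_residues_b=deleted,
        )
        matches, quality = match_residues(pair["model_a"], pair["model_b"])
        matched_a = {m.residue_a for m in matches}
        assert matched_a == set(range(1, 41)) - set(deleted)

    def test_symmetry_of_pair_set(self):
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=20, geometry="helix", seed=5),
            deleted_residues_b=(3, 4),
        )
        m_ab, _ = match_residues(pair["model_a"], pair["model_b"])
        m_ba, _ = match_residues(pair["model_b"], pair["model_a"])
        assert {(m.residue_a, m.residue_b) for m in m_ab} == {
            (m.residue_b, m.residue_a) for m in m_ba
        }

    def test_unrelated_folds_fail_quality_gate(self):
        helix = generate_toy_structure(
            ToyStructureSpec(n_residues=30, geometry="helix")
        )
        globule = generate_toy_structure(
            ToyStructureSpec(
                n_residues=30, geometry="compact-cluster", designed_buried=(15,)
            )
        )
        try:
            _, quality = match_residues(helix, globule)
            assert not quality.usable
            assert quality.tm_score <= 0.5 or quality.coverage < 0.5
        except AlignmentQualityError:
            pass  # fewer than 3 stable matches is also a failed gate

    def test_pair_file_round_trip(self, tmp_path):
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=12, geometry="helix", seed=6)
        )
        matches, _ = match_residues(pair["model_a"], pair["model_b"])
        path = tmp_path / "pairs.tsv"
        write_residue_pairs(matches, path)
        assert read_residue_pairs(path) == [(m.residue_a, m.residue_b) for m in matches]


class TestDeltaOmega:
    def test_identical_tracks_all_tied(self):
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=15, geometry="helix", seed=7)
        )
        matches, _ = match_residues(pair["model_a"], pair["model_b"])
        track = {i: 0.3 for i in range(1, 16)}
        df, summary = delta_omega_table(matches, track, dict(track))
        assert summary.n_tied == 15 and summary.n_higher_a == 0
        assert np.allclose(df["delta_omega"], 0.0)
        assert summary.p_value == 1.0

    def test_planted_block_recovered_exactly(self):
        n = 40
        omega_a = np.full(n, 0.2)
        omega_a[5:35] = 0.7  # 30 designated residues
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=n, geometry="helix", seed=8),
            omega_a=omega_a,
        )
        matches, _ = match_residues(pair["model_a"], pair["model_b"])
        df, summary = delta_omega_table(
            matches,
            {i + 1: float(pair["omega_a"][i]) for i in range(n)},
            {i + 1: float(pair["omega_b"][i]) for i in range(n)},
        )
        assert summary.n_higher_a == 30 and summary.n_higher_b == 0
        assert np.isclose(summary.mean_delta, 30 * 0.5 / n)

    def test_counts_partition_total(self, rng):
        pair = generate_paralog_pair(
            ToyStructureSpec(n_residues=20, geometry="helix", seed=9)
        )
        matches, _ = match_residues(pair["model_a"], pair["model_b"])
        ta = {i: float(x) for i, x in enumerate(rng.uniform(0, 2, 21), start=0)}
        tb = {i: float(x) for i, x in enumerate(rng.uniform(0, 2, 21), start=0)}
        _, s = delta_omega_table(matches, ta, tb)
        assert s.n_higher_a + s.n_higher_b + s.n_tied == s.n_pairs

    def test_superposition_invariance(self):
        """The delta-omega table ignores the coordinate frame entirely."""
        spec = ToyStructureSpec(n_residues=18, geometry="helix", seed=10)
        p1 = generate_paralog_pair(spec)
        p2 = generate_paralog_pair(
            ToyStructureSpec(n_residues=18, geometry="helix", seed=11)
        )
        track = {i: float(i) / 20 for i in range(1, 19)}
        m1, _ = match_residues(p1["model_a"], p1["model_b"])
        m2, _ = match_residues(p2["model_a"], p2["model_b"])
        df1, _ = delta_omega_table(m1, track, track)
        df2, _ = delta_omega_table(m2, track, track)
        assert df1.equals(df2)


class TestDivergenceVsTime:
    def test_identical_pair_zero_divergence(self):
        assert percent_identity("MKLV", "MKLV") == 100.0

    def test_gap_only_columns_ignored(self):
        assert percent_identity("MK-LV", "MKALV") == percent_identity("MKLV", "MKLV")

    def test_exact_linear_data(self):
        pairs = []
        base = "M" * 100
        for t in (10, 20, 40, 60):
            # divergence = 0.5 * time, exactly
            n_diff = int(0.5 * t)
            seq_b = "K" * n_diff + "M" * (100 - n_diff)
            pairs.append(
                {"name": f"p{t}", "seq_a": base, "seq_b": seq_b, "time": t,
                 "group": "meiotic"}
            )
        table, fits = divergence_vs_time(pairs)
        fit = fits.iloc[0]
        assert np.isclose(fit.slope, 0.5)
        assert np.isclose(fit.intercept, 0.0, atol=1e-9)
        assert np.isclose(fit.r_squared, 1.0)
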