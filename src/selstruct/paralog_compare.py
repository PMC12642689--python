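"""Matched-residue comparison of paralog structures.

Rigid superposition (Kabsch) plus iterative mutual-nearest-neighbour
C-alpha matching stands in for a flexible structure aligner: adequate for
same-fold paralog pairs, with a TM-score-style quality gate (> 0.5 and
sufficient coverage) to reject unreliable alignments.  Externally
produced residue-pair lists can be imported verbatim.  Given per-residue
posterior mean dN/dS tracks for the two proteins, the module tabulates
per-pair differences (delta omega) and regresses pairwise sequence
divergence against divergence time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from selstruct.struct_context import StructureModel

MATCH_CUTOFF = 4.0
TM_SCORE_GATE = 0.5
COVERAGE_GATE = 0.5


class AlignmentQualityError(ValueError):
    pass


# ---------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------

@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform taking ``moving`` onto ``fixed``.

    Standard Kabsch: SVD of the covariance of centered coordinates, with
    the determinant correction to exclude reflections.  Raises on
    degenerate (collinear or < 3 point) inputs where the rotation is
    not unique.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.shape[0] < 3:
        raise ValueError("need >= 3 paired points")
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) correspondence set")
    H = mc.T @ fc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fixed.mean(axis=0) - moving.mean(axis=0) @ R.T
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(moving) - fixed) ** 2, axis=1))))
    return transform, rmsd


def superpose(
    a: StructureModel,
    b: StructureModel,
    correspondence: list[tuple[int, int]] | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> tuple[RigidTransform, float]:
    """Superpose B onto A on corresponding C-alpha atoms.

    ``correspondence`` is a list of (residue_number_a, residue_number_b)
    seed pairs; when omitted, residues sharing a number in both
    structures seed the fit.
    """
    nums_a, ca_a, _ = a.ca_coords(chain_a)
    nums_b, ca_b, _ = b.ca_coords(chain_b)
    pos_a = {int(n): i for i, n in enumerate(nums_a)}
    pos_b = {int(n): i for i, n in enumerate(nums_b)}
    if correspondence is None:
        correspondence = [(n, n) for n in sorted(set(pos_a) & set(pos_b))]
    if len(correspondence) < 3:
        raise ValueError("need >= 3 correspondence pairs")
    fixed = np.array([ca_a[pos_a[i]] for i, _ in correspondence])
    moving = np.array([ca_b[pos_b[j]] for _, j in correspondence])
    return kabsch(moving, fixed)


# ---------------------------------------------------------------------
# Iterative mutual-nearest-neighbour matching
# ---------------------------------------------------------------------

@dataclass
class ResidueMatch:
    residue_a: int
    residue_b: int
    distance: float
    aa_a: str
    aa_b: str


@dataclass
class StructAlignQuality:
    """TM-score-style quality in [0, 1], coverage of the shorter chain,
    and rmsd over matched pairs; ``usable`` applies the gates
    (score > 0.5 and coverage >= 50% by default)."""

    tm_score: float
    coverage: float
    rmsd: float
    n_matched: int
    usable: bool


def _tm_d0(length: int) -> float:
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _mutual_nn(ca_a: np.ndarray, ca_b: np.ndarray, cutoff: float) -> list[tuple[int, int, float]]:
    tree_a = cKDTree(ca_a)
    tree_b = cKDTree(ca_b)
    d_ab, j_ab = tree_b.query(ca_a, k=1, distance_upper_bound=cutoff)
    d_ba, j_ba = tree_a.query(ca_b, k=1, distance_upper_bound=cutoff)
    pairs = []
    for i in range(len(ca_a)):
        j = j_ab[i]
        if np.isfinite(d_ab[i]) and j < len(ca_b) and j_ba[j] == i:
            pairs.append((i, int(j), float(d_ab[i])))
    return pairs


def match_residues(
    a: StructureModel,
    b: StructureModel,
    cutoff: float = MATCH_CUTOFF,
    max_iter: int = 10,
    chain_a: str | None = None,
    chain_b: str | None = None,
    tm_gate: float = TM_SCORE_GATE,
    coverage_gate: float = COVERAGE_GATE,
) -> tuple[list[ResidueMatch], StructAlignQuality]:
    """Iterative closest-C-alpha matching after rigid superposition.

    Alternates mutual-nearest-neighbour pairing within ``cutoff`` with
    re-superposition on the current pairs until the pair set stabilizes.
    Quality is the TM-score normalized by the shorter chain; results
    failing the gates are returned with ``usable=False``.
    """
    nums_a, ca_a, res_a = a.ca_coords(chain_a)
    nums_b, ca_b, res_b = b.ca_coords(chain_b)
    try:
        transform, _ = superpose(a, b, None, chain_a, chain_b)
        moved = transform.apply(ca_b)
    except ValueError:
        moved = ca_b - ca_b.mean(axis=0) + ca_a.mean(axis=0)
    pairs = _mutual_nn(ca_a, moved, cutoff)
    for _ in range(max_iter):
        if len(pairs) < 3:
            break
        transform, _ = kabsch(
            ca_b[[j for _, j, _ in pairs]], ca_a[[i for i, _, _ in pairs]]
        )
        moved = transform.apply(ca_b)
        new_pairs = _mutual_nn(ca_a, moved, cutoff)
        if {(i, j) for i, j, _ in new_pairs} == {(i, j) for i, j, _ in pairs}:
            pairs = new_pairs
            break
        pairs = new_pairs
    if len(pairs) < 3:
        raise AlignmentQualityError(
            f"only {len(pairs)} matched residues; no reliable alignment"
        )
    pairs.sort(key=lambda p: nums_a[p[0]])
    l_short = min(len(ca_a), len(ca_b))
    d0 = _tm_d0(l_short)
    dists = np.array([d for _, _, d in pairs])
    tm = float(np.sum(1.0 / (1.0 + (dists / d0) ** 2)) / l_short)
    coverage = len(pairs) / l_short
    rmsd = float(np.sqrt(np.mean(dists**2)))
    quality = StructAlignQuality(
        tm_score=tm,
        coverage=coverage,
        rmsd=rmsd,
        n_matched=len(pairs),
        usable=(tm > tm_gate) and (coverage >= coverage_gate),
    )
    matches = [
        ResidueMatch(
            residue_a=int(nums_a[i]),
            residue_b=int(nums_b[j]),
            distance=float(d),
            aa_a=res_a[i],
            aa_b=res_b[j],
        )
        for i, j, d in pairs
    ]
    return matches, quality


def read_residue_pairs(path: str | Path) -> list[tuple[int, int]]:
    """Import an externally produced two-column residue-pair TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    return [(int(r[0]), int(r[1])) for r in df.itertuples(index=False)]


def write_residue_pairs(matches: list[ResidueMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_a\tresidue_b\tdistance\n")
        for m in matches:
            fh.write(f"{m.residue_a}\t{m.residue_b}\t{m.distance:.3f}\n")


# ---------------------------------------------------------------------
# Delta-omega comparison at matched residues
# ---------------------------------------------------------------------

@dataclass
class DeltaOmegaSummary:
    n_pairs: int
    n_dropped: int
    n_higher_a: int
    n_higher_b: int
    n_tied: int
    mean_a: float
    mean_b: float
    mean_delta: float
    t_statistic: float
    p_value: float


def delta_omega_table(
    matches: list[ResidueMatch],
    track_a: dict[int, float],
    track_b: dict[int, float],
    tie_tolerance: float = 1e-9,
) -> tuple[pd.DataFrame, DeltaOmegaSummary]:
    """Per-matched-pair difference in posterior mean omega (A - B).

    Pairs lacking coverage in either track are dropped (counted).  The
    summary reports counts of pairs with omega higher in A vs B vs tied,
    group means, and a Welch t test between the two matched samples.
    """
    rows = []
    dropped = 0
    for m in matches:
        wa = track_a.get(m.residue_a)
        wb = track_b.get(m.residue_b)
        if wa is None or wb is None:
            dropped += 1
            continue
        rows.append(
            {
                "residue_a": m.residue_a,
                "residue_b": m.residue_b,
                "omega_a": wa,
                "omega_b": wb,
                "delta_omega": wa - wb,
            }
        )
    if not rows:
        raise ValueError("no matched pairs covered by both omega tracks")
    df = pd.DataFrame(rows)
    delta = df["delta_omega"].to_numpy()
    higher_a = int((delta > tie_tolerance).sum())
    higher_b = int((delta < -tie_tolerance).sum())
    tied = len(delta) - higher_a - higher_b
    xa = df["omega_a"].to_numpy()
    xb = df["omega_b"].to_numpy()
    if np.allclose(xa, xb):
        t, p = 0.0, 1.0
    else:
        import warnings

        with warnings.catch_warnings():
            # constant samples trigger a harmless precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
    summary = DeltaOmegaSummary(
        n_pairs=len(delta),
        n_dropped=dropped,
        n_higher_a=higher_a,
        n_higher_b=higher_b,
        n_tied=tied,
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        mean_delta=float(delta.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )
    return df, summary


def export_delta_attributes(
    df: pd.DataFrame, path: str | Path, chain: str = "A", side: str = "a"
) -> None:
    """Signed delta-omega attribute file for diverging color maps."""
    col = f"residue_{side}"
    with open(path, "w") as fh:
        fh.write("attribute: deltaOmega\nmatch mode: 1-to-1\nrecipient: residues\n")
        for _, row in df.iterrows():
            fh.write(f"\t:{int(row[col])}.{chain}\t{row['delta_omega']:.4f}\n")


# ---------------------------------------------------------------------
# Divergence vs time
# ---------------------------------------------------------------------

def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over columns where both sequences are non-gap."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    pairs = [
        (x, y) for x, y in zip(seq_a.upper(), seq_b.upper()) if x != "-" and y != "-"
    ]
    if not pairs:
        raise ValueError("no aligned non-gap positions")
    return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


def divergence_vs_time(
    seq_pairs: list[dict],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise divergence (100 - %identity) regressed on divergence time.

    Each entry of ``seq_pairs`` needs keys ``name``, ``seq_a``, ``seq_b``
    (aligned protein sequences), ``time`` and ``group``.  Returns the
    per-pair table and one OLS fit (slope, intercept, r^2) per group;
    groups need >= 2 distinct time points.
    """
    rows = []
    for pair in seq_pairs:
        pid = percent_identity(pair["seq_a"], pair["seq_b"])
        rows.append(
            {
                "name": pair["name"],
                "group": pair["group"],
                "time": float(pair["time"]),
                "percent_identity": pid,
                "divergence": 100.0 - pid,
            }
        )
    table = pd.DataFrame(rows)
    fits = []
    for group, sub in table.groupby("group"):
        if sub["time"].nunique() < 2:
            raise ValueError(f"group {group!r} needs >= 2 distinct time points")
        res = stats.linregress(sub["time"], sub["divergence"])
        fits.append(
            {
                "group": group,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
                "n": len(sub),
            }
        )
    return table, pd.DataFrame(fits)
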