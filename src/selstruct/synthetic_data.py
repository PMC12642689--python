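"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all seed-deterministic and each emitting a
machine-readable truth ledger:

* codon alignments evolved on a tree under a mixture of omega site
  classes (exact matrix-exponential transition probabilities, no
  event-level simulation);
* toy structures built from pseudo-atom residues with designed buried
  cores, designed dimer interfaces and planted pLDDT tracks, verified
  by the package's own SASA call before emission;
* population haplotype sets with planted synonymous/nonsynonymous
  polymorphisms and fixed differences against an outgroup.

Realistic protein geometry is a non-goal; the structures exist to give
the SASA and contact machinery controlled, checkable inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import biotite.structure as bst

from selstruct._codes import get_code, single_step_table
from selstruct.codon_evo.likelihood import ArrayTree, MixtureEngine
from selstruct.codon_evo.model import SiteClassMixture, discretize_beta
from selstruct.seqdata import CodonAlignment
from selstruct.struct_context import (
    StructureModel,
    contact_residues,
    sasa,
    relative_sesa,
)


class GeometryError(RuntimeError):
    """A toy-structure spec could not be realized geometrically."""


# ---------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------

def parametric_newick(shape: str, n_taxa: int, depth: float) -> str:
    """Ultrametric Newick string for a balanced or caterpillar tree with
    root-to-leaf path length ``depth`` (expected substitutions per codon)."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    if shape == "balanced":

        def sub(tx: list[str], parent_h: float) -> str:
            if len(tx) == 1:
                return f"{tx[0]}:{parent_h:.8f}"
            h = parent_h / 2.0
            mid = len(tx) // 2
            return f"({sub(tx[:mid], h)},{sub(tx[mid:], h)}):{parent_h - h:.8f}"

        mid = n_taxa // 2
        return f"({sub(taxa[:mid], depth)},{sub(taxa[mid:], depth)});"
    if shape == "caterpillar":
        step = depth / max(n_taxa - 1, 1)

        def cat(tx: list[str], h: float) -> str:
            if len(tx) == 2:
                return f"({tx[0]}:{h:.8f},{tx[1]}:{h:.8f})"
            return f"({tx[0]}:{h:.8f},{cat(tx[1:], h - step)}:{step:.8f})"

        return cat(taxa, depth) + ";"
    raise ValueError(f"unknown tree shape {shape!r}")


# ---------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------

@dataclass
class SimSpec:
    """Conditions for one codon-alignment simulation.

    ``site_class_plan`` is a list of (omega, proportion) pairs;
    proportions must sum to 1 and are realized as exact site counts
    (largest-remainder rounding) before random placement.
    """

    seed: int
    n_codons: int = 300
    kappa: float = 2.0
    tree: ArrayTree | None = None
    tree_shape: str = "balanced"
    n_taxa: int = 6
    depth: float = 0.5
    site_class_plan: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.3, 1.0)]
    )
    pi: np.ndarray | None = None
    genetic_code: int = 1


def m7_plan(p: float, q: float, k: int = 10) -> list[tuple[float, float]]:
    """Site-class plan matching the K-class discretization of beta(p, q)."""
    omegas, weights = discretize_beta(p, q, k)
    return [(float(o), float(w)) for o, w in zip(omegas, weights)]


def m8_plan(
    p: float, q: float, p0: float, omega_s: float, k: int = 10
) -> list[tuple[float, float]]:
    plan = [(o, w * p0) for o, w in m7_plan(p, q, k)]
    plan.append((float(omega_s), 1.0 - p0))
    return plan


def _exact_counts(props: np.ndarray, n: int) -> np.ndarray:
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-rem)[:short]:
        counts[idx] += 1
    return counts


@dataclass
class SimulatedAlignment:
    alignment: CodonAlignment
    site_labels: np.ndarray  # class index per codon site
    class_omegas: np.ndarray
    tree: ArrayTree
    newick: str
    ledger: dict


def simulate_codon_alignment(spec: SimSpec) -> SimulatedAlignment:
    """Evolve a codon alignment down a tree under the site-class plan.

    Root codons are drawn from the equilibrium frequencies; each branch
    applies the class-specific transition matrix exp(Q_k t).  Identical
    seeds give byte-identical alignments.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_code(spec.genetic_code)
    n_states = code.n_codons
    pi = (
        np.full(n_states, 1.0 / n_states)
        if spec.pi is None
        else np.asarray(spec.pi, float)
    )
    if spec.tree is not None:
        tree = spec.tree
        newick = "(supplied);"
    else:
        newick = parametric_newick(spec.tree_shape, spec.n_taxa, spec.depth)
        taxa = [f"t{i + 1}" for i in range(spec.n_taxa)]
        tree = ArrayTree.from_newick(newick, taxa)
    omegas = np.array([o for o, _ in spec.site_class_plan])
    props = np.array([w for _, w in spec.site_class_plan])
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("site-class proportions must sum to 1")
    counts = _exact_counts(props, spec.n_codons)
    labels = rng.permutation(np.repeat(np.arange(len(omegas)), counts))
    # the class weights set the shared rate scale, so they must match the
    # planted proportions for branch lengths to mean what they say
    nominal = SiteClassMixture(omegas, props, "custom")
    engine = MixtureEngine(nominal, spec.kappa, pi, spec.genetic_code)
    states = np.empty((tree.n_nodes, spec.n_codons), dtype=np.intp)
    states[tree.root] = rng.choice(n_states, size=spec.n_codons, p=pi)
    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        P = engine.transition_matrices(tree.lengths[node])
        parent_states = states[tree.parent[node]]
        out = np.empty(spec.n_codons, dtype=np.intp)
        for k in range(len(omegas)):
            sites = np.where(labels == k)[0]
            if len(sites) == 0:
                continue
            rows = np.cumsum(P[k][parent_states[sites]], axis=1)
            u = rng.random(len(sites))
            out[sites] = np.minimum(
                (rows < u[:, None]).sum(axis=1), n_states - 1
            )
        states[node] = out
    codon_strs = np.array(code.codons)
    sequences = [
        "".join(codon_strs[states[i]]) for i in range(tree.n_leaves)
    ]
    aln = CodonAlignment(list(tree.taxa), sequences, genetic_code=spec.genetic_code)
    ledger = {
        "kind": "codon_alignment",
        "seed": int(spec.seed),
        "kappa": spec.kappa,
        "n_codons": spec.n_codons,
        "newick": newick,
        "class_omegas": [float(o) for o in omegas],
        "class_proportions": [float(w) for w in props],
        "site_labels": [int(x) for x in labels],
    }
    return SimulatedAlignment(aln, labels, omegas, tree, newick, ledger)


# ---------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------

@dataclass
class ToyStructureSpec:
    """Conditions for one pseudo-atom toy structure.

    ``geometry`` is one of ``helix``, ``compact-cluster``,
    ``two-chain-dimer``.  Designed residue sets are 1-based residue
    numbers; for the dimer they apply symmetrically to both chains.
    """

    n_residues: int = 20
    geometry: str = "compact-cluster"
    designed_buried: tuple[int, ...] = ()
    designed_interface: tuple[int, ...] = ()
    plddt_track: np.ndarray | None = None
    aa_sequence: str | None = None  # one-letter; defaults to poly-ALA
    seed: int = 0


_SIDE_OFFSETS = 0.9 * np.array(
    [[1.0, 0.0, 0.35], [-0.5, 0.87, 0.35], [-0.5, -0.87, 0.35]]
)
_ATOM_NAMES = ["CA", "CB", "CG", "CD"]


def _residue_atoms(center: np.ndarray, orient: np.ndarray | None = None) -> np.ndarray:
    offsets = _SIDE_OFFSETS if orient is None else _SIDE_OFFSETS @ orient.T
    return np.vstack([center, center + offsets])


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _build_atom_array(
    chain_residue_centers: list[tuple[str, int, np.ndarray]],
    plddt: dict[tuple[str, int], float] | None = None,
    aa_sequence: str | None = None,
) -> StructureModel:
    n = 4 * len(chain_residue_centers)
    arr = bst.AtomArray(n)
    coords = np.empty((n, 3))
    for r, (chain, resnum, center) in enumerate(chain_residue_centers):
        sl = slice(4 * r, 4 * r + 4)
        coords[sl] = _residue_atoms(center)
        arr.chain_id[sl] = chain
        arr.res_id[sl] = resnum
        arr.res_name[sl] = (
            _ONE_TO_THREE.get(aa_sequence[resnum - 1].upper(), "ALA")
            if aa_sequence
            else "ALA"
        )
        arr.atom_name[sl] = _ATOM_NAMES
        arr.element[sl] = "C"
        arr.hetero[sl] = False
    arr.coord = coords
    b = np.full(n, 90.0)
    if plddt:
        for r, (chain, resnum, _) in enumerate(chain_residue_centers):
            b[4 * r : 4 * r + 4] = plddt.get((chain, resnum), 90.0)
    arr.set_annotation("b_factor", b)
    arr.set_annotation("occupancy", np.ones(n))
    return StructureModel(arr, model_source="predicted")


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    return np.column_stack([np.cos(golden * i) * r, y, np.sin(golden * i) * r])


def generate_toy_structure(spec: ToyStructureSpec) -> StructureModel:
    """Build and verify a toy structure realizing the designed geometry.

    Compact clusters bury the designed residues (rel. SESA < 0.1,
    shell residues > 0.5); dimers bury >= 15 A^2 at exactly the designed
    interface residues.  Verification uses the package's own SASA and
    contact operations; an infeasible spec raises :class:`GeometryError`.
    """
    n = spec.n_residues
    track = None
    if spec.plddt_track is not None:
        track = np.asarray(spec.plddt_track, float)
        if len(track) != n:
            raise ValueError("plddt track length must equal n_residues")

    if spec.geometry == "helix":
        centers = []
        for i in range(n):
            theta = np.deg2rad(100.0) * i
            centers.append(
                ("A", i + 1, np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]))
            )
        plddt = (
            {("A", i + 1): track[i] for i in range(n)} if track is not None else None
        )
        return _build_atom_array(centers, plddt, spec.aa_sequence)

    if spec.geometry == "compact-cluster":
        buried = sorted(set(spec.designed_buried))
        if not buried or any(b < 1 or b > n for b in buried):
            raise ValueError("compact-cluster needs designed_buried within 1..n")
        shell_ids = [i for i in range(1, n + 1) if i not in buried]
        centers = []
        core_dirs = _fibonacci_directions(max(len(buried), 1))
        for j, resnum in enumerate(buried):
            centers.append(("A", resnum, 1.0 * core_dirs[j] if len(buried) > 1 else np.zeros(3)))
        # inner shell occludes the core; any further residues go to a
        # distant outer shell so they stay individually well exposed
        n_inner = min(len(shell_ids), 11)
        inner_r = 4.6 + 0.4 * (len(buried) > 1)
        inner_dirs = _fibonacci_directions(n_inner)
        for j, resnum in enumerate(shell_ids[:n_inner]):
            centers.append(("A", resnum, inner_r * inner_dirs[j]))
        outer = shell_ids[n_inner:]
        if outer:
            outer_dirs = _fibonacci_directions(len(outer))
            for j, resnum in enumerate(outer):
                centers.append(("A", resnum, 14.0 * outer_dirs[j]))
        centers.sort(key=lambda t: t[1])
        plddt = (
            {("A", i + 1): track[i] for i in range(n)} if track is not None else None
        )
        model = _build_atom_array(centers, plddt)
        _, table = sasa(model)
        rel = {
            int(r.residue_number): relative_sesa(r.sasa, r.aa_type)
            for r in table.itertuples()
        }
        for b in buried:
            if rel[b] >= 0.1:
                raise GeometryError(
                    f"designed buried residue {b} has rel. SESA {rel[b]:.2f}"
                )
        for s in shell_ids:
            if rel[s] <= 0.5:
                raise GeometryError(
                    f"designed surface residue {s} has rel. SESA {rel[s]:.2f}"
                )
        return model

    if spec.geometry == "two-chain-dimer":
        iface = sorted(set(spec.designed_interface))
        if not iface or any(i < 1 or i > n for i in iface):
            raise ValueError("dimer needs designed_interface within 1..n")
        spacing = 10.0
        near, far = 5.4, 40.0
        centers = []
        for i in range(1, n + 1):
            centers.append(("A", i, np.array([spacing * i, 0.0, 0.0])))
        for i in range(1, n + 1):
            y = near if i in iface else far
            centers.append(("B", i, np.array([spacing * i, y, 0.0])))
        plddt = None
        if track is not None:
            plddt = {}
            for i in range(n):
                plddt[("A", i + 1)] = track[i]
                plddt[("B", i + 1)] = track[i]
        model = _build_atom_array(centers, plddt)
        table = contact_residues(model, (["A"], ["B"]))
        got = {
            (r.chain, int(r.residue_number))
            for r in table.itertuples()
            if r.contact
        }
        want = {(c, i) for c in ("A", "B") for i in iface}
        if got != want:
            raise GeometryError(
                f"designed interface not realized: got {sorted(got)}, "
                f"wanted {sorted(want)}"
            )
        off_iface = table[~table["contact"]]
        if (off_iface["delta_sasa"].abs() > 1.0).any():
            raise GeometryError("non-interface residues lose > 1 A^2 on complexing")
        return model

    raise ValueError(f"unknown toy geometry {spec.geometry!r}")


def generate_paralog_pair(
    spec: ToyStructureSpec,
    deleted_residues_b: tuple[int, ...] = (),
    omega_a: np.ndarray | None = None,
    omega_b: np.ndarray | None = None,
) -> dict:
    """A structure and its rigidly transformed paralog copy.

    The copy shares residue numbering with the original, optionally with
    residues deleted, and carries planted per-residue omega tracks for
    the matched-residue comparison.  Returns a dict with models, the
    applied rotation/translation, and the truth ledger.
    """
    rng = np.random.default_rng(spec.seed)
    model_a = generate_toy_structure(spec)
    # random rotation from QR of a Gaussian matrix (deterministic per seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    translation = rng.uniform(-20, 20, size=3)
    atoms_b = model_a.atoms.copy()
    keep = ~np.isin(atoms_b.res_id, list(deleted_residues_b))
    atoms_b = atoms_b[keep]
    atoms_b.coord = atoms_b.coord @ q.T + translation
    model_b = StructureModel(atoms_b, model_source="predicted")
    n = spec.n_residues
    track_a = np.full(n, 0.2) if omega_a is None else np.asarray(omega_a, float)
    track_b = np.full(n, 0.2) if omega_b is None else np.asarray(omega_b, float)
    ledger = {
        "kind": "paralog_pair",
        "seed": int(spec.seed),
        "rotation": q.tolist(),
        "translation": translation.tolist(),
        "deleted_residues_b": [int(x) for x in deleted_residues_b],
        "omega_a": track_a.tolist(),
        "omega_b": track_b.tolist(),
    }
    return {
        "model_a": model_a,
        "model_b": model_b,
        "rotation": q,
        "translation": translation,
        "omega_a": track_a,
        "omega_b": track_b,
        "ledger": ledger,
    }


# ---------------------------------------------------------------------
# Population + outgroup with planted MK counts
# ---------------------------------------------------------------------

def simulate_population(
    n_haplotypes: int,
    n_codons: int,
    planted: tuple[int, int, int, int],
    seed: int,
    genetic_code: int = 1,
) -> dict:
    """Ingroup haplotypes plus outgroup with exact planted MK counts.

    ``planted`` is (PN, PS, DN, DS).  Each planted event is a single
    nucleotide change on its own codon: polymorphisms segregate in a
    random proper subset of haplotypes; fixed differences separate all
    haplotypes from the outgroup.  Raises if the targets cannot be
    realized on stop-free single-step neighbours.
    """
    pn, ps, dn, ds = planted
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    total = pn + ps + dn + ds
    if total > n_codons:
        raise ValueError("more planted events than codons")
    rng = np.random.default_rng(seed)
    code = get_code(genetic_code)
    pairs, kind = single_step_table(genetic_code)
    syn_from = {}
    nonsyn_from = {}
    for (i, j), k in zip(pairs, kind):
        target = syn_from if k < 2 else nonsyn_from
        target.setdefault(int(i), []).append(int(j))
    ancestor = rng.integers(0, code.n_codons, size=n_codons)
    order = rng.permutation(n_codons)
    events = (["PN"] * pn) + (["PS"] * ps) + (["DN"] * dn) + (["DS"] * ds)
    ingroup = np.tile(ancestor, (n_haplotypes, 1))
    outgroup = ancestor.copy()
    ledger_events = []
    pos_iter = iter(order)
    for ev in events:
        table = syn_from if ev in ("PS", "DS") else nonsyn_from
        site = None
        for cand in pos_iter:
            if int(ancestor[cand]) in table:
                site = int(cand)
                break
        if site is None:
            raise ValueError(f"targets infeasible: no codon available for {ev}")
        neighbours = table[int(ancestor[site])]
        new = neighbours[int(rng.integers(len(neighbours)))]
        if ev in ("PN", "PS"):
            k = int(rng.integers(1, n_haplotypes))  # proper subset, never fixed
            carriers = rng.choice(n_haplotypes, size=k, replace=False)
            ingroup[carriers, site] = new
        else:
            ingroup[:, site] = new
        ledger_events.append(
            {"type": ev, "codon_site_1based": site + 1,
             "from": code.codons[int(ancestor[site])], "to": code.codons[new]}
        )
    codon_strs = np.array(code.codons)
    taxa = [f"hap{i + 1}" for i in range(n_haplotypes)]
    seqs = ["".join(codon_strs[row]) for row in ingroup]
    aln = CodonAlignment(taxa, seqs, genetic_code=genetic_code)
    out_seq = "".join(codon_strs[outgroup])
    ledger = {
        "kind": "population",
        "seed": int(seed),
        "planted": {"PN": pn, "PS": ps, "DN": dn, "DS": ds},
        "events": ledger_events,
    }
    return {"ingroup": aln, "outgroup": out_seq, "ledger": ledger}


def write_ledger(ledger: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=1)


# ---------------------------------------------------------------------
# Complete fixture set for the end-to-end pipeline
# ---------------------------------------------------------------------

def make_fixture_set(outdir: str | Path, seed: int = 0) -> Path:
    """Write a self-contained synthetic input set plus a ready run config.

    One gene (codon alignment + tree + matching toy structure with a
    planted pLDDT track), one paralog structure pair with planted omega
    tracks, and one population + outgroup set with planted MK counts.
    Every dataset gets a truth-ledger JSON.  Returns the config path.
    """
    from selstruct.seqdata import write_codon_fasta
    from selstruct.struct_context import write_structure
    from selstruct._codes import translate_cds

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # gene: M8-style mixture so the site models have structure to find
    plan = m8_plan(0.5, 1.5, 0.9, 4.0)
    sim = simulate_codon_alignment(
        SimSpec(seed=seed, n_codons=60, kappa=2.0, n_taxa=5, depth=0.8,
                site_class_plan=plan)
    )
    write_codon_fasta(sim.alignment, outdir / "geneA.fasta")
    (outdir / "geneA.nwk").write_text(sim.newick + "\n")
    write_ledger(sim.ledger, outdir / "geneA.truth.json")
    ref_protein = translate_cds(sim.alignment.sequences[0])
    n_res = len(ref_protein)
    plddt = np.where(np.arange(n_res) < n_res // 3, 30.0, 90.0)
    structure = generate_toy_structure(
        ToyStructureSpec(
            n_residues=n_res, geometry="helix", plddt_track=plddt,
            aa_sequence=ref_protein, seed=seed,
        )
    )
    write_structure(structure, outdir / "geneA.pdb")

    # paralog pair: helix + transformed copy with deletions and a
    # planted delta-omega block
    n_par = 40
    pair_spec = ToyStructureSpec(n_residues=n_par, geometry="helix", seed=seed + 1)
    omega_a = np.full(n_par, 0.2)
    omega_a[10:20] = 0.7  # diverged block in paralog A
    omega_b = np.full(n_par, 0.2)
    pair = generate_paralog_pair(
        pair_spec, deleted_residues_b=(5, 6), omega_a=omega_a, omega_b=omega_b
    )
    write_structure(pair["model_a"], outdir / "paralogA.pdb")
    write_structure(pair["model_b"], outdir / "paralogB.pdb")
    for side, track in (("A", pair["omega_a"]), ("B", pair["omega_b"])):
        with open(outdir / f"paralog{side}.omega.tsv", "w") as fh:
            fh.write("residue\tomega\n")
            for i, w in enumerate(track):
                fh.write(f"{i + 1}\t{w:.4f}\n")
    write_ledger(pair["ledger"], outdir / "paralog.truth.json")

    # population + outgroup with planted MK counts
    pop = simulate_population(8, 40, planted=(3, 4, 5, 2), seed=seed + 2)
    write_codon_fasta(pop["ingroup"], outdir / "population.fasta")
    (outdir / "outgroup.fasta").write_text(
        ">outgroup\n" + pop["outgroup"] + "\n"
    )
    write_ledger(pop["ledger"], outdir / "population.truth.json")

    config = {
        "seed": int(seed),
        "output_dir": "results",
        "reference_taxon": "t1",
        "genes": [
            {
                "name": "geneA",
                "alignment": "geneA.fasta",
                "tree": "geneA.nwk",
                "structure": "geneA.pdb",
                "lineage": "synthetic",
            }
        ],
        "paralogs": [
            {
                "name": "paralogAB",
                "structure_a": "paralogA.pdb",
                "structure_b": "paralogB.pdb",
                "track_a": "paralogA.omega.tsv",
                "track_b": "paralogB.omega.tsv",
            }
        ],
        "mk": [
            {
                "name": "populationA",
                "ingroup": "population.fasta",
                "outgroup": "outgroup.fasta",
                "regions": {"first_half": [[1, 20]], "second_half": [[21, 40]]},
            }
        ],
        "thresholds": {"min_taxa": 5},
    }
    config_path = outdir / "config.yaml"
    import yaml

    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
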