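"""Per-residue structural context: exposure, disorder, and contacts.

Parses PDB/mmCIF models (per-residue confidence expected in the B-factor
column for predicted models), computes solvent-accessible surface area
with a deterministic Shrake–Rupley sampler, and classifies residues into
the buried / surface / contact-surface trichotomy:

* buried: relative solvent exposure (rel. SESA) < 0.3;
* surface: rel. SESA >= 0.3 in the monomeric form;
* contact surface: rel. SESA >= 0.3 in the monomeric form and burying
  >= 15 A^2 of accessible surface in the interface of a complex.

Residues with pLDDT < 50 are flagged as likely intrinsically disordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get_structure, set_structure as cif_set_structure

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
PLDDT_DISORDER_THRESHOLD = 50.0
REL_SESA_BURIED_THRESHOLD = 0.3
INTERFACE_DELTA_SASA = 15.0
VDW_OVERLAP_THRESHOLD = -0.4

#: fixed per-element van der Waals radii (A); hydrogens used if present,
#: never added.  Unknown elements fall back to the carbon radius.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
FALLBACK_RADIUS = 1.70

#: theoretical maximum solvent accessibility per residue type (A^2),
#: Tien et al. (2013) "theoretical" column; used to normalize residue
#: SASA into relative SESA.  Values may exceed the maximum in unusual
#: conformations, so rel. SESA is deliberately not clamped at 1.
MAX_SASA_THEORETICAL = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def three_to_one(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper(), "X")


@dataclass
class StructureModel:
    """A parsed structure: a biotite atom array plus element-resolved
    van der Waals radii.

    ``model_source="predicted"`` marks the B-factor column as carrying
    per-residue pLDDT confidence.
    """

    atoms: bst.AtomArray
    model_source: str = "predicted"

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite atom coordinates")
        elements = np.char.upper(self.atoms.element.astype("U2"))
        unknown = sorted(set(elements) - set(VDW_RADII))
        if unknown:
            warnings.warn(
                f"unknown elements {unknown}; using fallback radius "
                f"{FALLBACK_RADIUS} A",
                stacklevel=2,
            )
        self.radii = np.array([VDW_RADII.get(e, FALLBACK_RADIUS) for e in elements])

    # -- residue-level views -------------------------------------------
    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms.chain_id))

    def residue_starts(self) -> np.ndarray:
        return bst.get_residue_starts(self.atoms)

    def residue_table(self) -> pd.DataFrame:
        starts = self.residue_starts()
        return pd.DataFrame(
            {
                "chain": self.atoms.chain_id[starts],
                "residue_number": self.atoms.res_id[starts],
                "aa_type": self.atoms.res_name[starts],
            }
        )

    def plddt(self) -> np.ndarray:
        """Per-residue confidence read from the B-factor column."""
        starts = self.residue_starts()
        return self.atoms.b_factor[starts].astype(float)

    def subset_chains(self, chains: list[str]) -> "StructureModel":
        mask = np.isin(self.atoms.chain_id, chains)
        if not mask.any():
            raise ValueError(f"no atoms in chains {chains}")
        return StructureModel(self.atoms[mask], self.model_source)

    def ca_coords(self, chain: str | None = None):
        """(residue_number, coord) for CA (or first) atoms, one per residue."""
        atoms = self.atoms
        if chain is not None:
            atoms = atoms[atoms.chain_id == chain]
        starts = bst.get_residue_starts(atoms)
        nums, coords, names = [], [], []
        for i, s in enumerate(starts):
            e = starts[i + 1] if i + 1 < len(starts) else len(atoms)
            sel = np.where(atoms.atom_name[s:e] == "CA")[0]
            j = s + (sel[0] if len(sel) else 0)
            nums.append(int(atoms.res_id[j]))
            coords.append(atoms.coord[j])
            names.append(str(atoms.res_name[s]))
        return np.array(nums), np.array(coords), names


def read_structure(
    path: str | Path, format: str | None = None, model_source: str = "predicted"
) -> StructureModel:
    """Read a PDB or mmCIF file (first model; highest-occupancy altlocs)."""
    path = Path(path)
    fmt = format or ("mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB")
    if fmt.upper() == "PDB":
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    elif fmt.lower() in ("mmcif", "cif", "pdbx"):
        cif = CIFFile.read(str(path))
        arr = cif_get_structure(
            cif, model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    else:
        raise ValueError(f"unknown structure format {format!r}")
    finite = np.all(np.isfinite(arr.coord), axis=1)
    if not finite.all():
        warnings.warn(f"skipping {int((~finite).sum())} atoms with missing coordinates")
        arr = arr[finite]
    return StructureModel(arr, model_source)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write PDB or mmCIF depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        cif = CIFFile()
        cif_set_structure(cif, model.atoms)
        cif.write(str(path))
    else:
        pdb = PDBFile()
        pdb.set_structure(model.atoms)
        pdb.write(str(path))


# ---------------------------------------------------------------------
# Shrake-Rupley SASA on a deterministic Fibonacci sphere lattice
# ---------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    theta = golden * i
    return np.column_stack([np.cos(theta) * r, y, np.sin(theta) * r])


def sasa(
    model: StructureModel,
    chains: list[str] | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-atom and per-residue solvent-accessible surface area (A^2).

    Shrake–Rupley: each atom's probe-expanded sphere is sampled on a
    fixed Fibonacci lattice of ``n_sphere_points``; a sample point is
    accessible if it lies outside every other atom's expanded sphere.
    Deterministic for identical input.
    """
    sub = model if chains is None else model.subset_chains(chains)
    coords = sub.atoms.coord.astype(float)
    radii = sub.radii + probe_radius
    n = len(coords)
    lattice = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    atom_sasa = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * lattice
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = np.sum(
                (pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2
            )
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom_sasa[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    starts = sub.residue_starts()
    res_sasa = np.add.reduceat(atom_sasa, starts)
    table = sub.residue_table()
    table["sasa"] = res_sasa
    return atom_sasa, table


def relative_sesa(residue_sasa: float, aa_type: str, max_table: dict | None = None) -> float:
    """Residue SASA divided by its theoretical maximum exposure.

    Not clamped at 1: values above 1 flag unusual conformations rather
    than being hidden.
    """
    table = max_table or MAX_SASA_THEORETICAL
    key = aa_type.upper()
    if key not in table:
        raise KeyError(f"no theoretical maximum SASA for residue type {aa_type!r}")
    return float(residue_sasa) / table[key]


# ---------------------------------------------------------------------
# Interface detection and classification
# ---------------------------------------------------------------------

@dataclass
class ResidueContext:
    """Structural context of one residue."""

    chain: str
    residue_number: int
    aa_type: str
    sasa_monomer: float
    rel_sesa: float
    burial_category: str  # buried | surface | contact
    sasa_complex: float = float("nan")
    delta_sasa: float = float("nan")
    plddt: float = float("nan")
    disorder: bool | None = None


def contact_residues(
    complex_model: StructureModel,
    chain_groups: tuple[list[str], list[str]],
    delta_sasa_threshold: float = INTERFACE_DELTA_SASA,
    min_rel_sesa: float = REL_SESA_BURIED_THRESHOLD,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> pd.DataFrame:
    """Interface residues of a two-sided complex.

    For every residue, delta-SASA = SASA(own side alone) - SASA(complex).
    Residues burying >= ``delta_sasa_threshold`` (15 A^2) that are also
    exposed in the monomeric form (rel. SESA >= 0.3) are labeled contact.
    Returns the full per-residue table with a boolean ``contact`` column.
    """
    side_a, side_b = (list(g) for g in chain_groups)
    if not side_a or not side_b:
        raise ValueError("both chain groups must be non-empty")
    if set(side_a) & set(side_b):
        raise ValueError("chain groups overlap")
    tables = []
    for side in (side_a, side_b):
        _, mono = sasa(complex_model, side, probe_radius, n_sphere_points)
        tables.append(mono)
    mono_table = pd.concat(tables, ignore_index=True)
    _, full = sasa(
        complex_model, side_a + side_b, probe_radius, n_sphere_points
    )
    merged = mono_table.merge(
        full,
        on=["chain", "residue_number", "aa_type"],
        suffixes=("_monomer", "_complex"),
        validate="one_to_one",
    )
    merged["delta_sasa"] = merged["sasa_monomer"] - merged["sasa_complex"]
    merged["rel_sesa"] = [
        relative_sesa(s, aa) if aa in MAX_SASA_THEORETICAL else float("nan")
        for s, aa in zip(merged["sasa_monomer"], merged["aa_type"])
    ]
    merged["contact"] = (merged["delta_sasa"] >= delta_sasa_threshold) & (
        merged["rel_sesa"] >= min_rel_sesa
    )
    return merged


def classify(
    model: StructureModel,
    chain_groups: tuple[list[str], list[str]] | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
    plddt_threshold: float = PLDDT_DISORDER_THRESHOLD,
) -> list[ResidueContext]:
    """Classify every residue as buried / surface / contact.

    Without ``chain_groups`` the model is treated as a monomer and no
    residue can be a contact.  Disorder flags come from pLDDT < 50 when
    the model is a predicted one.
    """
    has_plddt = model.model_source == "predicted"
    plddt = model.plddt() if has_plddt else None
    if chain_groups is None:
        _, table = sasa(model, None, probe_radius, n_sphere_points)
        table["delta_sasa"] = float("nan")
        table["sasa_complex"] = float("nan")
        table["contact"] = False
        table = table.rename(columns={"sasa": "sasa_monomer"})
        table["rel_sesa"] = [
            relative_sesa(s, aa) if aa in MAX_SASA_THEORETICAL else float("nan")
            for s, aa in zip(table["sasa_monomer"], table["aa_type"])
        ]
    else:
        table = contact_residues(
            model, chain_groups, probe_radius=probe_radius,
            n_sphere_points=n_sphere_points,
        )
    contexts: list[ResidueContext] = []
    full_res = model.residue_table()
    key_to_row = {
        (r.chain, r.residue_number): i for i, r in enumerate(table.itertuples())
    }
    for i, row in enumerate(full_res.itertuples()):
        j = key_to_row.get((row.chain, row.residue_number))
        if j is None:
            continue
        trow = table.iloc[j]
        rel = trow["rel_sesa"]
        if rel < REL_SESA_BURIED_THRESHOLD:
            category = "buried"
        elif bool(trow["contact"]):
            category = "contact"
        else:
            category = "surface"
        conf = float(plddt[i]) if plddt is not None else float("nan")
        contexts.append(
            ResidueContext(
                chain=str(row.chain),
                residue_number=int(row.residue_number),
                aa_type=str(row.aa_type),
                sasa_monomer=float(trow["sasa_monomer"]),
                rel_sesa=float(rel),
                burial_category=category,
                sasa_complex=float(trow.get("sasa_complex", float("nan"))),
                delta_sasa=float(trow.get("delta_sasa", float("nan"))),
                plddt=conf,
                disorder=(conf < plddt_threshold) if plddt is not None else None,
            )
        )
    return contexts


def contexts_to_frame(contexts: list[ResidueContext]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": [c.chain for c in contexts],
            "residue_number": [c.residue_number for c in contexts],
            "aa": [three_to_one(c.aa_type) for c in contexts],
            "sasa_monomer": [c.sasa_monomer for c in contexts],
            "sasa_complex": [c.sasa_complex for c in contexts],
            "delta_sasa": [c.delta_sasa for c in contexts],
            "rel_sesa": [c.rel_sesa for c in contexts],
            "plddt": [c.plddt for c in contexts],
            "disorder": [c.disorder for c in contexts],
            "category": [c.burial_category for c in contexts],
        }
    )


# ---------------------------------------------------------------------
# Atom-level van der Waals contacts
# ---------------------------------------------------------------------

@dataclass
class AtomContact:
    atom_a: str
    atom_b: str
    distance: float
    overlap: float


def vdw_contacts(
    model: StructureModel,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    overlap_threshold: float = VDW_OVERLAP_THRESHOLD,
) -> list[AtomContact]:
    """Atom pairs between two residues with van der Waals overlap
    ``r_i + r_j - d >= threshold`` (default -0.4 A, i.e. near-touching
    atoms count as interacting).  The residues are in contact iff the
    returned list is non-empty.
    """
    def _mask(chain: str, num: int) -> np.ndarray:
        m = (model.atoms.chain_id == chain) & (model.atoms.res_id == num)
        if not m.any():
            raise KeyError(f"residue {num} of chain {chain} not in structure")
        return m

    ma, mb = _mask(*residue_a), _mask(*residue_b)
    ia, ib = np.where(ma)[0], np.where(mb)[0]
    coords = model.atoms.coord
    d = np.linalg.norm(coords[ia][:, None, :] - coords[ib][None, :, :], axis=2)
    overlap = model.radii[ia][:, None] + model.radii[ib][None, :] - d
    out: list[AtomContact] = []
    for i, j in zip(*np.where(overlap >= overlap_threshold)):
        out.append(
            AtomContact(
                atom_a=str(model.atoms.atom_name[ia[i]]),
                atom_b=str(model.atoms.atom_name[ib[j]]),
                distance=float(d[i, j]),
                overlap=float(overlap[i, j]),
            )
        )
    return out
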