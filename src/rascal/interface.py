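"""Protein-protein interface analysis.

Implements the four quantities used to characterise the KRAS-RBD and KRAS-CRD
interfaces: typed inter-chain contacts (hydrogen bonds, salt bridges,
non-bonded contacts, with PDBSum-style criteria), Shrake-Rupley solvent
accessible surface areas and the per-partner area buried on complexation,
interface residue sets, and zinc-finger coordination sites.

Contact criteria (X-ray case, no explicit hydrogens):

* hydrogen bond: donor N/O/S to acceptor N/O/S, distance <= 3.5 Å, with
  donor/acceptor typing from a residue-atom dictionary; when hydrogens are
  present, additionally H...A <= 2.5 Å and D-H...A >= 90 deg (HBPLUS-style);
* salt bridge: Asp/Glu carboxylate O (or C-terminal OXT) to Lys NZ,
  Arg NE/NH1/NH2 or His ND1/NE2, distance <= 4.0 Å;
* non-bonded contact: any other inter-partner heavy-atom pair <= 3.9 Å.

A qualifying atom pair is classified once, with precedence
salt bridge > hydrogen bond > non-bonded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._chem import (ANIONIC_ATOMS, CATIONIC_ATOMS, HB_ACCEPTORS, HB_DONORS,
                    ZN_LIGAND_ATOMS, vdw_radius)
from .structio import AtomRecord, Selection, StructureModel, coords_of, select_atoms

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "InterfaceReport",
    "ZincSite",
    "sasa",
    "sphere_points",
    "buried_sasa",
    "enumerate_contacts",
    "interface_report",
    "find_zinc_sites",
]

DEFAULT_PROBE = 1.4   # Å, water probe
DEFAULT_POINTS = 960  # quadrature points per atom


@dataclass(frozen=True)
class ContactCriteria:
    hbond_cutoff: float = 3.5        # Å, donor-acceptor
    saltbridge_cutoff: float = 4.0   # Å, charged N/O pair
    nonbonded_cutoff: float = 3.9    # Å, any heavy pair
    h_acceptor_cutoff: float = 2.5   # Å, only with explicit hydrogens
    donor_angle_min: float = 90.0    # deg, D-H...A, only with explicit H

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond_cutoff, self.saltbridge_cutoff, self.nonbonded_cutoff)


@dataclass
class ContactRecord:
    type: str                     # hbond | saltbridge | nonbonded
    atom_a: tuple                 # (chain, res_seq, icode, res_name, atom_name)
    atom_b: tuple
    distance: float               # Å
    h_acceptor_distance: float | None = None
    donor_angle: float | None = None


@dataclass
class ZincSite:
    zinc: tuple                               # atom identity tuple
    coordinating: list[tuple[str, int, str, str, float]]  # (chain, res, res_name, atom, dist)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        seen = {(chain, res, res_name)
                for chain, res, res_name, _atom, _d in self.coordinating}
        return sorted(seen)


@dataclass
class InterfaceReport:
    contacts: list[ContactRecord]
    n_hbonds: int
    n_saltbridges: int
    n_nonbonded: int
    interface_residues_a: list[tuple[str, int, str]]
    interface_residues_b: list[tuple[str, int, str]]
    buried_sasa_a: float
    buried_sasa_b: float

    def to_dict(self) -> dict:
        return {
            "n_hbonds": self.n_hbonds,
            "n_saltbridges": self.n_saltbridges,
            "n_nonbonded": self.n_nonbonded,
            "n_interface_residues_a": len(self.interface_residues_a),
            "n_interface_residues_b": len(self.interface_residues_b),
            "interface_residues_a": [list(r) for r in self.interface_residues_a],
            "interface_residues_b": [list(r) for r in self.interface_residues_b],
            "buried_sasa_a_A2": self.buried_sasa_a,
            "buried_sasa_b_A2": self.buried_sasa_b,
        }

    def contacts_table(self):
        """Contacts as a pandas DataFrame (TSV-ready)."""
        import pandas as pd
        rows = []
        for c in self.contacts:
            rows.append({
                "type": c.type,
                "chain_a": c.atom_a[0], "res_a": c.atom_a[1], "resname_a": c.atom_a[3],
                "atom_a": c.atom_a[4],
                "chain_b": c.atom_b[0], "res_b": c.atom_b[1], "resname_b": c.atom_b[3],
                "atom_b": c.atom_b[4],
                "distance_A": round(c.distance, 3),
            })
        return pd.DataFrame(rows, columns=["type", "chain_a", "res_a", "resname_a", "atom_a",
                                           "chain_b", "res_b", "resname_b", "atom_b",
                                           "distance_A"])


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere point set (n, 3)."""
    if n < 32:
        raise ValueError("need at least 32 quadrature points")
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i   # golden angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sasa_arrays(coords: np.ndarray, radii: np.ndarray, probe: float,
                 n_points: int) -> np.ndarray:
    """Per-atom Shrake-Rupley areas for raw coordinate/radius arrays."""
    n = coords.shape[0]
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i]
        surface = coords[i] + ri * pts
        if neigh:
            nc = coords[neigh]
            nr = expanded[np.asarray(neigh)]
            # keep only neighbours actually intersecting this sphere
            d = np.linalg.norm(nc - coords[i], axis=1)
            close = d < ri + nr
            nc, nr = nc[close], nr[close]
            if len(nc):
                d2 = ((surface[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
                buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * ri * ri * frac
    return areas


def _heavy_atoms(atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if not a.is_hydrogen and not a.is_water]


def sasa(model: StructureModel | list[AtomRecord], probe_radius: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_POINTS,
         radius_overrides: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom solvent-accessible areas (Å²), Shrake-Rupley quadrature.

    Accepts a model (heavy, non-water atoms considered) or an explicit atom
    list. Deterministic for a fixed point count: the quadrature grid is a
    golden-spiral set, not random. An atom of unknown element raises unless a
    radius override is supplied.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    atoms = list(model.atoms()) if isinstance(model, StructureModel) else list(model)
    atoms = _heavy_atoms(atoms)
    coords = coords_of(atoms)
    radii = np.array([vdw_radius(a.element, radius_overrides) for a in atoms])
    return _sasa_arrays(coords, radii, probe_radius, n_points)


def buried_sasa(model: StructureModel, partner_a: Selection, partner_b: Selection,
                probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_POINTS,
                radius_overrides: dict[str, float] | None = None,
                ) -> tuple[float, float]:
    """Per-partner buried area: SASA(partner isolated) - SASA(partner in the
    two-partner complex), clamped at zero."""
    atoms_a = _heavy_atoms(select_atoms(model, partner_a, require_nonempty=True))
    atoms_b = _heavy_atoms(select_atoms(model, partner_b, require_nonempty=True))
    keys_a = {a.atom_key for a in atoms_a}
    if keys_a & {b.atom_key for b in atoms_b}:
        raise ValueError("partner selections overlap")
    iso_a = sasa(atoms_a, probe, n_points, radius_overrides)
    iso_b = sasa(atoms_b, probe, n_points, radius_overrides)
    both = sasa(atoms_a + atoms_b, probe, n_points, radius_overrides)
    complex_a = both[: len(atoms_a)].sum()
    complex_b = both[len(atoms_a):].sum()
    return (max(0.0, float(iso_a.sum() - complex_a)),
            max(0.0, float(iso_b.sum() - complex_b)))


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _atom_id(a: AtomRecord) -> tuple:
    return (a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name)


def _is_donor(a: AtomRecord) -> bool:
    if a.atom_name == "N" and a.element == "N" and a.res_name != "PRO":
        return True  # backbone amide
    return a.atom_name in HB_DONORS.get(a.res_name, set())


def _is_acceptor(a: AtomRecord) -> bool:
    if a.atom_name in ("O", "OXT") and a.element == "O":
        return True  # backbone carbonyl / C-terminal carboxylate
    return a.atom_name in HB_ACCEPTORS.get(a.res_name, set())


def _is_anionic(a: AtomRecord) -> bool:
    if a.atom_name == "OXT":
        return True
    return a.atom_name in ANIONIC_ATOMS.get(a.res_name, set())


def _is_cationic(a: AtomRecord) -> bool:
    return a.atom_name in CATIONIC_ATOMS.get(a.res_name, set())


def _hydrogens_of(model_atoms: list[AtomRecord], donor: AtomRecord) -> list[AtomRecord]:
    """Hydrogens bonded to a donor heavy atom (same residue, within 1.3 Å)."""
    out = []
    for a in model_atoms:
        if a.is_hydrogen and a.residue_key == donor.residue_key:
            if np.linalg.norm(a.coords - donor.coords) < 1.3:
                out.append(a)
    return out


def _hbond_geometry_ok(model_atoms: list[AtomRecord], donor: AtomRecord,
                       acceptor: AtomRecord, criteria: ContactCriteria,
                       ) -> tuple[bool, float | None, float | None]:
    """Explicit-hydrogen check; vacuously true when the donor has no H."""
    hydrogens = _hydrogens_of(model_atoms, donor)
    if not hydrogens:
        return True, None, None
    best: tuple[bool, float | None, float | None] = (False, None, None)
    for h in hydrogens:
        ha = float(np.linalg.norm(h.coords - acceptor.coords))
        v1 = donor.coords - h.coords
        v2 = acceptor.coords - h.coords
        cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if ha <= criteria.h_acceptor_cutoff and ang >= criteria.donor_angle_min:
            return True, ha, ang
        if best[1] is None or ha < best[1]:
            best = (False, ha, ang)
    return best


def enumerate_contacts(model: StructureModel, partner_a: Selection,
                       partner_b: Selection,
                       criteria: ContactCriteria | None = None,
                       ) -> list[ContactRecord]:
    """All qualifying inter-partner atom pairs, each classified once.

    Symmetric in partner order (up to swapping atom_a/atom_b in the records).
    """
    criteria = criteria or ContactCriteria()
    atoms_a = _heavy_atoms(select_atoms(model, partner_a))
    atoms_b = _heavy_atoms(select_atoms(model, partner_b))
    if {a.atom_key for a in atoms_a} & {b.atom_key for b in atoms_b}:
        raise ValueError("partner selections overlap")
    if not atoms_a or not atoms_b:
        return []
    all_atoms = list(model.atoms())
    ca = coords_of(atoms_a)
    cb = coords_of(atoms_b)
    tree_b = cKDTree(cb)
    records: list[ContactRecord] = []
    pairs = tree_b.query_ball_point(ca, criteria.max_cutoff)
    for i, hits in enumerate(pairs):
        a = atoms_a[i]
        for j in sorted(hits):
            b = atoms_b[j]
            d = float(np.linalg.norm(ca[i] - cb[j]))
            rec = _classify_pair(all_atoms, a, b, d, criteria)
            if rec is not None:
                records.append(rec)
    records.sort(key=lambda r: (r.atom_a[:3], r.atom_b[:3], r.atom_a[4], r.atom_b[4]))
    return records


def _classify_pair(all_atoms: list[AtomRecord], a: AtomRecord, b: AtomRecord,
                   d: float, criteria: ContactCriteria) -> ContactRecord | None:
    # precedence: salt bridge > hydrogen bond > non-bonded
    if d <= criteria.saltbridge_cutoff:
        if (_is_anionic(a) and _is_cationic(b)) or (_is_cationic(a) and _is_anionic(b)):
            return ContactRecord("saltbridge", _atom_id(a), _atom_id(b), d)
    if d <= criteria.hbond_cutoff and a.element in ("N", "O", "S") and b.element in ("N", "O", "S"):
        for donor, acceptor in ((a, b), (b, a)):
            if _is_donor(donor) and _is_acceptor(acceptor):
                ok, ha, ang = _hbond_geometry_ok(all_atoms, donor, acceptor, criteria)
                if ok:
                    return ContactRecord("hbond", _atom_id(a), _atom_id(b), d,
                                         h_acceptor_distance=ha, donor_angle=ang)
    if d <= criteria.nonbonded_cutoff:
        return ContactRecord("nonbonded", _atom_id(a), _atom_id(b), d)
    return None


def interface_report(model: StructureModel, partner_a: Selection,
                     partner_b: Selection, criteria: ContactCriteria | None = None,
                     probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_POINTS,
                     ) -> InterfaceReport:
    """Aggregate contacts, buried areas, and interface residue sets.

    A residue is an interface residue of a partner iff it loses solvent
    accessible area in the complex or participates in at least one contact.
    """
    contacts = enumerate_contacts(model, partner_a, partner_b, criteria)
    atoms_a = _heavy_atoms(select_atoms(model, partner_a, require_nonempty=True))
    atoms_b = _heavy_atoms(select_atoms(model, partner_b, require_nonempty=True))
    iso_a = sasa(atoms_a, probe, n_points)
    iso_b = sasa(atoms_b, probe, n_points)
    both = sasa(atoms_a + atoms_b, probe, n_points)
    cplx_a = both[: len(atoms_a)]
    cplx_b = both[len(atoms_a):]
    buried_a = max(0.0, float(iso_a.sum() - cplx_a.sum()))
    buried_b = max(0.0, float(iso_b.sum() - cplx_b.sum()))

    def _interface_residues(atoms, iso, cplx, contact_ids):
        lost: dict[tuple, float] = {}
        names: dict[tuple, tuple] = {}
        for atom, ai, ci in zip(atoms, iso, cplx):
            key = atom.residue_key
            lost[key] = lost.get(key, 0.0) + (ai - ci)
            names[key] = (atom.chain_id, atom.res_seq, atom.icode)
        out = {names[k] for k, v in lost.items() if v > 1e-6}
        out |= contact_ids
        return sorted(out, key=lambda r: (r[0], r[1], r[2]))

    ids_a = {(c.atom_a[0], c.atom_a[1], c.atom_a[2]) for c in contacts}
    ids_b = {(c.atom_b[0], c.atom_b[1], c.atom_b[2]) for c in contacts}
    res_a = _interface_residues(atoms_a, iso_a, cplx_a, ids_a)
    res_b = _interface_residues(atoms_b, iso_b, cplx_b, ids_b)
    counts = {"hbond": 0, "saltbridge": 0, "nonbonded": 0}
    for c in contacts:
        counts[c.type] += 1
    return InterfaceReport(
        contacts=contacts,
        n_hbonds=counts["hbond"],
        n_saltbridges=counts["saltbridge"],
        n_nonbonded=counts["nonbonded"],
        interface_residues_a=res_a,
        interface_residues_b=res_b,
        buried_sasa_a=buried_a,
        buried_sasa_b=buried_b,
    )


# ---------------------------------------------------------------------------
# Zinc sites
# ---------------------------------------------------------------------------

def find_zinc_sites(model: StructureModel, coordination_cutoff: float = 2.8,
                    min_residues: int = 3) -> list[ZincSite]:
    """One site per Zn atom with >= ``min_residues`` coordinating residues.

    Coordinating atoms are Cys SG, His ND1/NE2, and Asp/Glu carboxylate
    oxygens within the cutoff (default 2.8 Å, generous for Zn-S at ~2.3 Å).
    """
    zincs = [a for a in model.atoms() if a.element == "ZN"]
    if not zincs:
        return []
    ligand_atoms = [a for a in model.atoms()
                    if a.atom_name in ZN_LIGAND_ATOMS.get(a.res_name, set())]
    sites = []
    for zn in zincs:
        coord = []
        for a in ligand_atoms:
            d = float(np.linalg.norm(a.coords - zn.coords))
            if d <= coordination_cutoff:
                coord.append((a.chain_id, a.res_seq, a.res_name, a.atom_name, d))
        coord.sort(key=lambda c: c[4])
        n_res = len({(c[0], c[1]) for c in coord})
        if n_res >= min_residues:
            sites.append(ZincSite(zinc=_atom_id(zn), coordinating=coord))
    return sites
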