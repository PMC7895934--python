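"""Synthetic fixtures with exact ground truth.

Every test stage of the package can run without downloads: this module
generates two-chain complexes with planted hydrogen bonds, salt bridges and
non-bonded contacts; rigid-body-perturbed copies of a domain with known
rotation/translation; planar pseudo-lipid slabs standing in for a 7:3
POPC:POPS bilayer; pose ensembles with known (tilt, rotation, d_Gz); and
noisy Langmuir isotherms with known K_D.

Scaffolds are idealised poly-alanine α-helices (rise 1.5 Å per residue, twist
100°/residue) with substituted side-chain pseudo-atoms where donor/acceptor
or charged chemistry is required. Chains of a planted complex sit with their
helix axes 14 Å apart so that *only* the planted atom pairs fall inside the
interface module's detection cutoffs: planted sites are strided three
residues apart (4.5 Å along the axis), which keeps every cross-site and
backbone pair strictly outside 4.0 Å.

All generators take an explicit seed and are bit-reproducible; each uses its
own named numpy Generator and no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .binding import IsothermData, langmuir
from .membrane import (ALPHA4_RANGE, ALPHA5_RANGE, CRD_LOOP_RANGES,
                       GDOMAIN_RANGE, MembraneFrame, PoseAngles,
                       construct_pose, _bin_center, _wrap_angle)
from .structio import AtomRecord, Selection, StructureModel, select_atoms
from .superpose import RigidMotion

__all__ = [
    "CapacityError",
    "PlantedComplexTruth",
    "PoseEnsembleTruth",
    "PoseRecord",
    "DgzBinModel",
    "make_planted_complex",
    "make_perturbed_copy",
    "make_lipid_slab",
    "make_kras_like",
    "make_complex_like",
    "make_pose_ensemble",
    "make_isotherm",
    "make_zinc_cage",
    "write_fixture",
]

HELIX_RISE = 1.5        # Å per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Å, Cα radius
SITE_STRIDE = 3         # planted sites every 3 residues (4.5 Å apart)
CHAIN_GAP = 14.0        # Å between helix axes of a planted complex
MAX_SITES = 60

# planted-distance windows, strictly inside the detection cutoffs
HBOND_RANGE = (2.75, 3.35)        # donor-acceptor, cutoff 3.5
SALTBRIDGE_RANGE = (3.30, 3.90)   # charged pair, cutoff 4.0
NONBONDED_RANGE = (3.55, 3.85)    # C...C, cutoff 3.9


class CapacityError(ValueError):
    """More planted contacts requested than the scaffold can hold."""


@dataclass
class PlantedComplexTruth:
    """Exact planted inter-chain contacts; pairs are
    ((chain, res_seq, atom_name), (chain, res_seq, atom_name), distance)."""

    hbonds: list[tuple] = field(default_factory=list)
    saltbridges: list[tuple] = field(default_factory=list)
    nonbonded: list[tuple] = field(default_factory=list)
    buried_positive: bool = True
    seed: int = 0

    def counts(self) -> tuple[int, int, int]:
        return (len(self.hbonds), len(self.saltbridges), len(self.nonbonded))


# ---------------------------------------------------------------------------
# helix scaffolds
# ---------------------------------------------------------------------------

def _helix_atoms(chain_id: str, n_res: int, origin: np.ndarray,
                 start_res: int = 1) -> list[AtomRecord]:
    """Poly-alanine backbone (N, CA, C, O) along the +x axis."""
    atoms = []
    origin = np.asarray(origin, float)
    for i in range(n_res):
        ang = math.radians(HELIX_TWIST * i)
        ca = origin + np.array([HELIX_RISE * i,
                                HELIX_RADIUS * math.cos(ang),
                                HELIX_RADIUS * math.sin(ang)])
        res_seq = start_res + i
        offs = {
            "N": np.array([-0.52, 0.40, 0.30]),
            "CA": np.zeros(3),
            "C": np.array([0.55, -0.40, 0.20]),
            "O": np.array([0.75, -0.90, 0.65]),
        }
        for name, off in offs.items():
            atoms.append(AtomRecord(chain_id=chain_id, res_seq=res_seq, icode="",
                                    res_name="ALA", atom_name=name,
                                    element=name[0], coords=ca + off))
    return atoms


_SITE_CHEMISTRY = {
    # type -> (resname_a, atom_a, elem_a, resname_b, atom_b, elem_b, d-window)
    "hbond": ("SER", "OG", "O", "SER", "OG", "O", HBOND_RANGE),
    "saltbridge": ("ASP", "OD1", "O", "LYS", "NZ", "N", SALTBRIDGE_RANGE),
    "nonbonded": ("ALA", "CB", "C", "ALA", "CB", "C", NONBONDED_RANGE),
}


def make_planted_complex(n_hbonds: int, n_saltbridges: int, n_nonbonded: int,
                         seed: int) -> tuple[StructureModel, PlantedComplexTruth]:
    """Two-chain complex whose inter-chain contacts are exactly the planted
    ones under the interface module's default criteria."""
    for n in (n_hbonds, n_saltbridges, n_nonbonded):
        if n < 0:
            raise ValueError("contact counts must be >= 0")
    n_sites = n_hbonds + n_saltbridges + n_nonbonded
    if n_sites > MAX_SITES:
        raise CapacityError(
            f"{n_sites} planted contacts exceed the scaffold capacity ({MAX_SITES})")
    rng = np.random.default_rng(seed)
    n_res = max(10, SITE_STRIDE * n_sites + 4)
    atoms_a = _helix_atoms("A", n_res, origin=np.zeros(3))
    atoms_b = _helix_atoms("B", n_res, origin=np.array([0.0, CHAIN_GAP, 0.0]))

    types = (["hbond"] * n_hbonds + ["saltbridge"] * n_saltbridges
             + ["nonbonded"] * n_nonbonded)
    order = rng.permutation(len(types))
    truth = PlantedComplexTruth(seed=seed)
    by_residue_a = {a.res_seq: a for a in atoms_a if a.atom_name == "CA"}
    extra_a, extra_b = [], []
    for k, idx in enumerate(order):
        ctype = types[idx]
        res_a, atom_a, el_a, res_b, atom_b, el_b, (dlo, dhi) = _SITE_CHEMISTRY[ctype]
        site_res = 3 + SITE_STRIDE * k          # residue index, 1-based
        d = float(rng.uniform(dlo, dhi))
        x = by_residue_a[site_res].coords[0]    # CA x of the site residue
        ya = 5.0
        pa = np.array([x, ya, 0.0])
        pb = np.array([x, ya + d, 0.0])
        # retype the site residues and attach the pseudo side-chain atoms
        for lst, cid, rname, aname, elem, pos in (
                (extra_a, "A", res_a, atom_a, el_a, pa),
                (extra_b, "B", res_b, atom_b, el_b, pb)):
            lst.append(AtomRecord(chain_id=cid, res_seq=site_res, icode="",
                                  res_name=rname, atom_name=aname,
                                  element=elem, coords=pos))
        for atom in atoms_a:
            if atom.res_seq == site_res:
                atom.res_name = res_a
        for atom in atoms_b:
            if atom.res_seq == site_res:
                atom.res_name = res_b
        pair = (("A", site_res, atom_a), ("B", site_res, atom_b), d)
        getattr(truth, {"hbond": "hbonds", "saltbridge": "saltbridges",
                        "nonbonded": "nonbonded"}[ctype]).append(pair)

    # interleave pseudo-atoms into their residues, preserving model order
    merged = []
    extras = {(a.chain_id, a.res_seq): a for a in extra_a + extra_b}
    for atom in atoms_a + atoms_b:
        merged.append(atom)
        if atom.atom_name == "O":
            extra = extras.pop((atom.chain_id, atom.res_seq), None)
            if extra is not None:
                merged.append(extra)
    model = StructureModel.from_atoms(merged, id=f"planted-{seed}")
    model.validate()
    return model, truth


# ---------------------------------------------------------------------------
# rigid perturbation
# ---------------------------------------------------------------------------

def make_perturbed_copy(model: StructureModel, domain_sel: Selection,
                        axis: np.ndarray, angle_deg: float, screw_disp: float,
                        seed: int = 0) -> tuple[StructureModel, RigidMotion]:
    """Rotate a domain about ``axis`` through its centroid and translate it
    ``screw_disp`` along the axis; all other atoms are unchanged.

    Angles outside [0, 180] are normalised by flipping the axis, never an
    error. The returned truth is the motion ``domain_motion`` should recover.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    angle = _wrap_angle(float(angle_deg))
    screw = float(screw_disp)
    if angle < 0:
        angle, axis, screw = -angle, -axis, -screw
    out = model.copy()
    atoms = select_atoms(out, domain_sel)
    if not atoms:
        raise ValueError("domain selection is empty")
    centroid = np.mean([a.coords for a in atoms], axis=0)
    c, s = math.cos(math.radians(angle)), math.sin(math.radians(angle))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * K @ K
    shift = screw * axis
    for atom in atoms:
        atom.coords = R @ (atom.coords - centroid) + centroid + shift
    truth = RigidMotion(rotation_angle=angle, axis=axis,
                        screw_displacement=screw,
                        centroid_shift=abs(screw),
                        n_domain_atoms=len(atoms))
    return out, truth


# ---------------------------------------------------------------------------
# membranes
# ---------------------------------------------------------------------------

def make_lipid_slab(x_extent: float, y_extent: float, spacing: float,
                    headgroup_z: float, thickness: float) -> MembraneFrame:
    """Two planar pseudo-atom grids standing in for a bilayer.

    Leaflets sit at z = headgroup_z and z = headgroup_z - thickness; the
    bilayer centre of mass is on the mid-plane and the normal is +z.
    """
    if spacing <= 0 or thickness <= 0:
        raise ValueError("spacing and thickness must be positive")
    nx = int(math.floor(x_extent / spacing)) + 1
    ny = int(math.floor(y_extent / spacing)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    leaflet = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    top = leaflet + np.array([0, 0, headgroup_z])
    bottom = leaflet + np.array([0, 0, headgroup_z - thickness])
    coords = np.vstack([top, bottom])
    return MembraneFrame(lipid_coords=coords, normal=np.array([0.0, 0.0, 1.0]),
                         com=coords.mean(axis=0),
                         headgroup_offset=headgroup_z)


# ---------------------------------------------------------------------------
# KRAS-like reference bodies
# ---------------------------------------------------------------------------

def _golden_blob(n: int, center: np.ndarray, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points in a ball (golden spiral shells)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r_sph = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    shell = radius * (i / n) ** (1.0 / 3.0)
    pts = np.column_stack([r_sph * np.cos(phi), r_sph * np.sin(phi), z])
    return center + pts * shell[:, None]


def _vertical_helix(n: int, center_x: float, z0: float) -> list[np.ndarray]:
    out = []
    for k in range(n):
        ang = math.radians(HELIX_TWIST * k)
        out.append(np.array([center_x + HELIX_RADIUS * math.cos(ang),
                             HELIX_RADIUS * math.sin(ang),
                             z0 + HELIX_RISE * k]))
    return out


def make_kras_like(chain_id: str = "A") -> StructureModel:
    """Deterministic Cα-only G-domain stand-in, residues 1-169.

    Helix α5 (152-166) runs along +z (N→C up); helix α4 (127-136) is offset
    along +x, so the body-fixed rotation reference of the membrane module
    points to +x; the remaining residues fill a compact blob. The geometry is
    fixed (no randomness) so poses built from it carry exact angle truth.
    """
    coords: dict[int, np.ndarray] = {}
    for k, pos in enumerate(_vertical_helix(15, 0.0, -11.0)):
        coords[ALPHA5_RANGE[0] + k] = pos                  # 152..166
    for k, pos in enumerate(_vertical_helix(10, 10.0, -7.5)):
        coords[ALPHA4_RANGE[0] + k] = pos                  # 127..136
    filler = [r for r in range(GDOMAIN_RANGE[0], GDOMAIN_RANGE[1] + 1)
              if r not in coords]
    blob = _golden_blob(len(filler), center=np.array([5.0, 0.0, 0.0]), radius=9.0)
    for r, pos in zip(filler, blob):
        coords[r] = pos
    atoms = [AtomRecord(chain_id=chain_id, res_seq=r, icode="", res_name="ALA",
                        atom_name="CA", element="C", coords=coords[r])
             for r in sorted(coords)]
    return StructureModel.from_atoms(atoms, id="kras-like")


def make_complex_like(kras_chain: str = "A", raf_chain: str = "B") -> StructureModel:
    """Cα-only KRAS + RAF1(RBDCRD)-like complex for membrane-pose tests.

    The RAF chain spans residues 56-187: an RBD blob (56-131) away from the
    α4/α5 face, a short linker (132-137), a CRD blob (138-187) on the +x side
    with the two hydrophobic loops (143-151 and 157-164) protruding furthest
    along +x — the direction that faces the membrane in the α4/α5 pose
    family — so that membrane-proximal poses insert the loops first.
    """
    kras = make_kras_like(kras_chain)
    coords: dict[int, np.ndarray] = {}
    rbd = [r for r in range(56, 132)]
    blob = _golden_blob(len(rbd), center=np.array([-13.0, 7.0, 0.0]), radius=6.0)
    for r, pos in zip(rbd, blob):
        coords[r] = pos
    for k, r in enumerate(range(132, 138)):                # linker
        coords[r] = np.array([-6.0 + 2.5 * k, 5.0, 0.0])
    crd = [r for r in range(138, 188)]
    loop_res = set()
    for lo, hi in CRD_LOOP_RANGES:
        loop_res.update(range(lo, hi + 1))
    crd_core = [r for r in crd if r not in loop_res]
    blob = _golden_blob(len(crd_core), center=np.array([13.0, 0.0, 0.0]), radius=4.0)
    for r, pos in zip(crd_core, blob):
        coords[r] = pos
    for li, (lo, hi) in enumerate(CRD_LOOP_RANGES):
        span = hi - lo
        for k, r in enumerate(range(lo, hi + 1)):
            # arc protruding along +x, 2 Å beyond everything else
            frac = k / span
            coords[r] = np.array([17.0 + 3.0 * math.sin(math.pi * frac),
                                  2.5 if li == 0 else -2.5,
                                  1.5 * (frac - 0.5)])
    atoms = list(kras.atoms())
    atoms += [AtomRecord(chain_id=raf_chain, res_seq=r, icode="", res_name="ALA",
                         atom_name="CA", element="C", coords=coords[r])
              for r in sorted(coords)]
    return StructureModel.from_atoms(atoms, id="complex-like")


# ---------------------------------------------------------------------------
# pose ensembles
# ---------------------------------------------------------------------------

@dataclass
class DgzBinModel:
    """Generative d_Gz model: a mean per (tilt, rotation) bin plus noise."""

    default_mean: float = 30.0          # Å, G-domain COM above bilayer COM
    bin_means: dict | None = None       # {(tilt_center, rot_center): mean}
    noise_sd: float = 0.5               # Å
    bin_halfwidth: float = 5.0

    def mean_for(self, tilt: float, rotation: float) -> float:
        width = 2.0 * self.bin_halfwidth
        key = (_bin_center(tilt, width), _wrap_angle(_bin_center(_wrap_angle(rotation), width)))
        if self.bin_means and key in self.bin_means:
            return float(self.bin_means[key])
        return float(self.default_mean)


@dataclass
class PoseRecord:
    model: StructureModel | None
    angles: PoseAngles
    d_gz: float


@dataclass
class PoseEnsembleTruth:
    poses: list[tuple[float, float, float]]    # (tilt, rotation, d_gz)
    bin_means: dict                            # generative mean per touched bin
    seed: int = 0


def make_pose_ensemble(n: int, tilt_dist: tuple[float, float] = (90.0, 10.0),
                       rot_dist: tuple[float, float] = (-15.0, 10.0),
                       dgz_model: DgzBinModel | None = None, seed: int = 0,
                       frame: MembraneFrame | None = None,
                       reference: StructureModel | None = None,
                       with_models: bool = True,
                       ) -> tuple[list[PoseRecord], PoseEnsembleTruth]:
    """n rigid placements of a reference KRAS copy with exact pose truth.

    Tilt and rotation are Gaussian draws (tilt clipped to (0.5, 179.5) to stay
    clear of the degenerate poles); d_Gz is drawn from the per-bin generative
    model. Defaults emulate the dominant membrane-proximal orientation family
    of KRAS (tilt ~90°, rotation ~-15°, G-domain COM ~30 Å above the bilayer
    centre).
    """
    if n < 1:
        raise ValueError("need at least one pose")
    dgz_model = dgz_model or DgzBinModel()
    frame = frame or make_lipid_slab(60, 60, 5.0, headgroup_z=2.0, thickness=4.0)
    reference = reference or make_kras_like()
    rng = np.random.default_rng(seed)
    tilts = np.clip(rng.normal(tilt_dist[0], tilt_dist[1], n), 0.5, 179.5)
    rots = np.array([_wrap_angle(v) for v in rng.normal(rot_dist[0], rot_dist[1], n)])
    azimuths = rng.uniform(0.0, 360.0, n)
    poses: list[PoseRecord] = []
    truth_rows: list[tuple[float, float, float]] = []
    touched_bins: dict = {}
    width = 2.0 * dgz_model.bin_halfwidth
    for i in range(n):
        tilt, rot = float(tilts[i]), float(rots[i])
        mean = dgz_model.mean_for(tilt, rot)
        dgz = mean + float(rng.normal(0.0, dgz_model.noise_sd)) if dgz_model.noise_sd > 0 else mean
        key = (_bin_center(tilt, width), _wrap_angle(_bin_center(rot, width)))
        touched_bins[key] = mean
        model = None
        if with_models:
            model = construct_pose(reference, frame, tilt, rot, dgz,
                                   azimuth=float(azimuths[i]))
        poses.append(PoseRecord(model=model, angles=PoseAngles(tilt, rot), d_gz=dgz))
        truth_rows.append((tilt, rot, dgz))
    return poses, PoseEnsembleTruth(poses=truth_rows, bin_means=touched_bins,
                                    seed=seed)


# ---------------------------------------------------------------------------
# isotherms and zinc cages
# ---------------------------------------------------------------------------

def make_isotherm(kd: float, rmax: float, concentrations, noise_sd: float,
                  seed: int, replicate=None) -> IsothermData:
    """Noisy Langmuir isotherm: R = Rmax*C/(K_D+C) + N(0, noise_sd)."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    conc = np.asarray(concentrations, float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    resp = langmuir(conc, kd, rmax)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, conc.shape)
    return IsothermData(concentrations=conc, responses=resp, replicate=replicate)


def make_zinc_cage(n_cys: int = 3, n_his: int = 1, bond_length: float = 2.3,
                   chain_id: str = "Z") -> StructureModel:
    """Tetrahedral CysN/HisM zinc cage with ligand atoms at ``bond_length``."""
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    verts = verts / np.linalg.norm(verts[0]) * bond_length
    atoms = [AtomRecord(chain_id=chain_id, res_seq=500, icode="", res_name="ZN",
                        atom_name="ZN", element="ZN", coords=np.zeros(3),
                        is_hetero=True)]
    kinds = ["CYS"] * n_cys + ["HIS"] * n_his
    for i, (res_name, v) in enumerate(zip(kinds, verts)):
        aname = "SG" if res_name == "CYS" else "ND1"
        elem = "S" if res_name == "CYS" else "N"
        atoms.append(AtomRecord(chain_id=chain_id, res_seq=10 + 5 * i, icode="",
                                res_name=res_name, atom_name=aname, element=elem,
                                coords=v))
        atoms.append(AtomRecord(chain_id=chain_id, res_seq=10 + 5 * i, icode="",
                                res_name=res_name, atom_name="CA", element="C",
                                coords=v * (1.0 + 3.0 / bond_length)))
    return StructureModel.from_atoms(atoms, id="zinc-cage")


# ---------------------------------------------------------------------------
# sidecar serialisation
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fixture(model: StructureModel, truth, path: str | Path) -> Path:
    """Write a fixture as PDB plus a ``*.truth.json`` sidecar."""
    from .structio import write_structure
    path = Path(path)
    write_structure(model, path, format="pdb")
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    payload = asdict(truth) if hasattr(truth, "__dataclass_fields__") else truth
    sidecar.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))
    return sidecar
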