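"""Membrane orientation, occlusion and insertion analysis.

A KRAS pose relative to a lipid bilayer is described by two angles: the tilt,
separating the long axis of helix α5 (first principal axis of its Cα atoms,
oriented N→C) from the bilayer normal, and the rotation about that axis,
specifying which face of the G-domain approaches the membrane. The rotation
zero is calibrated so the three canonical membrane-facing orientations read
-15 deg (helices α4/α5 toward the membrane), -85 deg (α3/α4) and
105 deg (strands β1-β3). At tilt = 0 all rotations are equivalent and the
rotation is reported as 0 by convention.

Occlusion of a pose is measured by N_res_clash, the number of protein
residues with any atom within 1.0 Å (0.1 nm) of any lipid atom, and by
d_Gz, the displacement of the G-domain center of mass from the bilayer
center of mass along the membrane normal (mass-weighted heavy-atom COM of
residues 1-169 by default; positive on the protein side).

``construct_pose`` is the exact inverse of ``pose_angles`` under this
convention, which makes the round-trip (construct, then measure) an identity
and lets synthetic pose ensembles carry exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._chem import atomic_mass
from .structio import Selection, StructureModel, coords_of, select_atoms
from .superpose import DegenerateGeometryError, kabsch_fit, pair_structures

__all__ = [
    "MembraneFrame",
    "PoseAngles",
    "OcclusionResult",
    "OrientationEnsembleSummary",
    "ROTATION_OFFSET_DEG",
    "ALPHA5_RANGE",
    "ALPHA4_RANGE",
    "GDOMAIN_RANGE",
    "CRD_LOOP_RANGES",
    "KRAS_FIT_RANGES",
    "pose_angles",
    "construct_pose",
    "align_to_pose",
    "count_clashes",
    "compute_dgz",
    "ensemble_summary",
    "loop_insertion",
]

# KRAS author-numbering landmarks (G-domain 1-169).
ALPHA5_RANGE = (152, 166)    # helix α5 Cα set defining the long axis
ALPHA4_RANGE = (127, 136)    # helix α4, body-fixed rotation reference
GDOMAIN_RANGE = (1, 169)
# Cα fitting set omitting the flexible N-terminus and switch regions.
KRAS_FIT_RANGES = ((4, 26), (40, 56), (69, 166))
# RAF1 CRD hydrophobic/cationic membrane-insertion loops.
CRD_LOOP_RANGES = ((143, 151), (157, 164))

# Calibration constant: with the α4/α5 face toward the membrane the raw
# body-vector angle is 0 and the reported rotation must be -15 deg.
ROTATION_OFFSET_DEG = -15.0

DEFAULT_CLASH_CUTOFF = 1.0   # Å  (= 0.1 nm)


class WeightError(ValueError):
    """Non-positive ensemble weights."""


@dataclass
class MembraneFrame:
    """Bilayer reference frame: lipid pseudo-atoms, unit normal, center of
    mass, and the headgroup-plane offset along the normal."""

    lipid_coords: np.ndarray        # (n, 3) Å
    normal: np.ndarray              # unit 3-vector, protein side positive
    com: np.ndarray                 # (3,) Å
    headgroup_offset: float         # x . normal == offset on the top plane

    def __post_init__(self) -> None:
        self.lipid_coords = np.asarray(self.lipid_coords, float).reshape(-1, 3)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            self.normal = self.normal / n
        self.com = np.asarray(self.com, float)

    def to_dict(self) -> dict:
        return {
            "normal": [float(x) for x in self.normal],
            "com": [float(x) for x in self.com],
            "headgroup_offset_A": float(self.headgroup_offset),
            "n_lipid_atoms": int(self.lipid_coords.shape[0]),
        }


@dataclass(frozen=True)
class PoseAngles:
    tilt: float       # degrees, [0, 180]
    rotation: float   # degrees, (-180, 180]


@dataclass
class OcclusionResult:
    n_res_clash: int
    clashing_residues: list[tuple[str, int, str]]
    d_gz: float


@dataclass
class OrientationEnsembleSummary:
    """Per (tilt, rotation) bin: pose count, weight sum, weighted mean d_Gz."""

    bin_halfwidth: float
    bins: dict[tuple[float, float], dict] = field(default_factory=dict)

    @property
    def n_poses(self) -> int:
        return sum(b["count"] for b in self.bins.values())

    def table(self):
        import pandas as pd
        rows = [{"tilt_center_deg": k[0], "rotation_center_deg": k[1],
                 "count": v["count"], "weight": v["weight"],
                 "mean_dgz_A": v["mean_dgz"]} for k, v in sorted(self.bins.items())]
        return pd.DataFrame(rows, columns=["tilt_center_deg", "rotation_center_deg",
                                           "count", "weight", "mean_dgz_A"])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _wrap_angle(deg: float) -> float:
    """Wrap to (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


def _rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, float))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * K @ K


def _ca_selection(rng: tuple[int, int], chain: str | None) -> Selection:
    return Selection(chains=(chain,) if chain else None,
                     residue_ranges=(rng,), atom_names=("CA",))


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """First principal axis of a Cα set, oriented N→C."""
    if ca.shape[0] < 4:
        raise DegenerateGeometryError(
            f"helix axis needs >= 4 Cα atoms, got {ca.shape[0]}")
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return _unit(axis)


def _body_frame(kras_model: StructureModel, chain: str | None,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(α5 axis u, perpendicular reference r⊥ toward α4, α5 centroid)."""
    ca5 = coords_of(select_atoms(kras_model, _ca_selection(ALPHA5_RANGE, chain),
                                 require_nonempty=True))
    u = _helix_axis(ca5)
    c5 = ca5.mean(axis=0)
    ca4 = coords_of(select_atoms(kras_model, _ca_selection(ALPHA4_RANGE, chain),
                                 require_nonempty=True))
    r = ca4.mean(axis=0) - c5
    r_perp = r - (r @ u) * u
    return u, _unit(r_perp), c5


def _perp_component(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    return _unit(v - (v @ u) * u)


# ---------------------------------------------------------------------------
# pose angles and pose construction
# ---------------------------------------------------------------------------

def pose_angles(kras_model: StructureModel, frame: MembraneFrame,
                chain: str | None = None, tilt_tol_deg: float = 1e-9,
                ) -> PoseAngles:
    """Tilt and rotation of a KRAS model relative to a membrane frame."""
    u, r_perp, _ = _body_frame(kras_model, chain)
    n = frame.normal
    cos_t = float(np.clip(u @ n, -1.0, 1.0))
    tilt = math.degrees(math.acos(cos_t))
    if tilt <= tilt_tol_deg or tilt >= 180.0 - tilt_tol_deg:
        return PoseAngles(tilt=tilt, rotation=0.0)
    m_perp = _perp_component(-n, u)     # inward membrane normal, projected
    cos_p = float(np.clip(m_perp @ r_perp, -1.0, 1.0))
    sin_p = float(np.cross(m_perp, r_perp) @ u)
    phi_raw = math.degrees(math.atan2(sin_p, cos_p))
    return PoseAngles(tilt=tilt, rotation=_wrap_angle(phi_raw + ROTATION_OFFSET_DEG))


def construct_pose(reference: StructureModel, frame: MembraneFrame,
                   tilt: float, rotation: float, dgz: float,
                   chain: str | None = None, azimuth: float = 0.0,
                   gdomain_range: tuple[int, int] = GDOMAIN_RANGE,
                   ) -> StructureModel:
    """Rigidly place a copy of ``reference`` at exact (tilt, rotation, d_Gz).

    ``azimuth`` spins the pose about the membrane normal, which leaves all
    three pose observables unchanged (used to vary poses within a bin).
    """
    if not (0.0 <= tilt <= 180.0):
        raise ValueError("tilt must lie in [0, 180] degrees")
    u0, r0, _ = _body_frame(reference, chain)
    w0 = np.cross(u0, r0)
    B0 = np.column_stack([u0, r0, w0])

    n = frame.normal
    # in-plane direction fixing where the helix leans; any unit vector ⊥ n
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ n) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = _unit(ref - (ref @ n) * n)
    p = _rodrigues(n, math.radians(azimuth)) @ p
    theta = math.radians(tilt)
    t_hat = math.cos(theta) * n + math.sin(theta) * p
    if tilt <= 1e-9 or tilt >= 180.0 - 1e-9:
        a = p  # rotation degenerate; any perpendicular convention works
    else:
        a = _perp_component(-n, t_hat)
    phi = math.radians(_wrap_angle(rotation - ROTATION_OFFSET_DEG))
    r_hat = _rodrigues(t_hat, phi) @ a
    B1 = np.column_stack([t_hat, r_hat, np.cross(t_hat, r_hat)])
    R = B1 @ B0.T

    gdom = select_atoms(reference, Selection(chains=(chain,) if chain else None,
                                             residue_ranges=(gdomain_range,)),
                        require_nonempty=True)
    com0 = _mass_weighted_com(gdom)
    posed = reference.transform(R, -R @ com0)
    # G-domain COM now at origin; translate onto the requested d_Gz
    target = frame.com + dgz * n
    return posed.transform(np.eye(3), target)


def align_to_pose(complex_model: StructureModel, reference_kras: np.ndarray,
                  fit_sel: Selection, chain_map: dict[str, str] | None = None,
                  ) -> tuple[StructureModel, float]:
    """Rigidly move a whole complex so its KRAS matches a posed reference.

    ``reference_kras`` must be the coordinates of exactly the atoms that
    ``fit_sel`` resolves to on the complex, in model order. Every atom of the
    complex (KRAS, RBD, CRD, linker, hetero groups) moves together. Returns
    the transformed complex and the fit RMSD.
    """
    mobile_atoms = select_atoms(complex_model, fit_sel, require_nonempty=True)
    mobile = coords_of(mobile_atoms)
    reference_kras = np.asarray(reference_kras, float)
    fit = kabsch_fit(mobile, reference_kras)
    return complex_model.transform(fit.rotation, fit.translation), fit.rmsd


def align_complex_to_posed_reference(complex_model: StructureModel,
                                     posed_reference: StructureModel,
                                     fit_sel: Selection,
                                     chain_map: dict[str, str] | None = None,
                                     ) -> tuple[StructureModel, float]:
    """Convenience wrapper pairing by atom identity instead of raw order."""
    mobile, reference, _ = pair_structures(complex_model, posed_reference,
                                           fit_sel, chain_map)
    fit = kabsch_fit(mobile, reference)
    return complex_model.transform(fit.rotation, fit.translation), fit.rmsd


# ---------------------------------------------------------------------------
# occlusion metrics
# ---------------------------------------------------------------------------

def _mass_weighted_com(atoms) -> np.ndarray:
    coords = coords_of(atoms)
    masses = np.array([atomic_mass(a.element) for a in atoms])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def compute_dgz(kras_model: StructureModel, frame: MembraneFrame,
                gdomain_sel: Selection | None = None) -> float:
    """Signed displacement of the G-domain COM from the bilayer COM along the
    normal. Mass-weighted over heavy atoms of residues 1-169 by default."""
    sel = gdomain_sel or Selection(residue_ranges=(GDOMAIN_RANGE,))
    atoms = select_atoms(kras_model, sel, require_nonempty=True)
    com = _mass_weighted_com(atoms)
    return float((com - frame.com) @ frame.normal)


def count_clashes(protein: StructureModel, frame: MembraneFrame,
                  cutoff: float = DEFAULT_CLASH_CUTOFF,
                  gdomain_sel: Selection | None = None) -> OcclusionResult:
    """N_res_clash: residues with any atom within ``cutoff`` of any lipid atom.

    The companion d_Gz is computed over ``gdomain_sel`` when it resolves, else
    over the whole protein.
    """
    if cutoff <= 0:
        raise ValueError("clash cutoff must be positive")
    atoms = [a for a in protein.atoms() if not a.is_water]
    coords = coords_of(atoms)
    clashing: list[tuple[str, int, str]] = []
    if coords.shape[0] and frame.lipid_coords.shape[0]:
        tree = cKDTree(frame.lipid_coords)
        dists, _ = tree.query(coords, k=1)
        seen = set()
        for atom, d in zip(atoms, dists):
            if d <= cutoff and atom.residue_key not in seen:
                seen.add(atom.residue_key)
                clashing.append(atom.residue_key)
    try:
        dgz = compute_dgz(protein, frame, gdomain_sel)
    except Exception:
        dgz = float((_mass_weighted_com(atoms) - frame.com) @ frame.normal)
    clashing.sort()
    return OcclusionResult(n_res_clash=len(clashing), clashing_residues=clashing,
                           d_gz=dgz)


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------

def _bin_center(value: float, width: float) -> float:
    return round(value / width) * width


def ensemble_summary(poses, bin_halfwidth: float = 5.0,
                     ) -> OrientationEnsembleSummary:
    """Bin poses into disjoint (tilt, rotation) cells of full width
    2 x halfwidth anchored at 0 deg and average d_Gz per cell.

    ``poses`` is an iterable of (PoseAngles, d_gz) or (PoseAngles, d_gz,
    weight); weights default to uniform (equilibrium snapshots are already
    Boltzmann-distributed). Rotation bins wrap at ±180 deg; tilt bins do not.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("ensemble_summary needs at least one pose")
    width = 2.0 * bin_halfwidth
    acc: dict[tuple[float, float], dict] = {}
    for item in poses:
        if len(item) == 2:
            angles, dgz = item
            w = 1.0
        else:
            angles, dgz, w = item
        if w <= 0:
            raise WeightError(f"non-positive pose weight {w}")
        tilt_c = _bin_center(angles.tilt, width)
        rot_c = _wrap_angle(_bin_center(_wrap_angle(angles.rotation), width))
        key = (tilt_c, rot_c)
        cell = acc.setdefault(key, {"count": 0, "weight": 0.0, "wsum": 0.0})
        cell["count"] += 1
        cell["weight"] += w
        cell["wsum"] += w * dgz
    bins = {k: {"count": v["count"], "weight": v["weight"],
                "mean_dgz": v["wsum"] / v["weight"]} for k, v in acc.items()}
    return OrientationEnsembleSummary(bin_halfwidth=bin_halfwidth, bins=bins)


# ---------------------------------------------------------------------------
# loop insertion
# ---------------------------------------------------------------------------

def loop_insertion(complex_model: StructureModel, frame: MembraneFrame,
                   loop_sels: list[Selection] | None = None,
                   raf_chain: str | None = None):
    """Per-residue insertion depth below the headgroup plane, per loop.

    Depth is the signed distance of a residue's deepest atom below the plane
    along the normal (positive = inserted). Defaults to the two CRD
    hydrophobic loops, RAF1 residues 143-151 and 157-164.
    """
    import pandas as pd
    if loop_sels is None:
        loop_sels = [Selection(chains=(raf_chain,) if raf_chain else None,
                               residue_ranges=(rng,)) for rng in CRD_LOOP_RANGES]
    rows = []
    for loop_idx, sel in enumerate(loop_sels):
        atoms = select_atoms(complex_model, sel, require_nonempty=True)
        per_res: dict[tuple, dict] = {}
        for atom in atoms:
            h = float(atom.coords @ frame.normal) - frame.headgroup_offset
            depth = -h
            entry = per_res.setdefault(atom.residue_key,
                                       {"res_name": atom.res_name, "depth": -np.inf})
            if depth > entry["depth"]:
                entry["depth"] = depth
        for (chain, res_seq, icode), entry in sorted(per_res.items()):
            rows.append({
                "loop": loop_idx,
                "chain": chain,
                "res_seq": res_seq,
                "icode": icode,
                "res_name": entry["res_name"],
                "depth_A": entry["depth"],
                "inserted": bool(entry["depth"] > 0.0),
            })
    return pd.DataFrame(rows, columns=["loop", "chain", "res_seq", "icode",
                                       "res_name", "depth_A", "inserted"])
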