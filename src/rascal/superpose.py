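"""Least-squares superposition, RMSD and screw-axis domain motion.

The Kabsch algorithm (SVD of the cross-covariance, with the reflection guard)
gives the global least-squares rigid transform between two order-paired
coordinate sets. Domain motion between two crystal forms is quantified the way
RAS/RAF structure comparisons report it: both structures are superposed on an
anchor (e.g. KRAS), and the residual rigid transform of the domain of interest
(e.g. the RBD) is decomposed into a rotation angle about a screw axis, the
translation along that axis, and the total centroid displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structio import Selection, StructureModel, coords_of, select_atoms

__all__ = [
    "SuperpositionResult",
    "RigidMotion",
    "DegenerateGeometryError",
    "PairingError",
    "kabsch_fit",
    "rmsd",
    "apply_transform",
    "pair_structures",
    "domain_motion",
]

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Too few or rank-deficient coordinates for a unique superposition."""


class PairingError(ValueError):
    """Coordinate sets (or residue contents) cannot be put in 1:1 order."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray        # (3, 3), det = +1
    translation: np.ndarray     # (3,), Å
    rmsd: float                 # Å, after transform
    n_atoms: int
    pairing: list[tuple] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RigidMotion:
    """Screw decomposition of a rigid domain motion.

    ``rotation_angle`` in [0, 180] degrees; ``screw_displacement`` is the
    translation component along the rotation axis (sign tied to the axis
    orientation); ``centroid_shift`` the total displacement of the domain
    centroid. |screw_displacement| <= centroid_shift always holds.
    """

    rotation_angle: float       # degrees
    axis: np.ndarray            # unit 3-vector
    screw_displacement: float   # Å
    centroid_shift: float       # Å
    anchor_rmsd: float = 0.0
    n_anchor_atoms: int = 0
    n_domain_atoms: int = 0

    def to_dict(self) -> dict:
        return {
            "rotation_angle_deg": self.rotation_angle,
            "axis": [float(x) for x in self.axis],
            "screw_displacement_A": self.screw_displacement,
            "centroid_shift_A": self.centroid_shift,
            "anchor_rmsd_A": self.anchor_rmsd,
            "n_anchor_atoms": self.n_anchor_atoms,
            "n_domain_atoms": self.n_domain_atoms,
        }


def _as_paired(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise PairingError(f"coordinate sets must be paired (n, 3); got {a.shape} vs {b.shape}")
    return a, b


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform mapping ``mobile`` onto ``reference``.

    Reflections are excluded by flipping the sign of the smallest singular
    vector when det < 0, so the result is always a proper rotation.
    """
    mobile, reference = _as_paired(mobile, reference)
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 paired atoms, got {n}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    H = P.T @ Q
    if np.linalg.matrix_rank(H) < 2:
        raise DegenerateGeometryError("rank-deficient (collinear) configuration")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    fitted = mobile @ R.T + t
    value = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=value, n_atoms=n)


def rmsd(a: np.ndarray, b: np.ndarray, mode: str = "fixed") -> float:
    """Root-mean-square deviation between paired sets.

    ``fixed`` compares in the current frames; ``fitted`` first applies the
    optimal Kabsch superposition. Symmetric in its arguments in both modes.
    """
    a, b = _as_paired(a, b)
    if mode == "fixed":
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    if mode == "fitted":
        return kabsch_fit(a, b).rmsd
    raise ValueError(f"unknown rmsd mode {mode!r}")


def apply_transform(model: StructureModel, result: SuperpositionResult) -> StructureModel:
    """Apply a fitted rigid transform to every atom of a model."""
    return model.transform(result.rotation, result.translation)


def pair_structures(model_a: StructureModel, model_b: StructureModel,
                    sel: Selection, chain_map: dict[str, str] | None = None,
                    sel_b: Selection | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Pair atoms across two structures by (chain-role, res_seq, icode, name).

    ``chain_map`` maps chain ids of ``model_a`` to the equivalent chain ids of
    ``model_b`` (identity by default). Atoms present in only one structure are
    dropped with a logged count; an empty intersection raises PairingError.
    """
    chain_map = chain_map or {}
    sel_b = sel_b if sel_b is not None else _remap_selection(sel, chain_map)
    atoms_a = select_atoms(model_a, sel)
    atoms_b = select_atoms(model_b, sel_b)
    index_b = {}
    for atom in atoms_b:
        index_b[(atom.chain_id, atom.res_seq, atom.icode, atom.atom_name)] = atom
    pairs = []
    unmatched = 0
    for atom in atoms_a:
        key = (chain_map.get(atom.chain_id, atom.chain_id), atom.res_seq,
               atom.icode, atom.atom_name)
        other = index_b.get(key)
        if other is None:
            unmatched += 1
            continue
        pairs.append((atom, other))
    if unmatched:
        logger.info("pair_structures: dropped %d unmatched atoms", unmatched)
    if not pairs:
        raise PairingError("no atoms could be paired between the two structures")
    ca = np.array([p[0].coords for p in pairs])
    cb = np.array([p[1].coords for p in pairs])
    labels = [(p[0].chain_id, p[0].res_seq, p[0].icode, p[0].atom_name) for p in pairs]
    return ca, cb, labels


def _remap_selection(sel: Selection, chain_map: dict[str, str]) -> Selection:
    if sel.chains is None or not chain_map:
        return sel
    from dataclasses import replace
    return replace(sel, chains=tuple(chain_map.get(c, c) for c in sel.chains))


def _angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Rotation angle (degrees, [0, 180]) and unit axis of a proper rotation.

    The angle comes from the trace; the axis from the antisymmetric part, with
    the near-180 degenerate case handled by eigen-decomposition.
    """
    tr = np.trace(R)
    cos_t = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_t))
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(w)
    if norm > 1e-8:
        axis = w / norm
    else:
        if angle < 1.0:  # identity: axis is arbitrary
            return 0.0, np.array([0.0, 0.0, 1.0])
        # 180 degrees: axis = eigenvector of R for eigenvalue +1
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        axis = axis / np.linalg.norm(axis)
    return float(angle), axis


def domain_motion(struct_a: StructureModel, struct_b: StructureModel,
                  anchor_sel: Selection, domain_sel: Selection,
                  chain_map: dict[str, str] | None = None) -> RigidMotion:
    """Screw-axis motion of a domain between two structures sharing an anchor.

    Both structures are superposed on the anchor selection; the residual rigid
    transform carrying the domain of ``struct_a`` onto that of ``struct_b`` is
    then decomposed. The rotation angle is invariant to swapping a and b (the
    axis and screw sign flip).
    """
    anc_a, anc_b, _ = pair_structures(struct_a, struct_b, anchor_sel, chain_map)
    if anc_a.shape[0] < 3:
        raise PairingError(f"anchor pairs to only {anc_a.shape[0]} atoms")
    anchor_fit = kabsch_fit(anc_b, anc_a)  # bring b into a's frame
    dom_a, dom_b, _ = pair_structures(struct_a, struct_b, domain_sel, chain_map)
    if dom_a.shape[0] < 3:
        raise PairingError(f"domain pairs to only {dom_a.shape[0]} atoms")
    dom_b_aligned = anchor_fit.apply(dom_b)
    fit = kabsch_fit(dom_a, dom_b_aligned)
    angle, axis = _angle_axis(fit.rotation)
    screw = float(axis @ fit.translation)
    centroid_shift = float(np.linalg.norm(dom_b_aligned.mean(axis=0) - dom_a.mean(axis=0)))
    return RigidMotion(
        rotation_angle=angle,
        axis=axis,
        screw_displacement=screw,
        centroid_shift=centroid_shift,
        anchor_rmsd=anchor_fit.rmsd,
        n_anchor_atoms=anc_a.shape[0],
        n_domain_atoms=dom_a.shape[0],
    )
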