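"""Macromolecular coordinate I/O and atom selection.

This module owns the in-memory coordinate container used by every analysis in
the package: a small chain/residue/atom hierarchy keyed by *author* residue
numbering (1-based, inclusive ranges, insertion codes sorting after the bare
number), which is the numbering convention used throughout RAS/RAF structural
work (e.g. the KRAS G-domain fitting set Y4-N26, Y40-L56, D69-H166).

Parsing and serialisation of PDB (fixed-column v3.3) and mmCIF files are
delegated to :mod:`gemmi`; only model 1 of a multi-model file is kept unless a
model index is given. Hydrogens and waters are parsed but excluded from
selections by default, matching the deposited X-ray entries which carry no
hydrogens.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

try:
    import gemmi
except ImportError as _exc:  # pragma: no cover
    raise ImportError("rascal.structio requires gemmi") from _exc

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "Selection",
    "StructureFormatError",
    "CoordinateOverflowError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "coords_of",
    "parse_selection",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

# PDB %8.3f coordinate field limits
_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


class StructureFormatError(ValueError):
    """A coordinate file could not be parsed in the stated dialect."""


class CoordinateOverflowError(ValueError):
    """A coordinate does not fit the fixed-width PDB field."""


class EmptySelectionError(ValueError):
    """A selection resolved to zero atoms where atoms were required."""


@dataclass
class AtomRecord:
    """One atom with author identifiers and Cartesian coordinates in Å."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def atom_key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.res_seq, self.icode, self.atom_name, self.altloc)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_hetero(self) -> bool:
        return any(a.is_hetero for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.res_seq, self.icode, self.res_name,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero and not r.is_water]


@dataclass
class StructureModel:
    """Ordered chains → ordered residues → atoms, with header metadata."""

    id: str = ""
    title: str = ""
    chains: list[Chain] = field(default_factory=list)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def atoms(self) -> Iterator[AtomRecord]:
        for chain in self.chains:
            for res in chain.residues:
                yield from res.atoms

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def copy(self) -> "StructureModel":
        return StructureModel(self.id, self.title, [c.copy() for c in self.chains])

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom mapped x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = self.copy()
        for atom in out.atoms():
            atom.coords = R @ atom.coords + t
        return out

    def validate(self) -> None:
        """Enforce container invariants (uniqueness, residue ordering)."""
        seen: set[tuple] = set()
        for atom in self.atoms():
            if atom.atom_key in seen:
                raise ValueError(f"duplicate atom {atom.atom_key}")
            seen.add(atom.atom_key)
        for chain in self.chains:
            order = [(r.res_seq, r.icode) for r in chain.polymer_residues()]
            if order != sorted(order):
                raise ValueError(f"residues out of order in chain {chain.chain_id}")

    @staticmethod
    def from_atoms(atoms: Iterable[AtomRecord], id: str = "", title: str = "") -> "StructureModel":
        """Build the hierarchy from a flat atom iterable (order preserved)."""
        model = StructureModel(id=id, title=title)
        chain: Chain | None = None
        res: Residue | None = None
        for atom in atoms:
            if chain is None or chain.chain_id != atom.chain_id:
                chain = model.get_chain(atom.chain_id)
                if chain is None:
                    chain = Chain(atom.chain_id)
                    model.chains.append(chain)
                res = chain.residues[-1] if chain.residues else None
            if res is None or res.key != atom.residue_key:
                res = Residue(atom.chain_id, atom.res_seq, atom.icode, atom.res_name)
                chain.residues.append(res)
            res.atoms.append(atom)
        return model


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Declarative atom selection resolved deterministically against a model.

    ``residue_ranges`` are inclusive author-numbering ranges; ``None`` filters
    mean "no constraint". Waters and hydrogens are excluded unless explicitly
    re-enabled, and hetero groups are excluded unless ``include_hetero``.
    """

    chains: tuple[str, ...] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: tuple[str, ...] | None = None
    include_hetero: bool = False
    include_waters: bool = False
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.residue_ranges is not None:
            for start, end in self.residue_ranges:
                if start > end:
                    raise ValueError(f"range {start}-{end} has start > end")

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if atom.is_water and not self.include_waters:
            return False
        if atom.is_hetero and not atom.is_water and not self.include_hetero:
            return False
        if atom.is_hydrogen and not self.include_hydrogens:
            return False
        if self.residue_ranges is not None:
            if not any(lo <= atom.res_seq <= hi for lo, hi in self.residue_ranges):
                return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        return True


def parse_selection(text: str, **kwargs) -> Selection:
    """Parse ``"chain:start-end[,start-end]/atom_name"`` selection strings.

    Each component is optional: ``"A"``, ``"A:4-26,40-56"``, ``"A/CA"``,
    ``":10-20/CA"`` are all valid.
    """
    m = re.fullmatch(r"([^:/]*)(?::([^/]*))?(?:/(.*))?", text.strip())
    if m is None:
        raise ValueError(f"unparseable selection string: {text!r}")
    chain_part, range_part, atom_part = m.groups()
    chains = tuple(chain_part.split("+")) if chain_part else None
    ranges = None
    if range_part:
        ranges = []
        for token in range_part.split(","):
            token = token.strip()
            if "-" in token[1:]:  # allow negative start
                lo, hi = token.rsplit("-", 1)
                ranges.append((int(lo), int(hi)))
            else:
                ranges.append((int(token), int(token)))
        ranges = tuple(ranges)
    atoms = tuple(atom_part.split("+")) if atom_part else None
    return Selection(chains=chains, residue_ranges=ranges, atom_names=atoms, **kwargs)


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per (chain, res, icode, atom name): highest occupancy,
    ties broken by lexicographically smallest altloc id."""
    best: dict[tuple, tuple[float, str, int]] = {}
    for i, atom in enumerate(atoms):
        key = (atom.chain_id, atom.res_seq, atom.icode, atom.atom_name)
        rank = (-atom.occupancy, atom.altloc or "~", i)
        # '~' sorts after letters so a blank altloc wins only via occupancy/order
        if key not in best or rank < best[key]:
            best[key] = rank
    keep_idx = {rank[2] for rank in best.values()}
    return [a for i, a in enumerate(atoms) if i in keep_idx]


def select_atoms(model: StructureModel, sel: Selection,
                 require_nonempty: bool = False) -> list[AtomRecord]:
    """Resolve a Selection against a model, in model order.

    Altloc duplicates are reduced to one atom per (chain, residue, atom name)
    by the keep-highest-occupancy policy.
    """
    picked = [a for a in model.atoms() if sel.matches(a)]
    picked = _dedupe_altlocs(picked)
    if require_nonempty and not picked:
        raise EmptySelectionError(f"selection {sel} matched no atoms")
    return picked


def identify_chain_roles(model: StructureModel) -> dict[str, str]:
    """Assign 'kras' and 'raf' roles to polymer chains by residue numbering.

    Deposited RAS-RAF complexes do not fix chain ids, but the constructs do
    fix author numbering: the GTPase G-domain spans residues ~1-169 while the
    RAF1 RBD/CRD constructs start at residue >= 52. A chain whose polymer
    residues start below 20 is therefore KRAS; one starting at 50 or above is
    RAF. Raises when either role is missing or ambiguous.
    """
    roles: dict[str, str] = {}
    for chain in model.chains:
        poly = chain.polymer_residues()
        if len(poly) < 20:
            continue
        start = min(r.res_seq for r in poly)
        end = max(r.res_seq for r in poly)
        if start < 20 and end <= 200:
            role = "kras"
        elif start >= 50:
            role = "raf"
        else:
            continue
        if role in roles:
            raise ValueError(f"two candidate {role} chains: "
                             f"{roles[role]} and {chain.chain_id}")
        roles[role] = chain.chain_id
    missing = {"kras", "raf"} - set(roles)
    if missing:
        raise ValueError(f"could not identify chain role(s): {sorted(missing)}")
    return roles


def coords_of(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) array."""
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.coords for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    return "auto"


def read_structure(path: str | Path, format: str = "auto",
                   model_index: int = 0) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    ``model_index`` selects among models of a multi-model file (default: the
    first, i.e. model 1). Insertion codes and altlocs are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format if format != "auto" else _guess_format(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise StructureFormatError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if not (0 <= model_index < len(st)):
        raise StructureFormatError(
            f"model index {model_index} out of range for {path} ({len(st)} models)")
    gmodel = st[model_index]
    title = ""
    try:
        title = st.get_info("_struct.title") or ""
    except Exception:
        pass
    model = StructureModel(id=st.name or path.stem, title=title)
    for gchain in gmodel:
        chain = Chain(gchain.name)
        for gres in gchain:
            is_het = gres.het_flag == "H"
            res = Residue(gchain.name, gres.seqid.num, (gres.seqid.icode or " ").strip(),
                          gres.name)
            for gatom in gres:
                res.atoms.append(AtomRecord(
                    chain_id=gchain.name,
                    res_seq=gres.seqid.num,
                    icode=(gres.seqid.icode or " ").strip(),
                    res_name=gres.name,
                    atom_name=gatom.name,
                    element=gatom.element.name.upper(),
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=min(max(gatom.occ, 0.0), 1.0),
                    altloc="" if gatom.altloc in ("\x00", " ", "") else gatom.altloc,
                    b_factor=gatom.b_iso,
                    is_hetero=is_het,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    return model


def _to_gemmi(model: StructureModel) -> "gemmi.Structure":
    st = gemmi.Structure()
    st.name = model.id or "MODEL"
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.res_seq, res.icode or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.atom_name
                gatom.element = gemmi.Element(atom.element.capitalize())
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                if atom.altloc:
                    gatom.altloc = atom.altloc
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> Path:
    """Write a model to PDB or mmCIF; re-readable with identical coordinates
    to 3 decimals (PDB) or full precision (mmCIF)."""
    path = Path(path)
    fmt = format if format != "auto" else _guess_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise StructureFormatError(f"unknown output format {format!r}")
    if fmt == "pdb":
        for atom in model.atoms():
            if np.any(atom.coords > _PDB_COORD_MAX) or np.any(atom.coords < _PDB_COORD_MIN):
                raise CoordinateOverflowError(
                    f"coordinate {atom.coords} of {atom.atom_key} exceeds the fixed-width "
                    f"PDB field; write mmCIF instead")
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    return path
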