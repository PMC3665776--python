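"""Macromolecular coordinate I/O and backbone geometry.

Reading goes through :mod:`gemmi`; on top of it this module resolves
alternate conformations (highest occupancy wins), drops waters, separates
bound ligands from the polymer, and attaches van der Waals radii so that
downstream surface-area and contact computations need no further lookup.

Geometry primitives: Euclidean atom distances, signed torsion angles,
backbone phi/psi extraction with chain-break detection, and a coarse
Ramachandran classifier (favored / allowed / outlier).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "DihedralRecord",
    "PDBParseError",
    "DegenerateGeometryError",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "atom_distance",
    "dihedral",
    "phi_psi",
    "classify_ramachandran",
    "residue_kind",
]

# Fixed published van der Waals radii (Angstrom). Hydrogens are parsed but
# excluded from contact and SASA computations by default, since crystal
# structures typically lack them.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "BR": 1.85,
    "H": 1.20,
}
_DEFAULT_VDW = 1.70

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when coordinate input cannot be interpreted."""


class DegenerateGeometryError(ValueError):
    """Raised for torsions over (near-)collinear points."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.vdw_radius is None:
            self.vdw_radius = VDW_RADII.get(self.element.upper(), _DEFAULT_VDW)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str  # 3-letter residue name as in the file
    aa: str    # one-letter code, 'X' for non-standard, '' for hetero
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        """Residue label in the field's usual shorthand, e.g. ``Y24``."""
        one = self.aa if self.aa else "X"
        return f"{one}{self.number}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for ch in self.chains for r in ch.residues]

    def residue_by_id(self, rid: tuple[str, int, str]) -> Residue:
        for ch in self.chains:
            for r in ch.residues:
                if r.id == rid:
                    return r
        raise KeyError(rid)


@dataclass
class DihedralRecord:
    residue_id: tuple[str, int, str]
    aa: str
    phi: float | None
    psi: float | None
    rama_class: str  # favored | allowed | outlier | undefined


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken
    by the alphabetically first altloc identifier."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        kept.append(min(group, key=lambda a: (-a.occupancy, a.altloc or "~")))
    return kept


def _validate_coordinate_fields(text: str) -> None:
    """Reject ATOM/HETATM records whose fixed-width numeric fields do not parse.

    The downstream parser is lenient about trailing garbage in numbers; this
    check reports the offending line number instead of silently truncating.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z"),
                             (54, 60, "occupancy")):
            field = line[lo:hi].strip()
            if not field and what == "occupancy":
                continue
            try:
                float(field)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {field!r}") from None


def read_pdb(source: str | os.PathLike, ligand_names: set[str] | frozenset[str] = frozenset()) -> Structure:
    """Parse PDB-dialect text into a :class:`Structure`.

    ``source`` may be a path or the raw text itself.  HETATM residues whose
    3-letter name is in ``ligand_names`` are collected as ligands; waters and
    other hetero residues are dropped.  Duplicated altlocs keep only the
    highest-occupancy conformer.
    """
    ligand_names = {n.strip().upper() for n in ligand_names}
    src = os.fspath(source) if isinstance(source, os.PathLike) else source
    if "\n" in src or not os.path.exists(src):
        text, struct_id = src, "structure"
    else:
        with open(src) as fh:
            text = fh.read()
        struct_id = os.path.splitext(os.path.basename(src))[0]
    _validate_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse PDB input: {exc}") from exc
    struct_id = st.name or struct_id

    if len(st) == 0:
        raise PDBParseError("no models in input")
    model = st[0]

    structure = Structure(id=struct_id)
    ligands: list[Residue] = []
    for gch in model:
        chain = Chain(id=gch.name)
        for gres in gch:
            resname = gres.name.strip().upper()
            if resname in _WATER_NAMES:
                continue
            het = gres.het_flag == "H"
            atoms = []
            for ga in gres:
                atoms.append(Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name.upper(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(float(ga.occ), 0.0), 1.0),
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                ))
            atoms = _resolve_altlocs(atoms)
            res = Residue(
                chain_id=gch.name,
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=resname,
                aa=_THREE_TO_ONE.get(resname, "X" if not het else ""),
                atoms=atoms,
                hetero=het,
            )
            if het and resname not in _THREE_TO_ONE:
                if resname in ligand_names:
                    ligands.append(res)
                else:
                    logger.debug("dropping hetero residue %s %s", resname, res.id)
                continue
            chain.residues.append(res)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.number, r.insertion_code))
            structure.chains.append(chain)
    structure.ligands = ligands

    if not structure.polymer_residues() and not structure.ligands:
        raise PDBParseError("empty structure: no polymer residues or ligands found")
    return structure


def write_pdb(structure: Structure, path: str | os.PathLike | None = None,
              remarks: list[str] | None = None) -> str:
    """Serialize a :class:`Structure` to PDB text (ATOM/HETATM/TER/END)."""
    lines: list[str] = []
    for rem in remarks or []:
        lines.append(f"REMARK 999 {rem}"[:80])
    serial = 1

    def fmt(record: str, atom: Atom, res: Residue) -> str:
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        return (f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{res.name:>3s} "
                f"{res.chain_id[:1]:1s}{res.number:>4d}{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}")

    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(fmt("ATOM", atom, res))
                serial += 1
        lines.append(f"TER   {serial:>5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.id[:1]:1s}{chain.residues[-1].number:>4d}")
        serial += 1
    for res in structure.ligands:
        for atom in res.atoms:
            lines.append(fmt("HETATM", atom, res))
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def atom_distance(a: Atom, b: Atom) -> float:
    """Euclidean distance between two atoms in Angstrom."""
    return float(np.linalg.norm(a.coords - b.coords))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2-p3 axis, degrees in (-180, 180].

    Uses the standard right-hand (IUPAC) convention: 0 for a cis (eclipsed)
    arrangement, 180 for trans.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(float(np.dot(m, n2)), float(np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return 180.0 if angle == -180.0 else angle


def residue_kind(res: Residue, next_res: Residue | None) -> str:
    if res.aa == "G":
        return "glycine"
    if res.aa == "P":
        return "proline"
    if next_res is not None and next_res.aa == "P":
        return "pre-proline"
    return "general"


_CA_BREAK_DISTANCE = 4.5  # Angstrom; beyond this, consecutive residues are a chain break


def _is_break(prev: Residue, cur: Residue) -> bool:
    if cur.number - prev.number != 1 and not (cur.number == prev.number and cur.insertion_code):
        return True
    ca1, ca2 = prev.atom("CA"), cur.atom("CA")
    if ca1 is None or ca2 is None:
        return True
    return atom_distance(ca1, ca2) > _CA_BREAK_DISTANCE


def phi_psi(chain: Chain) -> list[DihedralRecord]:
    """Backbone phi/psi per residue, with terminal and chain-break flagging.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    The first phi and last psi are undefined; a numbering gap or a CA-CA
    distance above 4.5 A counts as a chain break and flags both neighbors.
    """
    res = chain.residues
    records: list[DihedralRecord] = []
    for i, r in enumerate(res):
        prev_ok = i > 0 and not _is_break(res[i - 1], r)
        next_ok = i < len(res) - 1 and not _is_break(r, res[i + 1])
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        phi = psi = None
        if None in (n, ca, c):
            logger.warning("residue %s missing backbone atoms; phi/psi undefined", r.label)
        else:
            if prev_ok:
                c_prev = res[i - 1].atom("C")
                if c_prev is not None:
                    try:
                        phi = dihedral(c_prev.coords, n.coords, ca.coords, c.coords)
                    except DegenerateGeometryError:
                        phi = None
            if next_ok:
                n_next = res[i + 1].atom("N")
                if n_next is not None:
                    try:
                        psi = dihedral(n.coords, ca.coords, c.coords, n_next.coords)
                    except DegenerateGeometryError:
                        psi = None
        if phi is None or psi is None:
            cls = "undefined"
        else:
            cls = classify_ramachandran(phi, psi, residue_kind(r, res[i + 1] if i < len(res) - 1 else None))
        records.append(DihedralRecord(residue_id=r.id, aa=r.aa, phi=phi, psi=psi, rama_class=cls))
    return records


# ---------------------------------------------------------------------------
# Coarse Ramachandran region grid
#
# A 10x10-degree three-level grid approximating the commonly used
# general / glycine / proline / pre-proline favored and allowed regions.
# Boxes are (phi_lo, phi_hi, psi_lo, psi_hi), half-open on the high edge.
# This is deliberately coarse: it classifies canonical secondary-structure
# torsions correctly but does not reproduce any published contour bit-exact.
# ---------------------------------------------------------------------------

_GRID_N = 36  # 10-degree bins


def _bin(angle: float) -> int:
    return min(int((angle + 180.0) // 10.0), _GRID_N - 1)


def _paint(grid: np.ndarray, boxes, level: int, expand: int = 0) -> None:
    for (plo, phi_, slo, shi) in boxes:
        i0, i1 = _bin(plo + 1e-9), _bin(phi_ - 1e-9)
        j0, j1 = _bin(slo + 1e-9), _bin(shi - 1e-9)
        for i in range(i0 - expand, i1 + expand + 1):
            for j in range(j0 - expand, j1 + expand + 1):
                ii, jj = i % _GRID_N, j % _GRID_N
                grid[ii, jj] = max(grid[ii, jj], level)


_GENERAL_FAVORED = [
    (-160, -40, -80, -10),    # right-handed alpha
    (-180, -50, 90, 180),     # beta / polyproline-II
    (-180, -50, -180, -160),  # beta, wrapped
]
_GENERAL_ALLOWED_EXTRA = [(40, 80, 0, 60)]  # left-handed alpha

_PRO_FAVORED = [(-90, -40, -60, -10), (-90, -40, 110, 180)]
_PREPRO_ALLOWED_EXTRA = _GENERAL_ALLOWED_EXTRA + [(-180, -40, 40, 90)]

# class levels: 0 outlier, 1 allowed, 2 favored
_LEVELS = {0: "outlier", 1: "allowed", 2: "favored"}


def _mirror(boxes):
    return [(-phi_, -plo, -shi, -slo) for (plo, phi_, slo, shi) in boxes]


def _build_grid(favored, allowed_extra) -> np.ndarray:
    g = np.zeros((_GRID_N, _GRID_N), dtype=np.int8)
    _paint(g, favored, 1, expand=2)        # allowed halo: 20 degrees around favored
    _paint(g, allowed_extra, 1)
    _paint(g, favored, 2)
    return g


_RAMA_GRIDS: dict[str, np.ndarray] = {
    "general": _build_grid(_GENERAL_FAVORED, _GENERAL_ALLOWED_EXTRA),
    "glycine": _build_grid(_GENERAL_FAVORED + _mirror(_GENERAL_FAVORED),
                           _GENERAL_ALLOWED_EXTRA + _mirror(_GENERAL_ALLOWED_EXTRA)),
    "proline": _build_grid(_PRO_FAVORED, []),
    "pre-proline": _build_grid(_GENERAL_FAVORED, _PREPRO_ALLOWED_EXTRA),
}


def classify_ramachandran(phi: float | None, psi: float | None, residue_kind: str = "general") -> str:
    """Classify a phi/psi pair as favored, allowed or outlier.

    Uses the packaged coarse 10x10-degree grid; deterministic. Undefined
    angles yield ``undefined``.
    """
    if phi is None or psi is None:
        return "undefined"
    if residue_kind not in _RAMA_GRIDS:
        raise ValueError(f"unknown residue kind {residue_kind!r}")
    grid = _RAMA_GRIDS[residue_kind]
    return _LEVELS[int(grid[_bin(phi), _bin(psi)])]
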