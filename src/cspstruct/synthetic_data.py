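"""Ground-truth generators: helical bundles and ortholog-family alignments.

Two emulations make the whole pipeline testable without any external data:

* a parametric alpha-helical bundle — ideal backbone geometry built from
  phi/psi torsions by internal-coordinate chain extension, helices arranged
  on a circle around a central axis, and a linear pseudo-ligand threaded
  along that axis. This stands in for the family's helical-bundle fold with
  a ligand in the central cavity.
* an ortholog-family alignment with a controlled per-column charge-flip
  rate: each group has a base sequence, and each species independently flips
  each column, with probability q, to a uniformly drawn letter of a
  *different* charge class (a designated subset of "selected" columns flips
  at an elevated rate). Because the target letter is drawn letter-uniformly,
  size classes vary as well, so size-profile code paths are exercised too.

Everything is bit-reproducible from (spec, seed). Side chains are not
generated; synthetic residues carry backbone N/CA/C/O plus a single
pseudo-CB, which is sufficient to exercise every geometric code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .family_map import (
    AlignedFamily,
    CHARGE_NEGATIVE,
    CHARGE_POSITIVE,
    FamilyRecord,
    STANDARD_AA,
    charge_class,
)
from .structio import Atom, Chain, ONE_TO_THREE, Residue, Structure, write_pdb

__all__ = [
    "BundleSpec",
    "FamilySpec",
    "GroundTruth",
    "build_helical_bundle",
    "bundle_pdb_text",
    "simulate_family",
    "family_fasta_text",
    "variable_column_probability",
    "estimate_flip_rate",
]

# Ideal backbone geometry (bond lengths in Angstrom, angles in degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_C_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.1
_OMEGA = 180.0

_AA_LIST = sorted(STANDARD_AA)


@dataclass
class BundleSpec:
    n_helices: int = 6
    residues_per_helix: int = 18
    bundle_radius: float = 8.0
    phi: float = -57.0
    psi: float = -47.0
    ligand_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 2:
            raise ValueError("need at least 1 helix of at least 2 residues")
        if self.ligand_length < 0:
            raise ValueError("ligand_length must be non-negative")


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d so that |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural-extension reference frame)."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        -bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O/CB coordinates for an ideal chain with fixed torsions."""
    theta = math.radians(_A_N_CA_C)
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = ca0 + _B_CA_C * np.array([math.cos(math.pi - theta), math.sin(math.pi - theta), 0.0])
    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = residues[-1]
        n_next = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = _place(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _place(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        prev["O"] = _place(prev["N"], prev["CA"], prev["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    last = residues[-1]
    last["O"] = _place(last["N"], last["CA"], last["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    for r in residues:
        r["CB"] = _place(r["N"], r["C"], r["CA"], _B_CA_CB, _A_C_CA_CB, 123.0)
    return residues


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``axis`` onto +z (Rodrigues)."""
    a = _normalize(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s, c = np.linalg.norm(v), float(np.dot(a, z))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def build_helical_bundle(spec: BundleSpec) -> tuple[Structure, dict[str, str]]:
    """Construct a helical bundle with a central pseudo-ligand.

    Helices (one chain each, named A, B, ...) are placed on a circle of
    ``bundle_radius`` around the z axis, antiparallel in alternation; the
    ligand is a linear chain of pseudo-carbons (HETATM residue ``LIG``) on
    the axis. Returns the structure and the per-chain one-letter sequences.
    Raises if the radius packs atoms closer than 1 A.
    """
    rng = np.random.default_rng(spec.seed)
    template = _build_backbone(spec.residues_per_helix, spec.phi, spec.psi)
    cas = np.array([r["CA"] for r in template])
    rot = _rotation_to_z(cas[-1] - cas[0])
    center = cas.mean(axis=0)

    structure = Structure(id=f"bundle-{spec.n_helices}h-seed{spec.seed}")
    sequences: dict[str, str] = {}
    serial = 1
    atom_coords: list[np.ndarray] = []
    chain_of_atom: list[int] = []
    for h in range(spec.n_helices):
        chain_id = chr(ord("A") + h)
        angle = 2 * math.pi * h / spec.n_helices
        offset = np.array([spec.bundle_radius * math.cos(angle),
                           spec.bundle_radius * math.sin(angle), 0.0])
        flip = np.diag([1.0, -1.0, -1.0]) if h % 2 else np.eye(3)
        seq = "".join(rng.choice(_AA_LIST, size=spec.residues_per_helix))
        sequences[chain_id] = seq
        chain = Chain(id=chain_id)
        for i, coords in enumerate(template):
            aa = seq[i]
            res = Residue(chain_id=chain_id, number=i + 1, insertion_code="",
                          name=ONE_TO_THREE[aa], aa=aa)
            for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")):
                pos = flip @ (rot @ (coords[name] - center)) + offset
                res.atoms.append(Atom(serial=serial, name=name, element=element, coords=pos))
                atom_coords.append(pos)
                chain_of_atom.append(h)
                serial += 1
            chain.residues.append(res)
        structure.chains.append(chain)

    if spec.ligand_length:
        lig = Residue(chain_id="L", number=1, insertion_code="", name="LIG", aa="",
                      hetero=True)
        z0 = -(spec.ligand_length - 1) * 1.53 / 2.0
        for i in range(spec.ligand_length):
            pos = np.array([0.0, 0.0, z0 + i * 1.53])
            lig.atoms.append(Atom(serial=serial, name=f"C{i + 1}", element="C", coords=pos))
            atom_coords.append(pos)
            chain_of_atom.append(-1)
            serial += 1
        structure.ligands.append(lig)

    # steric sanity: atoms of different chains (or chain vs ligand) must not
    # approach closer than 1 A, otherwise the requested radius is impossible
    pts = np.array(atom_coords)
    owners = np.array(chain_of_atom)
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(r=1.0):
        if owners[i] != owners[j]:
            raise ValueError(f"bundle_radius {spec.bundle_radius} A causes steric overlap "
                             "closer than 1 A between helices/ligand")
    return structure, sequences


def bundle_pdb_text(spec: BundleSpec) -> str:
    """PDB text for a bundle, with the generating spec recorded in a header."""
    structure, _ = build_helical_bundle(spec)
    remark = (f"synthetic helical bundle: n_helices={spec.n_helices} "
              f"residues_per_helix={spec.residues_per_helix} radius={spec.bundle_radius} "
              f"phi={spec.phi} psi={spec.psi} ligand_length={spec.ligand_length} "
              f"seed={spec.seed}")
    return write_pdb(structure, remarks=[remark])


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    base_length: int = 69
    n_species: int = 7
    groups: dict[str, float] = field(default_factory=lambda: {"1": 0.1})
    selected_columns: frozenset[int] = frozenset()
    q_selected: float = 0.5
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.selected_columns = frozenset(self.selected_columns)
        for q in list(self.groups.values()) + [self.q_selected, self.gap_rate]:
            if not 0.0 <= q <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if any(not 1 <= c <= self.base_length for c in self.selected_columns):
            raise ValueError("selected columns must lie within the base length")


@dataclass
class GroundTruth:
    charge_classes: dict[str, dict[str, list[str]]]   # group -> species -> per-column class
    flipped_columns: dict[tuple[str, str], list[int]]  # (group, species) -> 1-based columns
    variable_counts: dict[str, int]                    # group -> columns with >=2 classes
    analyzed_counts: dict[str, int]                    # group -> columns with >=2 non-gap species


def _species_codes(n: int) -> list[str]:
    return [chr(ord("A") + i) + "ant" for i in range(n)]


def simulate_family(spec: FamilySpec) -> tuple[AlignedFamily, GroundTruth]:
    """Simulate an ortholog-family alignment with known charge-flip structure.

    Per group: a base sequence is drawn letter-uniformly; each species flips
    each column with probability q (``q_selected`` on selected columns) to a
    uniform letter of a different charge class. Gaps are injected at
    ``gap_rate`` per (species, column). Ground truth is derived from the
    emitted letters, so it is consistent with the alignment by construction.
    """
    rng = np.random.default_rng(spec.seed)
    species = _species_codes(spec.n_species)
    records: list[FamilyRecord] = []
    truth = GroundTruth(charge_classes={}, flipped_columns={}, variable_counts={},
                        analyzed_counts={})
    letters_by_class = {
        "positive": sorted(CHARGE_POSITIVE),
        "negative": sorted(CHARGE_NEGATIVE),
        "neutral": sorted(STANDARD_AA - CHARGE_POSITIVE - CHARGE_NEGATIVE),
    }
    for group, q in spec.groups.items():
        base = rng.choice(_AA_LIST, size=spec.base_length)
        emitted: dict[str, str] = {}
        truth.charge_classes[group] = {}
        for sp in species:
            seq = []
            flipped = []
            for col in range(1, spec.base_length + 1):
                letter = base[col - 1]
                rate = spec.q_selected if col in spec.selected_columns else q
                if rng.random() < rate:
                    other = [l for cls, ls in letters_by_class.items()
                             if cls != charge_class(letter) for l in ls]
                    letter = rng.choice(other)
                    flipped.append(col)
                if spec.gap_rate and rng.random() < spec.gap_rate:
                    letter = "-"
                seq.append(letter)
            emitted[sp] = "".join(seq)
            truth.flipped_columns[(group, sp)] = flipped
            truth.charge_classes[group][sp] = [
                "gap" if l == "-" else charge_class(l) for l in emitted[sp]]
            records.append(FamilyRecord(id=f"{sp}CSP{group}", species=sp, group=group,
                                        sequence=emitted[sp]))
        n_var = n_analyzed = 0
        for col in range(spec.base_length):
            classes = {truth.charge_classes[group][sp][col] for sp in species
                       if truth.charge_classes[group][sp][col] != "gap"}
            nongap = sum(truth.charge_classes[group][sp][col] != "gap" for sp in species)
            if nongap < 2:
                continue
            n_analyzed += 1
            if len(classes) > 1:
                n_var += 1
        truth.variable_counts[group] = n_var
        truth.analyzed_counts[group] = n_analyzed
    return AlignedFamily(records=records), truth


def family_fasta_text(family: AlignedFamily) -> str:
    return "".join(f">{r.id}\n{r.sequence}\n" for r in family.records)


_CLASS_SIZES = {"positive": 2, "negative": 2, "neutral": 16}


def variable_column_probability(q: float, n_species: int) -> float:
    """Closed-form probability that a column is charge-variable.

    A column is variable unless all species end in the same charge class:
    either nobody flipped, or everybody flipped into one common class (flip
    targets are letter-uniform outside the base class, so the landing class
    is weighted by class size).
    """
    p_same = 0.0
    for c, size_c in _CLASS_SIZES.items():
        base_p = size_c / 20.0
        stay = (1.0 - q) ** n_species
        land = sum((q * size_d / (20.0 - size_c)) ** n_species
                   for d, size_d in _CLASS_SIZES.items() if d != c)
        p_same += base_p * (stay + land)
    return 1.0 - p_same


def estimate_flip_rate(observed_fraction: float, n_species: int) -> float:
    """Invert the closed-form variable-column probability to recover q.

    The probability is unimodal in q, not monotone: at q near 1 all species
    flip and can land in one common class, lowering the variable fraction
    again. Inversion is done on the increasing branch (q from 0 up to the
    maximizer), the regime a biological flip rate lives in; fractions at or
    above the achievable maximum return the maximizer.
    """
    if observed_fraction <= 0.0:
        return 0.0
    from scipy.optimize import minimize_scalar
    opt = minimize_scalar(lambda q: -variable_column_probability(q, n_species),
                          bounds=(0.0, 1.0), method="bounded")
    q_peak = float(opt.x)
    f_peak = variable_column_probability(q_peak, n_species)
    if observed_fraction >= f_peak:
        return q_peak
    return float(brentq(lambda q: variable_column_probability(q, n_species) - observed_fraction,
                        0.0, q_peak))
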