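"""Solvent-accessible surface area and surface-residue classification.

SASA is computed with the Shrake-Rupley numerical method: each heavy atom's
sphere (van der Waals radius + probe radius) is covered with a deterministic
Fibonacci lattice of test points, and the accessible fraction is the share
of points lying outside every neighbour's expanded sphere. Per-residue areas
are normalised by a theoretical maximum-ASA table (Tien et al. 2013 by
default), and residues with relative accessibility strictly above a
threshold (0.20 by default) form the surface set.

Surface "charge" here is residue-identity based: lysine and arginine count
positive, aspartate and glutamate negative; histidine is neutral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .family_map import CHARGE_NEGATIVE, CHARGE_POSITIVE
from .structio import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "SasaResult",
    "SurfaceSet",
    "ChargeProfile",
    "MAX_ASA_TIEN_2013",
    "shrake_rupley",
    "fibonacci_sphere",
    "relative_accessibility",
    "surface_residues",
    "surface_set_from_fractions",
    "charge_profile",
]

# Theoretical maximum solvent accessibility per residue (Tien et al. 2013), A^2.
MAX_ASA_TIEN_2013: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

ResId = tuple[str, int, str]


@dataclass
class SasaResult:
    structure_id: str
    per_atom: dict[tuple[ResId, str], float]
    per_residue: dict[ResId, float]
    residue_aa: dict[ResId, str]
    probe_radius: float
    n_points: int


@dataclass
class SurfaceSet:
    structure_id: str
    threshold: float
    members: frozenset[ResId]
    relative_accessibility: dict[ResId, float]


@dataclass
class ChargeProfile:
    structure_id: str
    n_positive: int
    n_negative: int


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden-angle spiral)."""
    k = np.arange(n_points)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(structure: Structure, probe_radius: float = 1.4, n_points: int = 960,
                  orientation: np.ndarray | None = None,
                  occlude_ligands: bool = False) -> SasaResult:
    """Shrake-Rupley SASA over all polymer heavy atoms.

    ``orientation`` optionally rotates the test-point lattice (3x3 rotation
    matrix); rotating it together with a rigidly moved molecule reproduces
    areas exactly, making rotation-invariance testable to machine precision.
    With ``occlude_ligands`` the bound hetero atoms block solvent but do not
    receive area themselves.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable point density")
    residues = structure.polymer_residues()
    atoms = [(res, a) for res in residues for a in res.heavy_atoms()]
    if not atoms:
        raise ValueError("structure has no polymer heavy atoms")

    coords = np.array([a.coords for _, a in atoms])
    radii = np.array([a.vdw_radius for _, a in atoms])
    occ_coords, occ_radii = coords, radii
    if occlude_ligands and structure.ligands:
        lig = [a for res in structure.ligands for a in res.heavy_atoms()]
        occ_coords = np.vstack([coords, [a.coords for a in lig]])
        occ_radii = np.concatenate([radii, [a.vdw_radius for a in lig]])

    unit = fibonacci_sphere(n_points)
    if orientation is not None:
        orientation = np.asarray(orientation, dtype=float)
        unit = unit @ orientation.T

    tree = cKDTree(occ_coords)
    expanded = occ_radii + probe_radius
    max_reach = expanded.max()

    per_atom: dict[tuple[ResId, str], float] = {}
    per_residue: dict[ResId, float] = {}
    residue_aa: dict[ResId, str] = {}
    for i, (res, atom) in enumerate(atoms):
        big_r = radii[i] + probe_radius
        pts = coords[i] + big_r * unit
        # candidate occluders: exact superset of spheres that can cover any test point
        neigh = tree.query_ball_point(coords[i], big_r + max_reach)
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            if j == i:  # occluder array starts with the polymer atoms in order
                continue
            d2 = np.einsum("ij,ij->i", pts - occ_coords[j], pts - occ_coords[j])
            accessible &= d2 > expanded[j] ** 2
        area = 4.0 * math.pi * big_r ** 2 * accessible.sum() / n_points
        per_atom[(res.id, atom.name)] = area
        per_residue[res.id] = per_residue.get(res.id, 0.0) + area
        residue_aa[res.id] = res.aa
    return SasaResult(structure_id=structure.id, per_atom=per_atom, per_residue=per_residue,
                      residue_aa=residue_aa, probe_radius=probe_radius, n_points=n_points)


def relative_accessibility(sasa: SasaResult,
                           max_asa_table: dict[str, float] | None = None) -> dict[ResId, float]:
    """Per-residue SASA divided by the residue type's maximum ASA.

    Values are not clamped at 1.0: extended termini can legitimately exceed
    the folded-context maximum, and classification only uses the threshold.
    """
    table = MAX_ASA_TIEN_2013 if max_asa_table is None else max_asa_table
    out: dict[ResId, float] = {}
    for rid, area in sasa.per_residue.items():
        aa = sasa.residue_aa[rid]
        if aa not in table:
            raise KeyError(f"residue {rid} has type {aa!r} absent from the max-ASA table")
        out[rid] = area / table[aa]
    return out


def surface_residues(sasa: SasaResult, max_asa_table: dict[str, float] | None = None,
                     threshold: float = 0.20) -> SurfaceSet:
    """Residues with relative accessibility strictly above ``threshold``."""
    rel = relative_accessibility(sasa, max_asa_table)
    return surface_set_from_fractions(rel, threshold=threshold, structure_id=sasa.structure_id)


def surface_set_from_fractions(fractions: dict, threshold: float = 0.20,
                               structure_id: str = "") -> SurfaceSet:
    """Apply the strict > threshold rule to precomputed accessibility fractions.

    Accepts any mapping residue-key -> fraction, so externally reported
    accessibility values (e.g. per-site means across several models) can be
    thresholded with the same rule as computed ones.
    """
    members = frozenset(k for k, v in fractions.items() if v > threshold)
    return SurfaceSet(structure_id=structure_id, threshold=threshold,
                      members=members, relative_accessibility=dict(fractions))


def charge_profile(surface: SurfaceSet, aa_by_residue: dict) -> ChargeProfile:
    """Count positively (K,R) and negatively (D,E) charged surface residues."""
    n_pos = n_neg = 0
    for rid in surface.members:
        aa = aa_by_residue[rid]
        if aa in CHARGE_POSITIVE:
            n_pos += 1
        elif aa in CHARGE_NEGATIVE:
            n_neg += 1
    return ChargeProfile(structure_id=surface.structure_id, n_positive=n_pos, n_negative=n_neg)
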