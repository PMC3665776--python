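"""Ligand-binding residues and binding-pocket size profiles.

A polymer residue is a binding residue when any of its heavy atoms lies
within a distance cutoff (5 A by default, inclusive) of any heavy atom of a
bound ligand; all ligand copies are pooled. The core binding set removes the
cysteine-bridge residues and the residues of the C-terminal helix, which is
not shared by all family members. Pocket "size" is the count of binding
residues in the small / intermediate / large side-chain classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from scipy.spatial import cKDTree

from .family_map import size_class
from .structio import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "BindingSet",
    "CoreBindingSet",
    "SizeProfile",
    "ligand_contact_residues",
    "core_binding_set",
    "size_profile",
    "compare_size_profiles",
    "load_binding_fixture",
]


@dataclass
class BindingSet:
    structure_id: str
    cutoff: float
    ligand_names: frozenset[str]
    members: frozenset
    member_labels: tuple[str, ...]


@dataclass
class CoreBindingSet:
    parent: BindingSet
    removed_cysteines: frozenset
    removed_last_helix: frozenset
    members: frozenset


@dataclass
class SizeProfile:
    sequence_id: str
    n_small: int
    n_intermediate: int
    n_large: int

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_small, self.n_intermediate, self.n_large)

    @property
    def total(self) -> int:
        return self.n_small + self.n_intermediate + self.n_large


def ligand_contact_residues(structure: Structure, ligand_names, cutoff: float = 5.0) -> BindingSet:
    """Polymer residues with a heavy atom within ``cutoff`` of any ligand heavy atom.

    The boundary is inclusive (min distance <= cutoff); hydrogens are ignored
    on both sides.
    """
    wanted = {n.strip().upper() for n in ligand_names}
    ligands = [res for res in structure.ligands if res.name in wanted]
    if not ligands:
        present = sorted({res.name for res in structure.ligands})
        raise ValueError(f"no ligand named {sorted(wanted)} in structure; "
                         f"hetero residues present: {present or 'none'}")
    lig_atoms = [a for res in ligands for a in res.heavy_atoms()]

    residues = structure.polymer_residues()
    atom_owner = []
    coords = []
    for res in residues:
        for a in res.heavy_atoms():
            atom_owner.append(res)
            coords.append(a.coords)
    tree = cKDTree(coords)
    members: set = set()
    labels: dict = {}
    for la in lig_atoms:
        for idx in tree.query_ball_point(la.coords, cutoff):
            res = atom_owner[idx]
            members.add(res.id)
            labels[res.id] = res.label
    ordered = sorted(members, key=lambda rid: (rid[0], rid[1], rid[2]))
    return BindingSet(structure_id=structure.id, cutoff=cutoff,
                      ligand_names=frozenset(wanted), members=frozenset(members),
                      member_labels=tuple(labels[rid] for rid in ordered))


def core_binding_set(binding: BindingSet, cysteine_bridge_residues, last_helix_residues) -> CoreBindingSet:
    """Remove cysteine-bridge and last-helix residues from a binding set.

    Both exclusion sets must be subsets of the binding members and disjoint
    from each other.
    """
    cys = frozenset(cysteine_bridge_residues)
    helix = frozenset(last_helix_residues)
    if not cys <= binding.members:
        raise ValueError(f"cysteine exclusions not all in the binding set: {sorted(cys - binding.members)}")
    if not helix <= binding.members:
        raise ValueError(f"last-helix exclusions not all in the binding set: {sorted(helix - binding.members)}")
    if cys & helix:
        raise ValueError(f"exclusion sets overlap: {sorted(cys & helix)}")
    remaining = binding.members - cys - helix
    return CoreBindingSet(parent=binding, removed_cysteines=cys,
                          removed_last_helix=helix, members=frozenset(remaining))


def size_profile(letters, sequence_id: str = "") -> SizeProfile:
    """Tally small / intermediate / large classes over binding-column letters.

    Gaps are skipped (and logged); any other non-standard letter is an error.
    """
    counts = {"small": 0, "intermediate": 0, "large": 0}
    for letter in letters:
        if letter == "-":
            logger.debug("sequence %s: gap at a binding column skipped", sequence_id)
            continue
        cls = size_class(letter)
        if cls == "unknown":
            raise ValueError(f"sequence {sequence_id!r}: non-standard letter {letter!r} at a binding column")
        counts[cls] += 1
    return SizeProfile(sequence_id=sequence_id, n_small=counts["small"],
                       n_intermediate=counts["intermediate"], n_large=counts["large"])


def compare_size_profiles(a: SizeProfile, b: SizeProfile):
    """Pearson chi-square on the 2x3 size-class table of two profiles.

    Size classes empty in both profiles are dropped before the test (the
    chi-square is undefined on zero margins); degrees of freedom follow the
    retained table.
    """
    from .stats import chisq_independence

    if a.total == 0 or b.total == 0:
        raise ValueError("both size profiles must have positive totals")
    table = [list(a.counts), list(b.counts)]
    keep = [j for j in range(3) if table[0][j] + table[1][j] > 0]
    if len(keep) < 2:
        raise ValueError("size profiles concentrate in one class; no comparison possible")
    if len(keep) < 3:
        logger.info("dropping %d empty size class(es) before the chi-square", 3 - len(keep))
    trimmed = [[row[j] for j in keep] for row in table]
    return chisq_independence(trimmed)


def load_binding_fixture() -> list[str]:
    """The 34 reference-structure binding-residue labels shipped with the package."""
    text = resources.files("cspstruct.data").joinpath("mbra_binding34.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
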