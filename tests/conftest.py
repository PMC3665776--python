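import numpy as np
import pytest

from cspstruct.structio import Atom, Chain, ONE_TO_THREE, Residue, Structure
from cspstruct.synthetic_data import BundleSpec, build_helical_bundle

_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_point_structure(points, elements=None, struct_id="cluster"):
    """One single-atom residue per coordinate; handy for SASA/contact oracles."""
    chain = Chain(id="A")
    st = Structure(id=struct_id, chains=[chain])
    for i, xyz in enumerate(points):
        el = "C" if elements is None else elements[i]
        res = Residue(chain_id="A", number=i + 1, insertion_code="", name="ALA", aa="A")
        res.atoms.append(Atom(serial=i + 1, name="CA", element=el, coords=np.asarray(xyz, float)))
        chain.residues.append(res)
    return st


def make_peptide(backbone, sequence, struct_id="peptide"):
    """Structure from per-residue {atom: coords} dicts (glycine gets no CB)."""
    chain = Chain(id="A")
    st = Structure(id=struct_id, chains=[chain])
    serial = 1
    for i, aa in enumerate(sequence):
        res = Residue(chain_id="A", number=i + 1, insertion_code="",
                      name=ONE_TO_THREE[aa], aa=aa)
        for name, coords in backbone[i].items():
            if name == "CB" and aa == "G":
                continue
            res.atoms.append(Atom(serial=serial, name=name, element=_ELEMENT_OF[name],
                                  coords=coords))
            serial += 1
        chain.residues.append(res)
    return st


@pytest.fixture(scope="session")
def bundle6():
    """The default six-helix bundle with an axial pseudo-ligand."""
    structure, sequences = build_helical_bundle(BundleSpec(seed=1))
    return structure, sequences


@pytest.fixture(scope="session")
def bundle6_sasa(bundle6):
    from cspstruct.surface import shrake_rupley
    structure, _ = bundle6
    return shrake_rupley(structure)


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.200   3.700   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.650   3.700   0.000  1.00  0.00           C
ATOM      9  C   SER A   3       8.200   5.100   0.000  1.00  0.00           C
HETATM   10  C1  LIG L   1       4.000   0.000   2.000  1.00  0.00           C
HETATM   11  O   HOH W   1       9.000   9.000   9.000  1.00  0.00           O
END
"""
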