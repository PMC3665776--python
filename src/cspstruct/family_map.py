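"""Family alignments: reading, reference-column mapping and residue classes.

A family alignment holds one aligned sequence per (species, ortholog group)
pair. Structural annotations made on one reference member (binding residues,
surface residues) are projected onto every other member through the shared
alignment columns, which is how per-species size and charge comparisons are
made without a structure for each species.

Residue classes follow the standard insect-CSP convention: size classes
small (S,T,C,G,P,A,V), intermediate (H,D,E,N,Q,I,L,M) and large (R,K,F,Y,W);
charge classes positive (K,R), negative (D,E) and neutral for everything
else, histidine included.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedFamily",
    "FamilyRecord",
    "ColumnMap",
    "ResidueClass",
    "read_alignment",
    "column_map",
    "project_residue_set",
    "pairwise_identity",
    "classify",
    "charge_class",
    "size_class",
    "SIZE_SMALL",
    "SIZE_INTERMEDIATE",
    "SIZE_LARGE",
    "CHARGE_POSITIVE",
    "CHARGE_NEGATIVE",
    "STANDARD_AA",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

SIZE_SMALL = set("STCGPAV")
SIZE_INTERMEDIATE = set("HDENQILM")
SIZE_LARGE = set("RKFYW")

CHARGE_POSITIVE = set("KR")
CHARGE_NEGATIVE = set("DE")

# The three size classes must partition the 20 standard amino acids.
assert SIZE_SMALL | SIZE_INTERMEDIATE | SIZE_LARGE == STANDARD_AA
assert not (SIZE_SMALL & SIZE_INTERMEDIATE or SIZE_SMALL & SIZE_LARGE
            or SIZE_INTERMEDIATE & SIZE_LARGE)

DEFAULT_ID_PATTERN = r"(?P<species>[A-Z][a-z]{3})CSP(?P<group>\d+)"


@dataclass(frozen=True)
class ResidueClass:
    aa: str
    size_class: str    # small | intermediate | large | unknown
    charge_class: str  # positive | negative | neutral


def size_class(aa: str) -> str:
    if aa in SIZE_SMALL:
        return "small"
    if aa in SIZE_INTERMEDIATE:
        return "intermediate"
    if aa in SIZE_LARGE:
        return "large"
    return "unknown"


def charge_class(aa: str) -> str:
    if aa in CHARGE_POSITIVE:
        return "positive"
    if aa in CHARGE_NEGATIVE:
        return "negative"
    return "neutral"


def classify(aa: str) -> ResidueClass:
    """Size and charge class of a one-letter residue code.

    Gaps and 'X' are flagged ``unknown``/``neutral`` rather than rejected,
    since projected columns legitimately contain them.
    """
    aa = aa.upper()
    return ResidueClass(aa=aa, size_class=size_class(aa), charge_class=charge_class(aa))


@dataclass
class FamilyRecord:
    id: str
    species: str | None
    group: str | None
    sequence: str


@dataclass
class AlignedFamily:
    records: list[FamilyRecord] = field(default_factory=list)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def get(self, record_id: str) -> FamilyRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(f"record {record_id!r} not in family")

    def by_group(self) -> dict[str, list[FamilyRecord]]:
        groups: dict[str, list[FamilyRecord]] = {}
        for r in self.records:
            if r.group is not None:
                groups.setdefault(r.group, []).append(r)
        return groups

    def species(self) -> set[str]:
        return {r.species for r in self.records if r.species is not None}


def read_alignment(source: str | os.PathLike, id_pattern: str = DEFAULT_ID_PATTERN) -> AlignedFamily:
    """Read an aligned FASTA into an :class:`AlignedFamily`.

    Species and ortholog-group labels are parsed from the record ids with
    ``id_pattern`` (named groups ``species`` and ``group``); records whose id
    does not match are kept with null labels and a warning.
    """
    pat = re.compile(id_pattern)
    src = os.fspath(source) if isinstance(source, os.PathLike) else source
    if "\n" in src or not os.path.exists(src):
        handle: io.TextIOBase | str = io.StringIO(src)
    else:
        handle = src
    records: list[FamilyRecord] = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        cleaned = []
        for ch in seq:
            if ch in STANDARD_AA or ch in "-X":
                cleaned.append(ch)
            else:
                logger.warning("record %s: letter %r treated as X", rec.id, ch)
                cleaned.append("X")
        m = pat.search(rec.id)
        if m is None:
            logger.warning("record id %r does not match the id pattern; labels set to None", rec.id)
            species = group = None
        else:
            species, group = m.group("species"), m.group("group")
        records.append(FamilyRecord(id=rec.id, species=species, group=group, sequence="".join(cleaned)))
    if len(records) < 2:
        raise ValueError("alignment must contain at least 2 records")
    length = len(records[0].sequence)
    for r in records:
        if len(r.sequence) != length:
            raise ValueError(f"ragged alignment: record {r.id!r} has length "
                             f"{len(r.sequence)}, expected {length}")
    return AlignedFamily(records=records)


@dataclass
class ColumnMap:
    reference_id: str
    number_to_column: dict[int, int]  # both 1-based
    coverage: float

    @property
    def column_to_number(self) -> dict[int, int]:
        return {c: n for n, c in self.number_to_column.items()}

    def column(self, residue_number: int) -> int:
        try:
            return self.number_to_column[residue_number]
        except KeyError:
            raise KeyError(f"residue number {residue_number} outside the reference map") from None


def column_map(family: AlignedFamily, reference_id: str, first_residue_number: int = 1) -> ColumnMap:
    """Map reference residue numbers to alignment columns (both 1-based).

    The k-th non-gap character of the reference sequence is residue
    ``first_residue_number + k - 1``; the offset accommodates constructs
    numbered from the precursor rather than the mature protein.
    """
    ref = family.get(reference_id)
    mapping: dict[int, int] = {}
    num = first_residue_number
    for col, ch in enumerate(ref.sequence, start=1):
        if ch != "-":
            mapping[num] = col
            num += 1
    if not mapping:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    return ColumnMap(reference_id=reference_id, number_to_column=mapping, coverage=1.0)


def project_residue_set(residue_numbers, cmap: ColumnMap, family: AlignedFamily,
                        target_id: str) -> list[tuple[int, str]]:
    """Project reference residue numbers onto a target sequence.

    Returns ``(alignment column, target letter)`` pairs in input order; a gap
    in the target at a projected column is reported as ``'-'``.
    """
    target = family.get(target_id)
    out: list[tuple[int, str]] = []
    for num in residue_numbers:
        col = cmap.column(num)
        letter = target.sequence[col - 1]
        if letter == "-":
            logger.debug("target %s gapped at column %d (ref residue %d)", target_id, col, num)
        out.append((col, letter))
    return out


def pairwise_identity(a: str, b: str, denominator: str = "shared") -> float:
    """Percent identity between two aligned sequences, to 0.1%.

    ``denominator='shared'`` divides identical matches by the number of
    columns where both sequences are non-gap; ``'shorter'`` divides by the
    shorter ungapped length instead.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    matches = shared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x != "-" and y != "-":
            shared += 1
            if x == y:
                matches += 1
    if denominator == "shared":
        denom = shared
    elif denominator == "shorter":
        denom = min(sum(c != "-" for c in a), sum(c != "-" for c in b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("no shared non-gap columns")
    return round(100.0 * matches / denom, 1)
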