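"""Chimeric mutant construction on a shared reference numbering.

Sequences are held as (residue, reference position) pairs derived from a
gapped alignment in which the reference sequence defines the numbering.
Region grafting replaces every reference position inside a named interval
with the donor's residues, honouring donor insertions/deletions, so grafted
products may change length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "KYTE_DOOLITTLE",
    "AlignedSequence",
    "RegionDefinition",
    "Substitution",
    "IndelSite",
    "DiffReport",
    "graft_regions",
    "diff_substitutions",
    "hydropathy_sum",
    "mutant_name",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Kyte-Doolittle per-residue hydropathy values.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class NumberingError(ValueError):
    """Raised when sequences disagree about the reference numbering."""


class UnknownRegionError(KeyError):
    """Raised when a graft names a region absent from the region map."""


@dataclass(frozen=True)
class AlignedSequence:
    """A sequence whose residues carry positions in a reference numbering.

    Parameters
    ----------
    id:
        Non-empty label.
    residues:
        One-letter residue codes, gaps already removed.
    ref_positions:
        1-based reference position of each residue, strictly increasing.
    """

    id: str
    residues: str
    ref_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) != len(self.ref_positions):
            raise ValueError("residues and ref_positions differ in length")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")
        pos = self.ref_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("ref_positions must be strictly increasing")

    @classmethod
    def from_gapped(cls, id: str, gapped: str, start: int = 1) -> "AlignedSequence":
        """Build from a gapped string where column ``i`` is position ``start+i``."""
        residues = []
        positions = []
        for offset, aa in enumerate(gapped):
            if aa == GAP:
                continue
            residues.append(aa)
            positions.append(start + offset)
        return cls(id=id, residues="".join(residues), ref_positions=tuple(positions))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def position_map(self) -> dict[int, str]:
        return dict(zip(self.ref_positions, self.residues))

    def residue_at(self, position: int) -> str | None:
        """Residue at a reference position, or None for a gap / uncovered site."""
        return self.position_map.get(position)

    def segment(self, start: int, end: int) -> str:
        """Residues with reference positions in the inclusive interval [start, end]."""
        return "".join(
            aa for aa, p in zip(self.residues, self.ref_positions) if start <= p <= end
        )


@dataclass(frozen=True)
class RegionDefinition:
    """Named inclusive interval [start, end] in reference numbering."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class Substitution:
    """Residue replacement at a reference position, e.g. ``E5Q``."""

    position: int
    original: str
    replacement: str

    def __post_init__(self) -> None:
        if self.original == self.replacement:
            raise ValueError("original equals replacement")

    @property
    def label(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"

    def reversed(self) -> "Substitution":
        return Substitution(self.position, self.replacement, self.original)


@dataclass(frozen=True)
class IndelSite:
    """Reference position present in exactly one of two compared sequences."""

    position: int
    residue: str
    kind: str  # "deletion": in a but not b; "insertion": in b but not a

    @property
    def label(self) -> str:
        mark = "del" if self.kind == "deletion" else "ins"
        return f"{self.residue}{self.position}{mark}"


@dataclass
class DiffReport:
    substitutions: list[Substitution] = field(default_factory=list)
    indels: list[IndelSite] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        """Total count of differing reference positions (substitutions + indels)."""
        return len(self.substitutions) + len(self.indels)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.substitutions] + [i.label for i in self.indels]


def graft_regions(
    base: AlignedSequence,
    donor: AlignedSequence,
    regions: Iterable[RegionDefinition],
    product_id: str | None = None,
) -> AlignedSequence:
    """Replace the named regions of ``base`` with the donor's residues.

    Inside any listed interval the product carries the donor's residues
    (including donor insertions/deletions); elsewhere the base's. Residues
    keep their reference positions, so no renumbering happens downstream of
    a length-changing graft.
    """
    regions = list(regions)
    covered = set(base.ref_positions) | set(donor.ref_positions)
    for region in regions:
        if not any(region.start <= p <= region.end for p in covered):
            raise ValueError(
                f"region {region.name} [{region.start},{region.end}] is outside "
                "both sequences' coverage"
            )

    def grafted(position: int) -> bool:
        return any(position in r for r in regions)

    merged: list[tuple[int, str]] = []
    for p, aa in zip(donor.ref_positions, donor.residues):
        if grafted(p):
            merged.append((p, aa))
    for p, aa in zip(base.ref_positions, base.residues):
        if not grafted(p):
            merged.append((p, aa))
    merged.sort()
    if product_id is None:
        product_id = f"{base.id}+graft"
    return AlignedSequence(
        id=product_id,
        residues="".join(aa for _, aa in merged),
        ref_positions=tuple(p for p, _ in merged),
    )


def diff_substitutions(a: AlignedSequence, b: AlignedSequence) -> DiffReport:
    """Per-position differences between two sequences on shared numbering.

    Positions where both carry a residue and they differ become
    :class:`Substitution` records; positions covered by only one of the two
    become :class:`IndelSite` records. Both lists are position-sorted.
    """
    map_a, map_b = a.position_map, b.position_map
    report = DiffReport()
    for p in sorted(set(map_a) | set(map_b)):
        ra, rb = map_a.get(p), map_b.get(p)
        if ra is not None and rb is not None:
            if ra != rb:
                report.substitutions.append(Substitution(p, ra, rb))
        elif ra is not None:
            report.indels.append(IndelSite(p, ra, "deletion"))
        else:
            report.indels.append(IndelSite(p, rb, "insertion"))
    return report


def hydropathy_sum(segment: str, scale: Mapping[str, float] = KYTE_DOOLITTLE) -> float:
    """Sum (not mean) of per-residue hydropathy values over a segment.

    The sum is the quantity used for loop comparisons here: it weighs both
    composition and length of a loop, unlike the length-normalised GRAVY
    mean. An empty segment scores 0.
    """
    missing = sorted(set(segment) - set(scale))
    if missing:
        raise KeyError(f"residues not in hydropathy scale: {missing}")
    return sum(scale[aa] for aa in segment)


def mutant_name(
    base_id: str,
    region_names: Iterable[str],
    components: Mapping[str, Sequence[str]],
    component_order: Sequence[str],
) -> str:
    """Deterministic mutant label from grafted region names.

    ``components`` maps a display component (e.g. ``N/C``) to the region
    names it covers (``[NT, CT]``); components appear in ``component_order``.
    Region names not covered by any listed component are appended in
    alphabetical order.
    """
    names = set(region_names)
    parts: list[str] = []
    for comp in component_order:
        covered = set(components.get(comp, ()))
        if covered and covered <= names:
            parts.append(comp)
            names -= covered
    parts.extend(sorted(names))
    if not parts:
        return base_id
    return base_id + "-" + "/".join(parts)
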