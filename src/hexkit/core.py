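"""Domain types for a haplotype-resolved hexaploid karyotype.

The genomes handled here have the structure of the Prussian carp
(*Carassius gibelio*): 25 homeologous chromosome groups, each present in
two allopolyploid subgenomes (A and B) and three autopolyploid haplotypes
(a, b, c), for 150 chromosomes in total.  Every chromosome is addressed by
the canonical name ``"<group><subgenome><haplotype>"``, e.g. ``"22Ba"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

SUBGENOMES = ("A", "B")
HAPLOTYPES = ("a", "b", "c")

_NAME_RE = re.compile(r"^(\d+)([A-Za-z])([A-Za-z])$")


class ChromosomeNameError(ValueError):
    """A chromosome name that does not follow <group><A|B><a|b|c>."""


@dataclass(frozen=True, order=True)
class ChromosomeID:
    """Identity of one chromosome: homeologous group, subgenome, haplotype."""

    group: int
    subgenome: str
    haplotype: str

    def __str__(self) -> str:
        return f"{self.group}{self.subgenome}{self.haplotype}"

    @classmethod
    def parse(cls, name: str, max_group: int = 25) -> "ChromosomeID":
        m = _NAME_RE.match(name.strip())
        if not m:
            raise ChromosomeNameError(f"malformed chromosome name: {name!r}")
        group = int(m.group(1))
        subgenome, haplotype = m.group(2), m.group(3)
        if not 1 <= group <= max_group:
            raise ChromosomeNameError(
                f"group {group} out of range 1-{max_group} in {name!r}"
            )
        if subgenome not in SUBGENOMES:
            raise ChromosomeNameError(f"subgenome {subgenome!r} not in A/B in {name!r}")
        if haplotype not in HAPLOTYPES:
            raise ChromosomeNameError(
                f"haplotype {haplotype!r} not in a/b/c in {name!r}"
            )
        return cls(group, subgenome, haplotype)


def parse_chrom_name(name: str, max_group: int = 25) -> ChromosomeID:
    """Parse a canonical chromosome name like ``"22Ba"``.

    Round-trips: ``str(parse_chrom_name(n)) == n`` for canonical *n*.
    """
    return ChromosomeID.parse(name, max_group=max_group)


@dataclass
class ValidationReport:
    """Result of checking a :class:`GenomeStructure` for completeness."""

    missing_cells: list[ChromosomeID] = field(default_factory=list)
    duplicate_cells: list[ChromosomeID] = field(default_factory=list)
    bad_lengths: list[ChromosomeID] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_cells or self.duplicate_cells or self.bad_lengths)

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok


class GenomeStructure:
    """The chromosome inventory: one entry per (group, subgenome, haplotype).

    Parameters
    ----------
    chromosomes
        Iterable of ``(ChromosomeID, length_bp)`` pairs.
    n_groups
        Number of homeologous groups expected (default 25, giving the
        150-chromosome hexaploid karyotype).
    """

    def __init__(
        self,
        chromosomes: Iterable[tuple[ChromosomeID, int]],
        n_groups: int = 25,
    ):
        self.n_groups = n_groups
        self._entries: list[tuple[ChromosomeID, int]] = list(chromosomes)
        self._lengths: dict[ChromosomeID, int] = {}
        for cid, length in self._entries:
            self._lengths.setdefault(cid, length)

    @property
    def chromosomes(self) -> list[ChromosomeID]:
        return [cid for cid, _ in self._entries]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, cid: ChromosomeID) -> bool:
        return cid in self._lengths

    def __iter__(self) -> Iterator[ChromosomeID]:
        return iter(self.chromosomes)

    def length(self, cid: ChromosomeID) -> int:
        return self._lengths[cid]

    def length_mbp(self, cid: ChromosomeID) -> float:
        return self._lengths[cid] / 1e6

    def triplets(self) -> list[tuple[int, str, tuple[ChromosomeID, ...]]]:
        """All (group, subgenome) haplotype triplets, 2 × n_groups of them."""
        out = []
        for g in range(1, self.n_groups + 1):
            for s in SUBGENOMES:
                out.append(
                    (g, s, tuple(ChromosomeID(g, s, h) for h in HAPLOTYPES))
                )
        return out

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        seen: dict[ChromosomeID, int] = {}
        for cid, length in self._entries:
            seen[cid] = seen.get(cid, 0) + 1
            if length <= 0 and cid not in report.bad_lengths:
                report.bad_lengths.append(cid)
        for cid, n in seen.items():
            if n > 1:
                report.duplicate_cells.append(cid)
        for g in range(1, self.n_groups + 1):
            for s in SUBGENOMES:
                for h in HAPLOTYPES:
                    cid = ChromosomeID(g, s, h)
                    if cid not in seen:
                        report.missing_cells.append(cid)
        return report


def validate_structure(structure: GenomeStructure) -> ValidationReport:
    """Report missing/duplicated (group, subgenome, haplotype) cells and
    non-positive lengths.  Empty report iff the inventory is a complete
    ``n_groups × 2 × 3`` grid with positive lengths."""
    return structure.validate()


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated interval (TE copy or gene) on a chromosome.

    Coordinates are 1-based inclusive, matching GFF3 and RepeatMasker
    conventions; BED input is converted on read.  Strand is retained but
    ignored by all downstream statistics.
    """

    chromosome: ChromosomeID
    start: int
    end: int
    kind: str
    strand: str = "."

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"bad coordinates {self.start}-{self.end} on {self.chromosome}"
            )
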