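"""Subgenome- and haplotype-resolved duplicate gene loss accounting.

After allopolyploidy, duplicated genes return to single copy
(rediploidization); whether loss hits both subgenomes evenly or one
preferentially is measured here on a conserved gene catalog (BUSCO-style,
4584 actinopterygian genes in the motivating system).  The unit of
presence is one (species, subgenome, haplotype) copy; a gene is *missing
from a subgenome* only when absent from every haplotype copy of that
subgenome — the only reading under which cross-species overlap counts are
well defined when comparator genomes are collapsed to one copy per
subgenome.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUBGENOME_PARTITION = "by_subgenome"
HAPLOTYPE_PARTITION = "by_haplotype"
COPY_PARTITION = "by_copy"


class PresenceMatrix:
    """Gene × (species, subgenome, haplotype) presence/absence.

    Backed by a boolean DataFrame whose columns are a 3-level MultiIndex
    ``(species, subgenome, haplotype)``; collapsed comparator genomes carry
    a single pseudo-haplotype.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 3:
            raise ValueError(
                "columns must be a (species, subgenome, haplotype) MultiIndex"
            )
        if data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if data.isna().any().any():
            raise ValueError("every cell must be defined")
        self.data = data.astype(bool)

    @property
    def n_genes(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def species(self) -> list[str]:
        return sorted(self.data.columns.get_level_values(0).unique())

    def subgenomes(self, species: str) -> list[str]:
        return sorted(self.data[species].columns.get_level_values(0).unique())

    def haplotypes(self, species: str, subgenome: str) -> list[str]:
        return sorted(self.data[species][subgenome].columns)


def missing_sets(
    matrix: PresenceMatrix, partition: str
) -> dict[tuple[str, str], set[str]]:
    """Missing-gene sets per unit per species.

    ``by_copy``: one set per (subgenome, haplotype) copy, keyed
    ``(species, "<S><h>")``.  ``by_subgenome``: genes absent from *all*
    haplotype copies of a subgenome, keyed ``(species, "A"|"B")``.
    ``by_haplotype``: genes absent from both subgenome copies of a
    haplotype, keyed ``(species, "a"|"b"|"c")``.
    """
    out: dict[tuple[str, str], set[str]] = {}
    if partition == COPY_PARTITION:
        for col in matrix.data.columns:
            sp, s, h = col
            absent = matrix.data.index[~matrix.data[col]]
            out[(sp, f"{s}{h}")] = set(absent)
    elif partition == SUBGENOME_PARTITION:
        for sp in matrix.species:
            for s in matrix.subgenomes(sp):
                block = matrix.data[sp][s]
                absent = matrix.data.index[~block.any(axis=1)]
                out[(sp, s)] = set(absent)
    elif partition == HAPLOTYPE_PARTITION:
        for sp in matrix.species:
            haps = sorted(
                {h for _s, h in matrix.data[sp].columns}
            )
            for h in haps:
                cols = [
                    (s, hh) for s, hh in matrix.data[sp].columns if hh == h
                ]
                block = matrix.data[sp][cols]
                absent = matrix.data.index[~block.any(axis=1)]
                out[(sp, h)] = set(absent)
    else:
        raise ValueError(f"unknown partition {partition!r}")
    return out


@dataclass
class LossRatio:
    count_a: int
    count_b: int
    ratio: float | None  # None when count_b == 0
    rounded: float | None = None

    def __post_init__(self):
        if self.ratio is not None and self.rounded is None:
            self.rounded = round(self.ratio, 1)


def loss_ratio(count_a: int, count_b: int) -> LossRatio:
    """A/B loss ratio with one-decimal rounding alongside full precision."""
    if count_b == 0:
        return LossRatio(count_a, count_b, None)
    return LossRatio(count_a, count_b, count_a / count_b)


def overlap_counts(
    missing: dict[tuple[str, str], set[str]],
    species: list[str],
    unit: str,
    complement_unit: str | None = None,
    universe: set[str] | None = None,
) -> dict[str, int]:
    """Cross-species overlap of missing sets for one unit.

    ``shared_specific`` counts genes missing in ``unit`` of *every* listed
    species and (when ``complement_unit`` is given) present in the
    complementary unit of every species — e.g. lost from subgenome A in
    all species but retained in B everywhere.  Full inclusion–exclusion
    cells over the species' missing sets are included under keys like
    ``"only:sp1"``, ``"sp1&sp2"``.
    """
    sets = {sp: missing[(sp, unit)] for sp in species}
    shared = set.intersection(*sets.values()) if sets else set()
    if complement_unit is not None:
        for sp in species:
            comp_missing = missing[(sp, complement_unit)]
            shared = {g for g in shared if g not in comp_missing}
    out = {"shared_specific": len(shared)}
    # inclusion-exclusion cells: exact membership patterns
    union = set.union(*sets.values()) if sets else set()
    for r in range(1, len(species) + 1):
        for combo in itertools.combinations(species, r):
            cell = set.intersection(*(sets[sp] for sp in combo))
            for sp in species:
                if sp not in combo:
                    cell = cell - sets[sp]
            key = "&".join(combo) if r > 1 else f"only:{combo[0]}"
            out[key] = len(cell)
    out["union"] = len(union)
    if universe is not None:
        out["none"] = len(universe - union)
    return out


@dataclass
class ComplementarityReport:
    species: str
    combined_missing: set[str] = field(default_factory=set)
    combined_missing_pct: float = 0.0
    retained: pd.DataFrame | None = None  # per subgenome-missing gene


def complementarity(matrix: PresenceMatrix, species: str) -> ComplementarityReport:
    """Combined A+B missing fraction and duplicate-retention table.

    A gene is combined-missing when absent from every copy of both
    subgenomes; the retained table marks, for each subgenome-missing gene,
    whether the other subgenome still carries it (the signature of
    equilibrated, complementary loss).
    """
    by_sub = missing_sets(matrix, SUBGENOME_PARTITION)
    subs = matrix.subgenomes(species)
    if len(subs) != 2:
        raise ValueError(f"species {species} does not have two subgenomes")
    sa, sb = subs
    miss_a, miss_b = by_sub[(species, sa)], by_sub[(species, sb)]
    combined = miss_a & miss_b
    rows = []
    for g in sorted(miss_a | miss_b):
        lost_in = [s for s, m in ((sa, miss_a), (sb, miss_b)) if g in m]
        rows.append(
            {
                "gene": g,
                "missing_from": "+".join(lost_in),
                "retained_elsewhere": len(lost_in) == 1,
            }
        )
    retained = pd.DataFrame(rows, columns=["gene", "missing_from", "retained_elsewhere"])
    return ComplementarityReport(
        species=species,
        combined_missing=combined,
        combined_missing_pct=100.0 * len(combined) / matrix.n_genes,
        retained=retained,
    )


def deletion_candidates(
    matrix: PresenceMatrix,
    species: str,
    annotation_missing: dict[str, set[str]],
    coverage: pd.DataFrame,
    band: tuple[float, float] = (0.5, 1.5),
) -> pd.DataFrame:
    """Genes putatively deleted after the autopolyploidization.

    A gene qualifies when it is absent in *exactly one* haplotype by both
    evidence lines (the presence matrix and an independent annotation
    screen, ``annotation_missing`` keyed by haplotype), and the haploid
    sequencing coverage of every remaining allele lies in
    ``band × median`` — alleles far above the single-copy band indicate a
    collapsed assembly rather than a true deletion.  Genes lacking
    coverage rows are excluded with a logged reason.

    ``coverage`` needs columns ``gene, chrom, mean_haploid_cov``.
    """
    lo, hi = band
    by_hap = missing_sets(matrix, HAPLOTYPE_PARTITION)
    haps = sorted({h for (sp, h) in by_hap if sp == species})
    cov_median = float(coverage["mean_haploid_cov"].median())
    cov_by_gene = {g: grp for g, grp in coverage.groupby("gene")}

    rows = []
    for g in matrix.genes:
        missing_haps = [h for h in haps if g in by_hap[(species, h)]]
        anno_haps = [h for h in haps if g in annotation_missing.get(h, set())]
        if len(missing_haps) != 1 or missing_haps != anno_haps:
            continue
        grp = cov_by_gene.get(g)
        if grp is None or grp.empty:
            log.info("deletion candidate %s skipped: no coverage rows", g)
            continue
        rel = grp["mean_haploid_cov"] / cov_median
        in_band = bool(((rel >= lo) & (rel <= hi)).all())
        rows.append(
            {
                "gene": g,
                "missing_haplotype": missing_haps[0],
                "min_rel_cov": float(rel.min()),
                "max_rel_cov": float(rel.max()),
                "candidate": in_band,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "missing_haplotype", "min_rel_cov", "max_rel_cov", "candidate"],
    )
    return df[df["candidate"]].reset_index(drop=True) if not df.empty else df


def loss_report(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-unit missing percentages for every species, both partitions."""
    rows = []
    for partition in (COPY_PARTITION, SUBGENOME_PARTITION, HAPLOTYPE_PARTITION):
        for (sp, unit), genes in sorted(missing_sets(matrix, partition).items()):
            rows.append(
                {
                    "species": sp,
                    "partition": partition,
                    "unit": unit,
                    "n_missing": len(genes),
                    "missing_pct": 100.0 * len(genes) / matrix.n_genes,
                }
            )
    return pd.DataFrame(rows)
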