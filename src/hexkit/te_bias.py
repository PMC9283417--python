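"""TE densities and the subgenome-biased index (SBI).

The SBI distinguishes allo- from autopolyploid origin of the three
haplotypes of each chromosome.  For one TE family, over all haplotype
triplets i (a, b, c of a chromosome group in each subgenome; 50 triplets in
the default 25-group karyotype):

    SBI = sum_i |D_ab,i - D_ac,i| / sum_i (D_ab,i + D_ac,i)

where D_xy,i = |f_x,i - f_y,i| is the absolute difference of the family's
copy counts on haplotypes x and y of triplet i.  A TE found on only one
haplotype of every triplet drives the SBI toward 1 (allopolyploid-like
haplotype specificity); a TE spread evenly over the triplet gives small
values.  The SBI is undefined when the denominator is 0 — absence of signal
is not evidence of either ploidy mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import HAPLOTYPES, SUBGENOMES, ChromosomeID, FeatureRecord, GenomeStructure


class TETable:
    """Counts of each TE family on each chromosome of a genome structure."""

    def __init__(
        self,
        counts: Mapping[tuple[str, ChromosomeID], int],
        structure: GenomeStructure,
    ):
        self.structure = structure
        self._counts: dict[tuple[str, ChromosomeID], int] = {}
        for (fam, cid), n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for {fam} on {cid}")
            if cid not in structure:
                raise KeyError(f"chromosome {cid} absent from structure")
            self._counts[(fam, cid)] = int(n)

    @classmethod
    def from_features(
        cls, features: Iterable[FeatureRecord], structure: GenomeStructure
    ) -> "TETable":
        counts: dict[tuple[str, ChromosomeID], int] = {}
        for f in features:
            key = (f.kind, f.chromosome)
            counts[key] = counts.get(key, 0) + 1
        return cls(counts, structure)

    @property
    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self._counts})

    def count(self, family: str, cid: ChromosomeID) -> int:
        return self._counts.get((family, cid), 0)

    def to_frame(self) -> pd.DataFrame:
        """Family × chromosome count matrix (zeros filled in)."""
        chroms = self.structure.chromosomes
        data = {
            str(cid): [self.count(f, cid) for f in self.families] for cid in chroms
        }
        return pd.DataFrame(data, index=self.families)


@dataclass
class BiasReport:
    """Per-family SBI, A/B bias index and classification."""

    family: str
    sbi: float | None
    ab_index: float | None
    ab_direction: str | None  # which subgenome dominates, when defined
    label: str = "unclassified"


def te_density(
    te_table: TETable, structure: GenomeStructure | None = None
) -> pd.DataFrame:
    """Copies per Mbp: count / (length_bp / 1e6), per family × chromosome."""
    structure = structure or te_table.structure
    counts = te_table.to_frame()
    lengths_mbp = pd.Series(
        {str(cid): structure.length_mbp(cid) for cid in structure}
    )
    if (lengths_mbp <= 0).any():
        raise ValueError("non-positive chromosome length")
    return counts.div(lengths_mbp[counts.columns], axis=1)


def _triplet_counts(
    te_table: TETable, family: str, use_density: bool = False
) -> list[tuple[float, float, float]]:
    out = []
    for _g, _s, (ca, cb, cc) in te_table.structure.triplets():
        f = [float(te_table.count(family, c)) for c in (ca, cb, cc)]
        if use_density:
            f = [
                v / te_table.structure.length_mbp(c)
                for v, c in zip(f, (ca, cb, cc))
            ]
        out.append(tuple(f))
    return out


def sbi(
    te_table: TETable,
    family: str,
    *,
    use_density: bool = False,
    symmetrize: bool = False,
) -> float | None:
    """Subgenome-biased index for one TE family; ``None`` when undefined.

    ``symmetrize=True`` evaluates the index with each haplotype as the
    pivot in turn and returns the maximum — a sensitivity variant; the
    default is the a-pivot formula exactly as defined.
    """
    triplets = _triplet_counts(te_table, family, use_density=use_density)

    def index_for_pivot(p: int) -> float | None:
        o1, o2 = [j for j in range(3) if j != p]
        num = den = 0.0
        for f in triplets:
            d1 = abs(f[p] - f[o1])
            d2 = abs(f[p] - f[o2])
            num += abs(d1 - d2)
            den += d1 + d2
        return None if den == 0 else num / den

    if not symmetrize:
        return index_for_pivot(0)
    vals = [v for p in range(3) if (v := index_for_pivot(p)) is not None]
    return max(vals) if vals else None


def ab_bias_index(te_table: TETable, family: str) -> tuple[float | None, str | None]:
    """A-vs-B bias of a TE family: sum_i |g_A,i - g_B,i| / sum_i (g_A,i + g_B,i)
    over homeologous groups i, with g_S,i the family's total count on the
    three haplotypes of subgenome S in group i.  Returns (index, dominant
    subgenome); (None, None) when the family is absent everywhere.
    """
    num = den = 0.0
    tot = {s: 0.0 for s in SUBGENOMES}
    for g in range(1, te_table.structure.n_groups + 1):
        gs = {
            s: sum(
                te_table.count(family, ChromosomeID(g, s, h)) for h in HAPLOTYPES
            )
            for s in SUBGENOMES
        }
        num += abs(gs["A"] - gs["B"])
        den += gs["A"] + gs["B"]
        for s in SUBGENOMES:
            tot[s] += gs[s]
    if den == 0:
        return None, None
    direction = "A" if tot["A"] >= tot["B"] else "B"
    return num / den, direction


def classify_te(
    report: BiasReport, sbi_threshold: float = 0.8, ab_threshold: float = 0.5
) -> str:
    """Label a family from its indices.

    haplotype-biased if SBI ≥ sbi_threshold; else A-/B-biased if the A/B
    index ≥ ab_threshold; else unbiased; undefined indices → undefined.
    """
    if not (0 < sbi_threshold <= 1 and 0 < ab_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if report.sbi is None or report.ab_index is None:
        return "undefined"
    if report.sbi >= sbi_threshold:
        return "haplotype-biased"
    if report.ab_index >= ab_threshold:
        return f"{report.ab_direction}-biased"
    return "unbiased"


def bias_report(
    te_table: TETable,
    sbi_threshold: float = 0.8,
    ab_threshold: float = 0.5,
    **sbi_kwargs,
) -> list[BiasReport]:
    """SBI, A/B index and label for every family in the table."""
    reports = []
    for fam in te_table.families:
        s = sbi(te_table, fam, **sbi_kwargs)
        ab, direction = ab_bias_index(te_table, fam)
        rep = BiasReport(fam, s, ab, direction)
        rep.label = classify_te(rep, sbi_threshold, ab_threshold)
        reports.append(rep)
    return reports


def bias_report_frame(reports: list[BiasReport]) -> pd.DataFrame:
    rows = [
        {
            "te_family": r.family,
            "sbi": math.nan if r.sbi is None else r.sbi,
            "ab_index": math.nan if r.ab_index is None else r.ab_index,
            "ab_direction": r.ab_direction or "",
            "label": r.label,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
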