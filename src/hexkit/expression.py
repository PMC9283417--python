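"""Per-chromosome expression totals and homeolog expression-bias labels.

RNA-seq read counts per gene and organ are totalled per chromosome (raw
and per-million normalized, mirroring chromosome-level read-count plots)
and compared across the six copies of each homeolog group to ask whether
one subgenome or haplotype dominates expression.  Labels are assigned per
group and organ: dominant when one side's summed share exceeds
``dominance_fold`` times the other's, silent below a minimum-count floor,
balanced otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import HAPLOTYPES, SUBGENOMES, ChromosomeID

UNASSIGNED = "unassigned"


@dataclass
class ExpressionMatrix:
    """Gene × organ raw counts with a gene → chromosome map."""

    counts: pd.DataFrame  # index: gene, columns: organs
    gene_chrom: dict[str, ChromosomeID]
    library_sizes: pd.Series = field(default=None)

    def __post_init__(self):
        if (self.counts < 0).any().any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)

    @property
    def organs(self) -> list[str]:
        return list(self.counts.columns)


def chrom_totals(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromosome × organ totals, raw and counts-per-million.

    Genes without a chromosome assignment are bucketed as ``unassigned``
    so that per-organ totals are conserved.
    """
    chrom_of = pd.Series(
        {
            g: str(matrix.gene_chrom[g]) if g in matrix.gene_chrom else UNASSIGNED
            for g in matrix.counts.index
        }
    )
    raw = matrix.counts.groupby(chrom_of).sum()
    lib = matrix.library_sizes
    if (lib <= 0).any():
        # an all-zero organ normalizes to zero rather than dividing by zero
        cpm = raw.copy().astype(float)
        for organ in raw.columns:
            cpm[organ] = (
                raw[organ] * 1e6 / lib[organ] if lib[organ] > 0 else 0.0
            )
    else:
        cpm = raw * 1e6 / lib
    return raw, cpm


@dataclass
class HomeologGroup:
    """Up to six member genes of one homeologous group, keyed by copy."""

    group: int
    members: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        for (s, h) in self.members:
            if s not in SUBGENOMES or h not in HAPLOTYPES:
                raise ValueError(f"bad member key ({s}, {h})")


def homeolog_bias(
    group: HomeologGroup,
    matrix: ExpressionMatrix,
    organ: str,
    dominance_fold: float = 2.0,
    min_count: int = 10,
) -> str:
    """Expression-bias label for one homeolog group in one organ.

    Returns one of ``A-dominant``, ``B-dominant``,
    ``haplotype-dominant:<h>``, ``balanced``, ``silent``.
    """
    if not group.members:
        raise ValueError("empty homeolog group")
    counts = {
        key: float(matrix.counts.at[gene, organ])
        if gene in matrix.counts.index
        else 0.0
        for key, gene in group.members.items()
    }
    total = sum(counts.values())
    if total < min_count:
        return "silent"
    by_sub = {
        s: sum(v for (ss, _h), v in counts.items() if ss == s) for s in SUBGENOMES
    }
    winner = max(SUBGENOMES, key=lambda s: by_sub[s])
    loser = "B" if winner == "A" else "A"
    if by_sub[winner] >= dominance_fold * by_sub[loser] and by_sub[winner] > 0:
        # within the winning subgenome, is one haplotype itself dominant?
        by_hap = {
            h: sum(v for (s, hh), v in counts.items() if s == winner and hh == h)
            for h in HAPLOTYPES
        }
        top = max(by_hap, key=lambda h: by_hap[h])
        rest = sum(v for h, v in by_hap.items() if h != top)
        if by_hap[top] >= dominance_fold * rest and by_hap[top] > 0:
            return f"haplotype-dominant:{top}"
        return f"{winner}-dominant"
    return "balanced"


def bias_summary(
    groups: list[HomeologGroup],
    matrix: ExpressionMatrix,
    dominance_fold: float = 2.0,
    min_count: int = 10,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Contingency of bias labels × organs and a per-organ dominance flag.

    The flag for an organ is raised only when one subgenome dominates in
    more than half of the expressed (non-silent) groups — the global
    pattern absent from an equilibrated polyploid.
    """
    records = []
    for organ in matrix.organs:
        for grp in groups:
            records.append(
                {
                    "organ": organ,
                    "group": grp.group,
                    "label": homeolog_bias(
                        grp, matrix, organ, dominance_fold, min_count
                    ),
                }
            )
    df = pd.DataFrame(records, columns=["organ", "group", "label"])
    if df.empty:
        return pd.DataFrame(), {}
    contingency = (
        df.groupby(["organ", "label"]).size().unstack(fill_value=0)
    )
    flags = {}
    for organ in matrix.organs:
        sub = df[df["organ"] == organ]
        expressed = sub[sub["label"] != "silent"]
        n = len(expressed)
        flags[organ] = False
        if n:
            for s in SUBGENOMES:
                if (expressed["label"] == f"{s}-dominant").sum() > n / 2:
                    flags[organ] = True
    return contingency, flags
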