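"""Ortholog detection and synonymous-rate (Ks) divergence dating.

Ortholog/ohnolog pairs between two gene sets are found by the reciprocal
best hit (RBH) rule on all-vs-all similarity searches, then restricted to
pairs confirmed by strict synteny: at least ``min_run`` pairs collinear on
one chromosome pair with at most ``max_gap`` intervening unpaired genes on
both genomes (per-chain inversions allowed).  Per-pair Ks is estimated by
Nei–Gojobori (1986) counting on codon alignments with the Jukes–Cantor
multiple-hit correction; the median Ks of a genome pair summarizes its
divergence, which a linear molecular clock converts to a time interval via
a user-supplied calibration range.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

log = logging.getLogger(__name__)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# reciprocal best hits


def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: highest bitscore, ties by lower evalue then
    lexicographic subject id."""
    ranked = hits.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ranked.groupby("query", sort=False)["subject"].first()


def reciprocal_best_hits(
    hits_xy: pd.DataFrame, hits_yx: pd.DataFrame
) -> pd.DataFrame:
    """RBH pairs from bidirectional hit tables (outfmt-6 columns).

    Returns a DataFrame ``gene_x, gene_y`` forming a matching: each gene
    appears in at most one pair.
    """
    if hits_xy.empty or hits_yx.empty:
        return pd.DataFrame(columns=["gene_x", "gene_y"])
    best_xy = _best_hits(hits_xy)
    best_yx = _best_hits(hits_yx)
    pairs = [
        (x, y)
        for x, y in best_xy.items()
        if best_yx.get(y) == x
    ]
    return pd.DataFrame(sorted(pairs), columns=["gene_x", "gene_y"])


# ---------------------------------------------------------------------------
# synteny confirmation


def synteny_filter(
    pairs: pd.DataFrame,
    order_x: dict[str, tuple[str, int]],
    order_y: dict[str, tuple[str, int]],
    min_run: int = 5,
    max_gap: int = 4,
) -> pd.DataFrame:
    """Flag RBH pairs confirmed by collinear chains.

    ``order_x``/``order_y`` map gene id → (chromosome, rank) where rank is
    the gene's position among all annotated genes of its chromosome.
    Anchors on one chromosome pair are sorted by x-rank; a chain is a
    maximal run of adjacent anchors in which the number of intervening
    genes is ≤ ``max_gap`` on both genomes and the y-direction is constant
    (so inverted blocks chain too).  Only chains of ≥ ``min_run`` anchors
    are confirmed.

    Returns the input with ``synteny_confirmed`` and ``chain_id`` columns.
    """
    recs = []
    for x, y in zip(pairs["gene_x"], pairs["gene_y"]):
        if x not in order_x:
            raise KeyError(f"gene {x!r} missing from x order table")
        if y not in order_y:
            raise KeyError(f"gene {y!r} missing from y order table")
        cx, rx = order_x[x]
        cy, ry = order_y[y]
        recs.append((x, y, cx, rx, cy, ry))

    confirmed: dict[tuple[str, str], str] = {}
    chain_no = 0
    by_chrom_pair: dict[tuple[str, str], list] = {}
    for rec in recs:
        by_chrom_pair.setdefault((rec[2], rec[4]), []).append(rec)

    for (cx, cy), anchors in sorted(by_chrom_pair.items()):
        anchors.sort(key=lambda r: r[3])
        chain: list = [anchors[0]]
        direction = 0
        for prev, cur in zip(anchors, anchors[1:]):
            gap_x = cur[3] - prev[3] - 1
            dy = cur[5] - prev[5]
            gap_y = abs(dy) - 1
            step_dir = 1 if dy > 0 else -1
            ok = gap_x <= max_gap and gap_y <= max_gap and dy != 0
            if ok and (direction == 0 or step_dir == direction):
                chain.append(cur)
                direction = step_dir
            else:
                if len(chain) >= min_run:
                    chain_no += 1
                    for r in chain:
                        confirmed[(r[0], r[1])] = f"chain_{chain_no}"
                chain = [cur]
                direction = 0
        if len(chain) >= min_run:
            chain_no += 1
            for r in chain:
                confirmed[(r[0], r[1])] = f"chain_{chain_no}"

    out = pairs.copy()
    keys = list(zip(out["gene_x"], out["gene_y"]))
    out["chain_id"] = [confirmed.get(k, "") for k in keys]
    out["synteny_confirmed"] = out["chain_id"] != ""
    return out


def homeolog_components(
    pairs: pd.DataFrame,
    gene_chrom_x: dict[str, str],
    gene_chrom_y: dict[str, str],
) -> list[set[str]]:
    """Connected components of the chromosome graph whose edges are shared
    ortholog anchors — recovers homeologous chromosome groups."""
    g = nx.Graph()
    for x, y in zip(pairs["gene_x"], pairs["gene_y"]):
        cx, cy = gene_chrom_x.get(x), gene_chrom_y.get(y)
        if cx is None or cy is None:
            continue
        g.add_edge(cx, cy)
    return [set(c) for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# codon alignment


def backtranslate(
    prot_aln_x: str, prot_aln_y: str, cds_x: str, cds_y: str
) -> tuple[str, str]:
    """Thread ungapped CDS onto a pairwise protein alignment.

    Each amino-acid column becomes its codon; gap columns become ``---``.
    Raises if a CDS length or translation disagrees with its protein.
    """
    if len(prot_aln_x) != len(prot_aln_y):
        raise ValueError("protein alignment rows differ in length")

    def thread(prot_aln: str, cds: str) -> str:
        prot = prot_aln.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"CDS length {len(cds)} != 3 x protein length {len(prot)}"
            )
        for i, aa in enumerate(prot):
            codon = cds[3 * i : 3 * i + 3].upper()
            expected = _CODON_TABLE.get(codon)
            if expected is None and codon in _STOPS:
                raise ValueError(f"internal stop codon {codon} at position {i}")
            if expected is not None and aa.upper() not in (expected, "X"):
                raise ValueError(
                    f"codon {codon} translates to {expected}, not {aa}, at {i}"
                )
        out, j = [], 0
        for aa in prot_aln:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * j : 3 * j + 3].upper())
                j += 1
        return "".join(out)

    return thread(prot_aln_x, cds_x), thread(prot_aln_y, cds_y)


# ---------------------------------------------------------------------------
# NG86


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of single-nucleotide changes that are
    synonymous; mutations to stop codons count as nonsynonymous."""
    aa = _CODON_TABLE[codon]
    out = []
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TABLE.get(alt) == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons,
    averaged over all minimal mutational pathways that avoid stop codons
    (all pathways if every one passes through a stop)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            aa_cur = _CODON_TABLE.get(cur)
            aa_nxt = _CODON_TABLE.get(nxt)
            if aa_cur is not None and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in results if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


@dataclass
class KsEstimate:
    """NG86 site and difference counts with Jukes–Cantor-corrected rates."""

    n_codons: int
    S: float  # synonymous sites (mean of the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    ps: float
    pn: float
    ks: float | None  # None when saturated (1 - 4/3 ps <= 0)
    ka: float | None

    @property
    def defined(self) -> bool:
        return self.ks is not None


def _jc_correct(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def ks_ng86(codon_aln_x: str, codon_aln_y: str) -> KsEstimate:
    """Nei–Gojobori (1986) Ks/Ka from a pairwise codon alignment.

    Gapped or ambiguous codon columns are skipped; columns containing a
    stop codon are rejected.  Site counts satisfy S + N = 3 × compared
    codons.  Saturation (ps ≥ 3/4) yields ``ks=None`` rather than an
    exception.
    """
    if len(codon_aln_x) != len(codon_aln_y) or len(codon_aln_x) % 3:
        raise ValueError("codon alignments must be equal length multiples of 3")
    s_sites = [0.0, 0.0]
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(codon_aln_x), 3):
        c1, c2 = codon_aln_x[i : i + 3].upper(), codon_aln_y[i : i + 3].upper()
        if "-" in c1 or "-" in c2:
            continue
        if any(b not in _BASES for b in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            raise ValueError(f"stop codon in compared column {i // 3}")
        n_codons += 1
        s_sites[0] += sum(_syn_fraction(c1))
        s_sites[1] += sum(_syn_fraction(c2))
        d_s, d_n = _pathway_diffs(c1, c2)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable codon columns")
    S = (s_sites[0] + s_sites[1]) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    return KsEstimate(
        n_codons=n_codons,
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
        ps=ps,
        pn=pn,
        ks=_jc_correct(ps),
        ka=_jc_correct(pn),
    )


# ---------------------------------------------------------------------------
# summarization and dating


def median_ks(estimates: list[KsEstimate | float | None]) -> float:
    """Median of the defined Ks values; undefined estimates are excluded
    with a logged count.  Raises when nothing is defined."""
    vals = []
    n_undef = 0
    for e in estimates:
        k = e.ks if isinstance(e, KsEstimate) else e
        if k is None or (isinstance(k, float) and math.isnan(k)):
            n_undef += 1
        else:
            vals.append(float(k))
    if n_undef:
        log.info("median_ks: %d undefined estimates excluded", n_undef)
    if not vals:
        raise ValueError("no defined Ks estimates")
    return float(np.median(vals))


@dataclass(frozen=True)
class CalibrationRange:
    """A calibration pair: its median Ks and literature time range (My)."""

    pair_id: str
    t_lo: float
    t_hi: float
    k_cal: float

    def __post_init__(self):
        if not 0 < self.t_lo <= self.t_hi:
            raise ValueError("need 0 < t_lo <= t_hi")
        if self.k_cal <= 0:
            raise ValueError("calibration Ks must be positive")


@dataclass
class DatingResult:
    pair_id: str
    median_ks: float
    t_lo: float
    t_hi: float


def calibrate_time(
    median_ks_value: float,
    calibrations: CalibrationRange | list[CalibrationRange],
    pair_id: str = "",
) -> DatingResult:
    """Linear-clock time interval for a genome pair's median Ks.

    Each calibration scales as ``[t_lo, t_hi] × K / K_cal``; with several
    calibrations the union envelope (min lower, max upper) is reported,
    mirroring the use of a consensus range from independent studies.
    """
    if median_ks_value < 0:
        raise ValueError("median Ks must be >= 0")
    if isinstance(calibrations, CalibrationRange):
        calibrations = [calibrations]
    if not calibrations:
        raise ValueError("at least one calibration required")
    lows = [c.t_lo * median_ks_value / c.k_cal for c in calibrations]
    highs = [c.t_hi * median_ks_value / c.k_cal for c in calibrations]
    return DatingResult(pair_id, median_ks_value, min(lows), max(highs))
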