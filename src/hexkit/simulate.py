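"""Seeded generator of synthetic hexaploid datasets.

Emulates the statistical structure the downstream analyses assume for a
150-chromosome hexaploid (25 homeologous groups × subgenomes {A,B} ×
haplotypes {a,b,c}): TE insertion counts with optional subgenome- or
haplotype-bias, conserved-gene presence/absence with per-subgenome loss
rates, optional A/B complementarity and cross-species shared loss,
ortholog pairs with clock-derived Ks (optionally as mutable codon
sequences), tree/divergence evidence for the haplotype-c vote, and
organ-level expression counts with chromosome-level bias.

Every generator takes an explicit seed (or a ``numpy`` Generator) and is
bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HAPLOTYPES, SUBGENOMES, ChromosomeID, GenomeStructure
from .expression import ExpressionMatrix
from .gene_loss import PresenceMatrix
from .haplotype import TriTreeEvidence
from .te_bias import TETable

# codon families whose third position is fully degenerate and whose first
# two positions admit no synonymous change — each codon contributes exactly
# one synonymous site, which makes simulated Ks analytically controllable
_FOURFOLD_PREFIXES = ("GG", "GC", "AC", "GT", "CC", "TC")
_BASES = "ACGT"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TESpec:
    """One simulated TE family: base insertion rate and optional bias."""

    family: str
    rate_per_mbp: float = 3.0
    bias_mode: str = "none"  # none | subgenome:A | subgenome:B | haplotype:a|b|c
    fold: float = 1.0

    def __post_init__(self):
        if self.rate_per_mbp < 0 or self.fold < 0:
            raise ValueError("rates and fold factors must be >= 0")
        if self.bias_mode != "none":
            kind, _, target = self.bias_mode.partition(":")
            if kind == "subgenome" and target in SUBGENOMES:
                return
            if kind == "haplotype" and target in HAPLOTYPES:
                return
            raise ValueError(f"unknown bias mode {self.bias_mode!r}")

    def matches(self, cid: ChromosomeID) -> bool:
        if self.bias_mode == "none":
            return False
        kind, _, target = self.bias_mode.partition(":")
        return (
            cid.subgenome == target if kind == "subgenome" else cid.haplotype == target
        )


@dataclass
class GeneLossSpec:
    """Duplicate-loss process on a conserved gene catalog.

    ``p_a``/``p_b`` are per-species probabilities that a gene is lost from
    the whole A resp. B subgenome; ``p_hap`` removes individual haplotype
    copies on top; ``shared_fraction`` of genes have their loss outcome
    drawn once ancestrally and propagated to all species.  With
    ``complementarity`` on, no gene is ever absent from both subgenomes
    (requires ``p_a + p_b <= 1``).
    """

    n_genes: int = 4584
    p_a: float = 0.13
    p_b: float = 0.08
    p_hap: float = 0.0025
    complementarity: bool = True
    shared_fraction: float = 0.7

    def __post_init__(self):
        for p in (self.p_a, self.p_b, self.p_hap, self.shared_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.complementarity and self.p_a + self.p_b > 1:
            raise ValueError(
                "complementarity unsatisfiable: p_a + p_b > 1"
            )


@dataclass
class ClockSpec:
    """Molecular clock: Ks accumulates at ``rate`` per My per lineage, so a
    divergence time T gives expected pairwise Ks = 2 × rate × T, perturbed
    by a multiplicative gamma factor of mean 1 and sd ``dispersion``."""

    rate: float = 0.005
    dispersion: float = 0.2

    def __post_init__(self):
        if self.rate < 0 or self.dispersion < 0:
            raise ValueError("negative clock parameters")


@dataclass
class ExpressionSpec:
    organs: tuple[str, ...] = ("brain", "eye", "gonad", "liver", "muscle")
    library_size: int = 1_000_000
    genes_per_chromosome: int = 20
    #: (organ, chromosome-name) → multiplier; unlisted cells are 1
    bias: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.library_size < 0:
            raise ValueError("library size must be >= 0")
        if any(m < 0 for m in self.bias.values()):
            raise ValueError("negative bias multipliers")


@dataclass
class SimulationConfig:
    n_groups: int = 25
    chrom_length_mean: float = 34e6
    chrom_length_sd: float = 8e6
    te_specs: list[TESpec] = field(
        default_factory=lambda: [
            TESpec("TE_Abiased", 3.0, "subgenome:A", 10.0),
            TESpec("TE_Bbiased", 3.0, "subgenome:B", 10.0),
            TESpec("TE_neutral", 3.0),
        ]
    )
    gene_loss: GeneLossSpec = field(default_factory=GeneLossSpec)
    clock: ClockSpec = field(default_factory=ClockSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    tree_noise: float = 0.05
    #: divergence times in My: haplotypes a/b/c (autopolyploid, recent) and
    #: subgenomes A/B (allotetraploid ancestor)
    t_haplotype: float = 1.0
    t_subgenome: float = 23.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# karyotype


def simulate_structure(
    config: SimulationConfig, seed=None
) -> GenomeStructure:
    """One chromosome per (group, subgenome, haplotype); lengths drawn from
    a normal distribution truncated to positive values."""
    if config.n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if config.chrom_length_mean <= 0:
        raise ValueError("non-positive length mean")
    rng = _rng(config.seed if seed is None else seed)
    entries = []
    for g in range(1, config.n_groups + 1):
        for s in SUBGENOMES:
            for h in HAPLOTYPES:
                length = 0.0
                while length <= 0:
                    length = rng.normal(
                        config.chrom_length_mean, config.chrom_length_sd
                    )
                entries.append((ChromosomeID(g, s, h), int(round(length))))
    return GenomeStructure(entries, n_groups=config.n_groups)


# ---------------------------------------------------------------------------
# TE counts


def simulate_te(
    structure: GenomeStructure, te_specs: list[TESpec], seed
) -> TETable:
    """Poisson TE counts: mean = rate × length(Mbp) × fold on chromosomes
    matching the family's bias mode, else rate × length(Mbp)."""
    rng = _rng(seed)
    counts = {}
    for spec in te_specs:
        for cid in structure:
            mean = spec.rate_per_mbp * structure.length_mbp(cid)
            if spec.matches(cid):
                mean *= spec.fold
            counts[(spec.family, cid)] = int(rng.poisson(mean))
    return TETable(counts, structure)


# ---------------------------------------------------------------------------
# gene presence/absence


def _draw_pattern(
    spec: GeneLossSpec, haplotypes: tuple[str, ...], rng: np.random.Generator
) -> dict[tuple[str, str], bool]:
    """Presence pattern over (subgenome, haplotype) copies for one gene in
    one species (or the ancestor)."""
    if spec.complementarity:
        # mutually exclusive subgenome losses preserve both marginals
        # exactly while forbidding joint loss
        u = rng.random()
        lost_sub = "A" if u < spec.p_a else ("B" if u < spec.p_a + spec.p_b else None)
        lost = {s: s == lost_sub for s in SUBGENOMES}
    else:
        lost = {s: rng.random() < p for s, p in (("A", spec.p_a), ("B", spec.p_b))}
    pattern = {}
    for s in SUBGENOMES:
        for h in haplotypes:
            present = not lost[s] and not (rng.random() < spec.p_hap)
            pattern[(s, h)] = present
    if spec.complementarity:
        for s in SUBGENOMES:
            other = "B" if s == "A" else "A"
            s_gone = not any(pattern[(s, h)] for h in haplotypes)
            other_gone = not any(pattern[(other, h)] for h in haplotypes)
            if s_gone and other_gone:
                # haplotype-level attrition completed a joint loss; restore
                # one copy on the subgenome that was not subgenome-lost
                restore = other if lost[s] else s
                pattern[(restore, haplotypes[0])] = True
                break
    return pattern


def simulate_gene_complement(
    structure: GenomeStructure,
    spec: GeneLossSpec,
    n_species: int,
    seed,
    species_names: list[str] | None = None,
) -> PresenceMatrix:
    """Presence/absence of ``n_genes`` conserved genes per
    (species, subgenome, haplotype).

    A ``shared_fraction`` of genes draw their pattern once ancestrally and
    propagate it to every species; the rest draw independently per
    species.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _rng(seed)
    species = species_names or [f"sp{i + 1}" for i in range(n_species)]
    haps = HAPLOTYPES
    genes = [f"busco{i:05d}" for i in range(spec.n_genes)]
    columns = pd.MultiIndex.from_tuples(
        [(sp, s, h) for sp in species for s in SUBGENOMES for h in haps],
        names=["species", "subgenome", "haplotype"],
    )
    data = np.ones((spec.n_genes, len(columns)), dtype=bool)
    col_pos = {c: i for i, c in enumerate(columns)}
    for gi in range(spec.n_genes):
        if rng.random() < spec.shared_fraction:
            pattern = _draw_pattern(spec, haps, rng)
            per_species = {sp: pattern for sp in species}
        else:
            per_species = {sp: _draw_pattern(spec, haps, rng) for sp in species}
        for sp, pattern in per_species.items():
            for (s, h), present in pattern.items():
                data[gi, col_pos[(sp, s, h)]] = present
    return PresenceMatrix(pd.DataFrame(data, index=genes, columns=columns))


# ---------------------------------------------------------------------------
# ortholog pairs with target Ks


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    prefixes = rng.integers(0, len(_FOURFOLD_PREFIXES), size=n_codons)
    thirds = rng.integers(0, 4, size=n_codons)
    return "".join(
        _FOURFOLD_PREFIXES[p] + _BASES[t] for p, t in zip(prefixes, thirds)
    )


def _diverge_cds(cds: str, target_ks: float, rng: np.random.Generator) -> str:
    """Mutate third positions of 4-fold codons until the pair's synonymous
    divergence matches ``target_ks`` under the Jukes–Cantor correction."""
    n_codons = len(cds) // 3
    ps = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    k = int(round(ps * n_codons))
    if k > n_codons:
        raise ValueError(f"target Ks {target_ks} saturates a {n_codons}-codon CDS")
    sites = rng.choice(n_codons, size=k, replace=False)
    seq = list(cds)
    for c in sites:
        pos = 3 * c + 2
        alternatives = [b for b in _BASES if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


def simulate_ortholog_ks(
    clock: ClockSpec,
    n_pairs: int,
    divergence_time: float,
    seed,
    n_codons: int = 300,
    with_sequences: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Ortholog pairs with true Ks = 2 × rate × T × gamma(mean 1).

    Returns (table, sequences): the table has ``gene_x, gene_y, true_ks``;
    when ``with_sequences`` the dict maps gene ids to CDS mutated at
    synonymous sites to the pair's true Ks.
    """
    if divergence_time < 0:
        raise ValueError("divergence time must be >= 0")
    rng = _rng(seed)
    base = 2.0 * clock.rate * divergence_time
    if clock.dispersion > 0 and base > 0:
        cv = clock.dispersion
        shape = 1.0 / cv**2
        factors = rng.gamma(shape, scale=1.0 / shape, size=n_pairs)
    else:
        factors = np.ones(n_pairs)
    true_ks = base * factors
    rows = []
    seqs: dict[str, str] = {}
    for i, ks in enumerate(true_ks):
        gx, gy = f"ox{i:05d}", f"oy{i:05d}"
        rows.append({"gene_x": gx, "gene_y": gy, "true_ks": float(ks)})
        if with_sequences:
            cds = _random_cds(n_codons, rng)
            seqs[gx] = cds
            seqs[gy] = _diverge_cds(cds, float(ks), rng)
    return pd.DataFrame(rows), seqs


# ---------------------------------------------------------------------------
# tree and divergence evidence for the haplotype-c vote


_OUTGROUPS_12 = ("CarAur_A", "CypCar_A", "CarAur_B", "CypCar_B", "CteIde", "OnyMac")


def _draw_candidate(true_c: str, noise: float, rng: np.random.Generator) -> str:
    if rng.random() < noise:
        return HAPLOTYPES[rng.integers(0, 3)]
    return true_c


def _support(correct: bool, rng: np.random.Generator) -> tuple[float, float]:
    """(SH-aLRT, UFB): high band for correct calls, lower for wrong ones."""
    lo, hi = (90.0, 100.0) if correct else (50.0, 90.0)
    return rng.uniform(lo, hi), rng.uniform(lo, hi)


def _triplet_newick(leaves: dict[str, str], outgroup_hap: str, label: str) -> str:
    pair = [leaves[h] for h in HAPLOTYPES if h != outgroup_hap]
    return f"(({pair[0]},{pair[1]}){label},{leaves[outgroup_hap]})"


def simulate_tree_evidence(
    n_groups: int,
    true_c: dict[int, str],
    noise: float,
    seed,
) -> dict[int, TriTreeEvidence]:
    """Per-group evidence bundles in which each line names the true c
    haplotype with probability (1 − noise) and is uniform over all three
    otherwise; supports are drawn high for correct calls (90–100) and in a
    lower band (50–90) for wrong ones."""
    if not 0 <= noise <= 1:
        raise ValueError("noise must lie in [0, 1]")
    rng = _rng(seed)
    out = {}
    for g in range(1, n_groups + 1):
        tc = true_c[g]
        leaves = {h: f"CarGib_{g}A{h}" for h in HAPLOTYPES}
        leaves_b = {h: f"CarGib_{g}B{h}" for h in HAPLOTYPES}

        cand12 = _draw_candidate(tc, noise, rng)
        sh12, ufb12 = _support(cand12 == tc, rng)
        tripA = _triplet_newick(leaves, cand12, f"{sh12:.1f}/{ufb12:.1f}")
        tripB = _triplet_newick(leaves_b, cand12, "90.0/95.0")
        tree12 = (
            f"((({tripA}96/99,CarAur_A)97/99,CypCar_A)98/99,"
            f"((({tripB}96/99,CarAur_B)97/99,CypCar_B)98/99,"
            f"(CteIde,OnyMac)99/100));"
        )

        cand4 = _draw_candidate(tc, noise, rng)
        sh4, ufb4 = _support(cand4 == tc, rng)
        tree4 = f"({_triplet_newick(leaves, cand4, f'{sh4:.1f}/{ufb4:.1f}')},CarAur_A);"

        cand_div = _draw_candidate(tc, noise, rng)
        sister = [h for h in HAPLOTYPES if h != cand_div]
        divergence = {}
        for x, y in itertools.combinations(HAPLOTYPES, 2):
            if {x, y} == set(sister):
                d = 0.8 + rng.uniform(-0.05, 0.05)
            else:
                d = 1.1 + rng.uniform(-0.05, 0.05)
            divergence[(x, y)] = round(d, 4)

        out[g] = TriTreeEvidence(
            group=g,
            tree12=tree12,
            tree4=tree4,
            triplet_leaves12=leaves,
            triplet_leaves4=leaves,
            reference12="OnyMac",
            reference4="CarAur_A",
            divergence=divergence,
        )
    return out


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression(
    structure: GenomeStructure, spec: ExpressionSpec, seed
) -> ExpressionMatrix:
    """Multinomial read counts per organ over genes, with per-gene weights
    (gamma-distributed) scaled by chromosome-level bias multipliers."""
    rng = _rng(seed)
    genes, gene_chrom = [], {}
    for cid in structure:
        for i in range(spec.genes_per_chromosome):
            gid = f"g{cid}_{i:03d}"
            genes.append(gid)
            gene_chrom[gid] = cid
    base = rng.gamma(2.0, 1.0, size=len(genes))
    counts = {}
    for organ in spec.organs:
        w = base.copy()
        for j, gid in enumerate(genes):
            mult = spec.bias.get((organ, str(gene_chrom[gid])), 1.0)
            w[j] *= mult
        if spec.library_size == 0 or w.sum() == 0:
            counts[organ] = np.zeros(len(genes), dtype=int)
        else:
            counts[organ] = rng.multinomial(spec.library_size, w / w.sum())
    df = pd.DataFrame(counts, index=genes)
    return ExpressionMatrix(df, gene_chrom)


# ---------------------------------------------------------------------------
# ortholog anchors linking the chromosomes of each homeologous group


def simulate_anchor_map(
    structure: GenomeStructure,
    seed,
    anchors_per_relation: int = 10,
    genes_per_chromosome: int = 40,
) -> dict:
    """Collinear ortholog anchors tying the six chromosomes of each group.

    Each chromosome carries ``genes_per_chromosome`` ordered genes;
    anchors link consecutive copies in the order Aa-Ab-Ac-Ba-Bb-Bc, so the
    shared-anchor graph has exactly one connected component per group.
    Returns a dict with ``anchors`` (gene_x, gene_y, relation), ``orders``
    (gene → (chrom, rank)) and ``gene_chrom``.
    """
    rng = _rng(seed)
    orders: dict[str, tuple[str, int]] = {}
    gene_chrom: dict[str, str] = {}
    gene_of: dict[tuple[str, int], str] = {}
    for cid in structure:
        for r in range(genes_per_chromosome):
            gid = f"g_{cid}_{r:03d}"
            orders[gid] = (str(cid), r)
            gene_chrom[gid] = str(cid)
            gene_of[(str(cid), r)] = gid

    copy_order = [f"{s}{h}" for s in SUBGENOMES for h in HAPLOTYPES]
    rows = []
    for g in range(1, structure.n_groups + 1):
        start = int(
            rng.integers(0, max(1, genes_per_chromosome - anchors_per_relation))
        )
        for c1, c2 in zip(copy_order, copy_order[1:]):
            ch1, ch2 = f"{g}{c1}", f"{g}{c2}"
            for i in range(anchors_per_relation):
                rows.append(
                    {
                        "gene_x": gene_of[(ch1, start + i)],
                        "gene_y": gene_of[(ch2, start + i)],
                        "relation": f"{c1}-{c2}",
                    }
                )
    return {
        "anchors": pd.DataFrame(rows),
        "orders": orders,
        "gene_chrom": gene_chrom,
    }


def simulate_hits_from_pairs(
    pairs: pd.DataFrame,
    seed,
    n_decoys: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bidirectional similarity tables in which each true pair is the
    mutual best hit, padded with lower-scoring decoy hits."""
    rng = _rng(seed)
    xs = list(pairs["gene_x"])
    ys = list(pairs["gene_y"])
    fwd, rev = [], []

    def hit(q, s, score):
        return {
            "query": q, "subject": s, "pident": 90.0, "length": 300,
            "mismatches": 30, "gapopens": 0, "qstart": 1, "qend": 300,
            "sstart": 1, "send": 300,
            "evalue": 10.0 ** (-score / 10.0), "bitscore": score,
        }

    for x, y in zip(xs, ys):
        score = float(rng.uniform(400, 600))
        fwd.append(hit(x, y, score))
        rev.append(hit(y, x, score))
        for _ in range(n_decoys):
            fwd.append(hit(x, ys[rng.integers(0, len(ys))], float(rng.uniform(50, 300))))
            rev.append(hit(y, xs[rng.integers(0, len(xs))], float(rng.uniform(50, 300))))
    return pd.DataFrame(fwd), pd.DataFrame(rev)
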