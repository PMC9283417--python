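# Methods

## The karyotype model

All statistics key into a fixed inventory: `n_groups` homeologous
chromosome groups (default 25) × subgenomes {A, B} × haplotypes {a, b, c},
one chromosome per cell, canonical names `<group><subgenome><haplotype>`.
A and B descend from the two diploid parents of an ancient
allotetraploidization; a/b/c are the three copies produced when a recent
autopolyploid addition raised the lineage to hexaploidy, with c the
phylogenetic outgroup of each triplet. Validation reports missing or
duplicated cells and non-positive lengths rather than raising, so partial
inventories can be inspected. Unplaced scaffolds and features on
unrecognized chromosome names are bucketed as `unassigned`, counted, and
excluded from per-chromosome statistics.

Coordinates follow each input format's own convention: GFF3 and
RepeatMasker-style tables are 1-based inclusive, BED is converted from
0-based half-open on read. Strand is carried but ignored — all densities
and counts here are strand-agnostic.

## Subgenome-biased index

For one TE family and triplet *i*, `D_ab = |f_a − f_b|` and
`D_ac = |f_a − f_c|` are absolute copy-count differences;
`SBI = Σ|D_ab − D_ac| / Σ(D_ab + D_ac)` summed jointly over the 2 ×
`n_groups` triplets of both subgenomes. Since `|x − y| ≤ x + y` for
non-negative x, y, the index is confined to [0, 1]; it equals 1 when, in
every triplet, the family sits entirely on one haplotype, and 0 when b
and c deviate from a symmetrically.

Choices worth stating:

- **Zero denominator → undefined**, never 0 or 1. A family with equal
  counts on all haplotypes carries no signal about ploidy mode, and
  mapping it to either end of the scale would bias the classification.
- **The formula is asymmetric in haplotype a** (D_bc never appears). It
  is implemented exactly as defined; `symmetrize=True` evaluates the
  index with each haplotype as pivot and takes the maximum, as a
  sensitivity variant only.
- **Counts, not densities**, are the default frequencies: triplet members
  are length-matched homologs, so length normalization approximately
  cancels. `use_density=True` switches to copies/Mbp.
- Classification thresholds: `sbi_threshold = 0.8` (haplotype-biased)
  and `ab_threshold = 0.5` (subgenome-biased) are defaults chosen so that
  strongly biased simulated families (fold ≥ 10–20) are recovered at
  ≥ 95% sensitivity while unbiased Poisson noise over 50 triplets
  essentially never crosses them; both are configurable.

The A/B index is the analogous statistic on per-group subgenome totals,
`Σ|g_A − g_B| / Σ(g_A + g_B)`; it is a reconstruction of a
subgenome-bias detector, not a statistic with a published definition.

## Haplotype-c vote

Three evidence lines per group: the triplet's resolution inside a
many-taxon chromosome tree, a 4-taxon tree (triplet + reference genome),
and the 3×3 divergence matrix. Tree evidence is extracted by rooting at
the reference leaf and finding the unique haplotype pair that forms a
clade excluding the third and the reference; an unresolved triplet
(polytomy, or interleaved with other taxa) abstains. Divergence evidence
takes the complement of the minimally diverged pair; minima tied within
ε = 0.02 percentage points abstain.

The cascade: (1) two or more agreeing conclusive lines win (`majority`);
(2) otherwise the tree with strictly higher ultrafast-bootstrap support
wins (`best_support`) — a lone conclusive line, or one tree against the
divergence line, also resolves here, since trees are privileged over the
divergence heuristic; (3) an exact support tie, including 100/100, goes
to the many-taxon tree (`twelve_taxon_override`). All lines abstaining
leaves the group unassigned for manual review. Node labels of the form
`SH-aLRT/UFB` are parsed; UFB is the comparison scalar, SH-aLRT is
metadata only, keeping step (2) totally ordered. After c is fixed, a/b
labels for the remaining two chromosomes are arbitrary and assigned
lexicographically for determinism.

Pairwise divergence of aligned haplotypes is
`100 × (substituted columns + indel events) / aligned columns`, where a
maximal run of gap columns in one sequence is one event — event counting
keeps a single long indel from dominating the percentage (per-column
counting is available by flag). Columns with N in either sequence, or
gaps in both, are excluded from numerator and denominator.

## Orthology and Ks

RBH: a pair (x, y) forms when each is the other's top-bitscore hit, ties
broken by lower e-value then lexicographic subject id, making the
matching deterministic. Synteny confirmation sorts each chromosome
pair's anchors by query rank and chains maximal runs in which both the
query-side and subject-side gaps are ≤ `max_gap` = 4 intervening genes
and the subject direction is constant within the chain (so inverted
blocks chain, but a direction flip starts a new chain); chains with
≥ `min_run` = 5 anchors are confirmed. Applying the gap bound on *both*
genomes is the strictest defensible reading of "largest gap fewer than
five genes"; a flag could relax it to one side, which we deliberately do
not default to.

Ks uses Nei–Gojobori (1986) counting: per-codon synonymous-site
fractions averaged over the two sequences (S + N = 3 × compared codons
always), differences averaged over all minimal mutational pathways,
excluding pathways through stop codons (falling back to all pathways in
the rare case every pathway hits a stop); mutations *to* stop codons
count as nonsynonymous in site counting. Jukes–Cantor correction
`Ks = −¾ ln(1 − 4/3 ps)`; saturation (`ps ≥ ¾`) yields an undefined
flag, not an exception, and undefined estimates are excluded from the
median with a logged count. A maximum-likelihood codon-model estimator
would be the other standard choice; for the small divergences this
package targets (Ks < 0.4) counting and ML estimates agree closely, and
the counting estimator is dependency-free and exactly testable against
pathway enumeration.

Dating is a linear clock through a user-supplied calibration:
`[T_lo, T_hi] × K / K_cal`. Multiple calibrations report the union
envelope (min lower, max upper), mirroring the use of a consensus range
from independent studies. Calibration values are required inputs — the
package ships none.

## Duplicate-loss accounting

Presence is tracked per (species, subgenome, haplotype) copy over a
conserved catalog (default size 4584, the actinopterygian BUSCO set).
"Missing from subgenome S" requires absence from *all* haplotype copies
of S — the only definition under which cross-species overlap counts stay
well defined when comparator genomes are collapsed to one copy per
subgenome. BUSCO `Fragmented` counts as present by default (flag to
invert). Cross-species overlap counts report genes missing in a unit of
all species and, for subgenome-specific loss, additionally present in
the complementary subgenome of all species, plus full
inclusion–exclusion cells. Deletion candidates require absence in
exactly one haplotype by both evidence lines (presence matrix and an
independent annotation screen) and haploid coverage of every remaining
allele within [0.5, 1.5] × the median — alleles above the band indicate
assembly collapse, not deletion. The band is a stated default with no
published value behind it.

## Expression bias

Chromosome-level totals are raw read counts and counts-per-million (the
chromosome-scale unit plotted in such studies); per-gene TPM is out of
scope because the generator does not model transcript lengths. A
homeolog group is `silent` below a 10-read floor, `A/B-dominant` when
one subgenome's summed counts are ≥ 2× the other's,
`haplotype-dominant:<h>` when one haplotype inside the winning subgenome
is itself ≥ 2× the rest, else `balanced`. The fold and floor are
defaults for the undefined notion of "preferential" expression; labels
are invariant under uniform scaling of an organ's counts. A per-organ
global dominance flag is raised only when one subgenome dominates more
than half of expressed groups.

## Synthetic data generator

The generator emulates the statistical structure each stage assumes, at
the configured study conditions:

- **Karyotype**: lengths ~ Normal(34 Mb, 8 Mb) truncated positive
  (≈ 5.1 Gb / 150 chromosomes).
- **TE counts**: Poisson with mean rate × length(Mbp), multiplied by a
  fold factor on chromosomes matching the bias mode. Poisson dispersion
  is an assumption — real TE counts may be overdispersed.
- **Gene loss**: defaults p_A = 0.13, p_B = 0.08 (the observed per-
  subgenome loss range), per-copy haplotype attrition p_hap = 0.0025
  (matching the observed 0.2–0.3% haplotype differences), ancestral
  shared-loss fraction 0.7. With complementarity on, subgenome losses
  are drawn as mutually exclusive events (P(A-only) = p_A,
  P(B-only) = p_B), which preserves both marginal rates exactly while
  forbidding joint loss; p_A + p_B > 1 is rejected as unsatisfiable. A
  guard restores one copy in the vanishingly rare case haplotype-level
  attrition would complete a joint loss, so complementarity-on implies
  combined-missing = 0 deterministically.
- **Ks pairs**: true Ks = 2 r T (r = 0.005/My, T = 23 My for the A–B
  split, 1 My for haplotypes) times a gamma multiplier of mean 1 and sd
  `dispersion` (0.2) — multiplicative gamma keeps Ks ≥ 0 with median
  near 2rT. Emitted sequences are built from codon families whose third
  position is fully fourfold-degenerate and whose other positions admit
  no synonymous change, so each codon contributes exactly one synonymous
  site; mutating k distinct third positions then gives ps = k/L exactly,
  making the NG86 estimate analytically predictable.
- **Tree evidence**: each line names the true c with probability
  1 − noise and is uniform over all three haplotypes otherwise; supports
  are drawn U(90, 100) for correct calls and U(50, 90) for wrong ones —
  a generative convention chosen so the tie-break cascade is reachable
  in tests, not an empirical model of bootstrap behavior.
- **Expression**: multinomial counts per organ over genes with
  gamma-distributed gene weights and chromosome-level multipliers.
- **Anchors**: each group's six chromosomes are tied by collinear anchor
  runs between consecutive copies, so the shared-anchor graph has
  exactly one component per group.

Everything is driven by `numpy` Generators seeded explicitly;
identical (config, seed) reproduces outputs bit-for-bit.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sequence evolution with indels or selection,
overdispersed TE insertion, assembly and annotation artifacts,
mapping-ambiguity in expression counts, and lineage-specific rate
variation beyond a scalar dispersion.

## Problem sizes and numerical choices

The test suite and acceptance checks run at desk scale: exhaustive SBI
enumeration on a two-triplet genome (4096 configurations), 1000-table
oracle equivalence, ≤ 20-gene synteny toys against a brute-force chain
enumerator, 200-pair Ks recovery at targets 0.05–0.3 (within 10%),
100-seed vote-recovery experiments, and 200-seed loss-ratio
distributions at the full catalog size of 4584 genes. The full synthetic
pipeline (150 chromosomes, default specs) completes in seconds.

One documented property is knowingly out of statistical reach: requiring
the simulated A/B loss-ratio estimate inside [1.8, 2.2] in ≥ 95% of
seeds at p_A = 2 p_B = 0.16 and n = 4584. The ratio of two binomial
counts at these rates has sd ≈ 0.126, so the band captures only ~88% of
draws (~95% after one-decimal rounding). The corresponding acceptance
test is left failing rather than widening the band or enlarging the
catalog; the unit suite asserts the properties that do hold
(unbiasedness, binomial-consistent spread).

Tie-breaks and degenerate inputs are handled deterministically
throughout: divergence ties abstain at ε = 0.02; RBH ties fall through
bitscore → e-value → lexicographic id; all-zero TE families, saturated
Ks pairs and empty alignments yield flagged undefined values or typed
errors, never silent zeros.

## Limitations

The package consumes trees, alignments and similarity hits — it infers
none of them. The SBI's pivot asymmetry is inherited from its
definition; the symmetrized variant is provided but non-default.
Divergence-based outgroup calling assumes approximately clock-like
haplotype evolution. The A/B bias index and several thresholds
(dominance fold, coverage band) are reasoned defaults without published
counterparts, and conclusions drawn from them should be
sensitivity-checked with the provided flags.
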