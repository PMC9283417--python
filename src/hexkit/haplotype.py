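"""Assignment of the autopolyploid outgroup haplotype (c) per chromosome group.

Among the three haplotypes of each homeologous group, one (labelled c) is
the phylogenetic outgroup — the copy added by the recent autopolyploidization.
Three independent evidence lines identify it: a many-taxon chromosome tree,
a 4-taxon tree (the triplet plus one reference genome), and pairwise
haplotype divergences.  A chromosome is assigned to haplotype c when at
least two of the three analyses agree; disagreements fall through a
deterministic tie-break cascade (best tree support, then the many-taxon
tree).  After c is fixed, the a/b labels of the remaining two chromosomes
are arbitrary and set lexicographically.
"""

from __future__ import annotations

import io as _io
import itertools
import logging
from dataclasses import dataclass, field

import dendropy

log = logging.getLogger(__name__)

INCONCLUSIVE = None

#: tolerance (percentage points) for declaring a divergence tie
DIVERGENCE_TIE_EPS = 0.02


# ---------------------------------------------------------------------------
# sequence divergence


def pairwise_divergence(
    seq1: str, seq2: str, *, indels_per_base: bool = False
) -> float:
    """Percent difference between two aligned sequences.

    Counts substituted columns plus indel events over aligned columns:
    a run of consecutive gap columns in one sequence is one indel event
    (``indels_per_base=True`` counts every gap column instead).  Columns
    containing N in either sequence are excluded from numerator and
    denominator, as are columns gapped in both sequences.
    """
    if len(seq1) != len(seq2):
        raise ValueError(f"unequal alignment lengths: {len(seq1)} vs {len(seq2)}")
    s1, s2 = seq1.upper(), seq2.upper()
    cols = [
        (a, b)
        for a, b in zip(s1, s2)
        if "N" not in (a, b) and not (a == "-" and b == "-")
    ]
    if not cols:
        raise ValueError("empty alignment after exclusions")
    subs = sum(1 for a, b in cols if a != b and "-" not in (a, b))
    events = 0
    for which in (0, 1):
        in_gap = False
        for col in cols:
            is_gap = col[which] == "-"
            if is_gap and not in_gap:
                events += 1
            in_gap = is_gap
    if indels_per_base:
        events = sum(1 for a, b in cols if "-" in (a, b))
    return 100.0 * (subs + events) / len(cols)


# ---------------------------------------------------------------------------
# tree evidence


def _parse_support(label: str | None) -> tuple[float | None, float | None]:
    """Parse a node label of the form 'SH-aLRT/UFB' or a bare support.

    Returns (ufb, sh_alrt); the comparison scalar for the cascade is UFB.
    """
    if not label:
        return None, None
    label = label.strip()
    if "/" in label:
        sh, _, ufb = label.partition("/")
        try:
            return float(ufb), float(sh)
        except ValueError:
            return None, None
    try:
        return float(label), None
    except ValueError:
        return None, None


def outgroup_from_tree(
    newick: str | dendropy.Tree,
    triplet_leaves: dict[str, str],
    reference_leaf: str,
) -> tuple[str | None, float | None]:
    """Find which haplotype of a triplet is the outgroup in a rooted view.

    Parameters
    ----------
    newick
        The tree (Newick string or dendropy Tree); internal node labels are
        read as support values ("UFB" or "SH-aLRT/UFB").
    triplet_leaves
        Mapping haplotype label → leaf name, e.g. ``{"a": "5Aa", ...}``.
    reference_leaf
        Leaf used to root the tree (an outgroup species).

    Returns
    -------
    (haplotype, support)
        The triplet member not in the cherry formed by the other two, with
        the cherry's support; ``(None, None)`` when the triplet is
        unresolved (polytomy) or not cleanly split.
    """
    if isinstance(newick, dendropy.Tree):
        tree = newick.clone(depth=1)
    else:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    by_name = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter() if lf.taxon is not None
    }
    wanted = set(triplet_leaves.values()) | {reference_leaf}
    missing = wanted - set(by_name)
    if missing:
        raise KeyError(f"leaves missing from tree: {sorted(missing)}")

    ref = by_name[reference_leaf]
    tree.reroot_at_edge(ref.edge, update_bipartitions=False)
    by_name = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter() if lf.taxon is not None
    }

    def ancestors(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    haps = sorted(triplet_leaves)
    for third in haps:
        pair = [h for h in haps if h != third]
        n1, n2 = (by_name[triplet_leaves[h]] for h in pair)
        anc1 = ancestors(n1)
        anc2 = set(id(n) for n in ancestors(n2))
        mrca = next((n for n in anc1 if id(n) in anc2), None)
        if mrca is None or mrca is tree.seed_node:
            continue
        clade_leaves = {
            lf.taxon.label for lf in mrca.leaf_iter() if lf.taxon is not None
        }
        if triplet_leaves[third] in clade_leaves or reference_leaf in clade_leaves:
            continue
        ufb, _sh = _parse_support(mrca.label)
        return third, ufb
    return INCONCLUSIVE, None


def outgroup_from_divergence(
    divergence: dict[tuple[str, str], float],
    eps: float = DIVERGENCE_TIE_EPS,
) -> str | None:
    """Outgroup as the complement of the minimally diverged pair.

    ``divergence`` maps unordered haplotype pairs to percent difference.
    Returns ``None`` (inconclusive) when the minimum is not unique within
    ``eps`` percentage points.
    """
    norm: dict[frozenset, float] = {}
    for (x, y), d in divergence.items():
        if d < 0:
            raise ValueError("negative divergence")
        norm[frozenset((x, y))] = float(d)
    haps = sorted({h for pair in norm for h in pair})
    if len(haps) != 3 or len(norm) != 3:
        raise ValueError("divergence must cover the three haplotype pairs")
    items = sorted(norm.items(), key=lambda kv: kv[1])
    if items[1][1] - items[0][1] <= eps:
        return INCONCLUSIVE
    (pair, _d) = items[0]
    (third,) = set(haps) - pair
    return third


# ---------------------------------------------------------------------------
# the vote cascade


@dataclass
class TriTreeEvidence:
    """Evidence bundle for one homeologous group's haplotype triplet."""

    group: int
    tree12: str | None  # Newick over >= 12 taxa
    tree4: str | None  # Newick over the triplet + one reference
    triplet_leaves12: dict[str, str] = field(default_factory=dict)
    triplet_leaves4: dict[str, str] = field(default_factory=dict)
    reference12: str = ""
    reference4: str = ""
    divergence: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class Vote:
    source: str  # tree12 | tree4 | divergence
    candidate: str | None
    support: float | None = None


@dataclass
class Assignment:
    group: int
    chosen_c: str | None
    rule_used: str  # majority | best_support | twelve_taxon_override | unassigned
    votes: list[Vote] = field(default_factory=list)


def assign_haplotype_c(evidence: TriTreeEvidence) -> Assignment:
    """Choose haplotype c for one group from up to three evidence lines.

    Cascade: (1) if at least two conclusive lines agree, their candidate
    wins (rule ``majority``); (2) otherwise the tree candidate with strictly
    higher support wins (``best_support``; a lone conclusive line also
    resolves here); (3) a support tie — including 100/100 — goes to the
    many-taxon tree (``twelve_taxon_override``).  Inconclusive lines
    abstain; if every line abstains the group is left unassigned.
    """
    votes: list[Vote] = []
    if evidence.tree12 is not None:
        cand, sup = outgroup_from_tree(
            evidence.tree12, evidence.triplet_leaves12, evidence.reference12
        )
        votes.append(Vote("tree12", cand, sup))
    if evidence.tree4 is not None:
        cand, sup = outgroup_from_tree(
            evidence.tree4, evidence.triplet_leaves4, evidence.reference4
        )
        votes.append(Vote("tree4", cand, sup))
    if evidence.divergence:
        votes.append(Vote("divergence", outgroup_from_divergence(evidence.divergence)))

    conclusive = [v for v in votes if v.candidate is not None]
    if not conclusive:
        log.warning("group %d: all evidence inconclusive", evidence.group)
        return Assignment(evidence.group, None, "unassigned", votes)

    tally: dict[str, int] = {}
    for v in conclusive:
        tally[v.candidate] = tally.get(v.candidate, 0) + 1
    best_hap, best_n = max(tally.items(), key=lambda kv: kv[1])
    if best_n >= 2:
        return Assignment(evidence.group, best_hap, "majority", votes)

    tree_votes = [
        v for v in conclusive if v.source in ("tree12", "tree4")
    ]
    if not tree_votes:
        # only the divergence line spoke; it trivially has the best support
        return Assignment(evidence.group, conclusive[0].candidate, "best_support", votes)
    if len(tree_votes) == 1:
        # one tree vs (possibly) divergence: the tree wins in the ladder
        return Assignment(evidence.group, tree_votes[0].candidate, "best_support", votes)

    t12 = next(v for v in tree_votes if v.source == "tree12")
    t4 = next(v for v in tree_votes if v.source == "tree4")
    s12 = t12.support if t12.support is not None else -1.0
    s4 = t4.support if t4.support is not None else -1.0
    if s12 != s4:
        winner = t12 if s12 > s4 else t4
        return Assignment(evidence.group, winner.candidate, "best_support", votes)
    return Assignment(evidence.group, t12.candidate, "twelve_taxon_override", votes)


def relabel_after_c(
    chromosome_names: list[str], chosen_c: str
) -> dict[str, str]:
    """Deterministic a/b labels for the two non-c chromosomes of a triplet
    (lexicographic by chromosome name); c keeps its assignment."""
    others = sorted(n for n in chromosome_names if not n.endswith(chosen_c))
    mapping = {}
    for name, hap in zip(others, ("a", "b")):
        mapping[name] = hap
    for name in chromosome_names:
        if name not in mapping:
            mapping[name] = "c"
    return mapping


def assign_all(evidence_by_group: dict[int, TriTreeEvidence]) -> list[Assignment]:
    return [
        assign_haplotype_c(evidence_by_group[g]) for g in sorted(evidence_by_group)
    ]
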