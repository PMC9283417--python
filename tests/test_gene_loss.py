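import numpy as np
import pandas as pd
import pytest

from hexkit.gene_loss import (
    HAPLOTYPE_PARTITION,
    SUBGENOME_PARTITION,
    PresenceMatrix,
    complementarity,
    deletion_candidates,
    loss_ratio,
    missing_sets,
    overlap_counts,
)
from hexkit.simulate import GeneLossSpec, SimulationConfig, simulate_gene_complement, simulate_structure


def matrix_from(rows, species=("sp1",), haps=("a", "b", "c")):
    """rows: {gene: set of present (species, subgenome, haplotype)}."""
    columns = pd.MultiIndex.from_tuples(
        [(sp, s, h) for sp in species for s in "AB" for h in haps],
        names=["species", "subgenome", "haplotype"],
    )
    data = pd.DataFrame(
        [[col in present for col in columns] for present in rows.values()],
        index=list(rows),
        columns=columns,
    )
    return PresenceMatrix(data)


ALL = {(sp, s, h) for sp in ("sp1",) for s in "AB" for h in "abc"}


class TestMissingSets:
    def test_subgenome_aggregation(self):
        # absent from all three A copies, present in B
        m = matrix_from({"g1": ALL - {("sp1", "A", h) for h in "abc"}, "g2": ALL})
        by_sub = missing_sets(m, SUBGENOME_PARTITION)
        assert by_sub[("sp1", "A")] == {"g1"}
        assert by_sub[("sp1", "B")] == set()

    def test_partial_subgenome_absence_not_aggregated(self):
        m = matrix_from({"g1": ALL - {("sp1", "A", "a")}})
        by_sub = missing_sets(m, SUBGENOME_PARTITION)
        assert by_sub[("sp1", "A")] == set()

    def test_haplotype_partition(self):
        m = matrix_from({"g1": ALL - {("sp1", "A", "c"), ("sp1", "B", "c")}})
        by_hap = missing_sets(m, HAPLOTYPE_PARTITION)
        assert by_hap[("sp1", "c")] == {"g1"}
        assert by_hap[("sp1", "a")] == set()

    def test_all_present_all_empty(self):
        m = matrix_from({"g1": ALL, "g2": ALL})
        assert all(not s for s in missing_sets(m, SUBGENOME_PARTITION).values())

    def test_unknown_partition_rejected(self):
        m = matrix_from({"g1": ALL})
        with pytest.raises(ValueError):
            missing_sets(m, "by_magic")

    def test_simulated_per_copy_fraction(self):
        """Realized subgenome-A loss matches the configured rate within a
        binomial confidence band."""
        spec = GeneLossSpec(p_a=0.13, p_b=0.08, p_hap=0.0, shared_fraction=0.0)
        st = simulate_structure(SimulationConfig(n_groups=2), seed=0)
        m = simulate_gene_complement(st, spec, 1, seed=42)
        by_sub = missing_sets(m, SUBGENOME_PARTITION)
        frac = len(by_sub[("sp1", "A")]) / m.n_genes
        sd = np.sqrt(0.13 * 0.87 / m.n_genes)
        assert abs(frac - 0.13) < 3 * sd


class TestLossRatio:
    def test_printed_ratio_two(self):
        r = loss_ratio(266, 133)
        assert r.rounded == 2.0

    def test_printed_ratio_one_point_nine(self):
        r = loss_ratio(444, 235)
        assert r.rounded == 1.9
        assert r.ratio == pytest.approx(1.889, abs=1e-3)

    def test_equal_counts(self):
        assert loss_ratio(100, 100).rounded == 1.0

    def test_zero_denominator_undefined(self):
        assert loss_ratio(10, 0).ratio is None


class TestOverlapCounts:
    def test_disjoint_sets(self):
        missing = {
            ("sp1", "A"): {"g1"}, ("sp2", "A"): {"g2"},
            ("sp1", "B"): set(), ("sp2", "B"): set(),
        }
        out = overlap_counts(missing, ["sp1", "sp2"], "A", complement_unit="B")
        assert out["shared_specific"] == 0

    def test_identical_sets(self):
        shared = {f"g{i}" for i in range(7)}
        missing = {
            ("sp1", "A"): shared, ("sp2", "A"): shared,
            ("sp1", "B"): set(), ("sp2", "B"): set(),
        }
        out = overlap_counts(missing, ["sp1", "sp2"], "A", complement_unit="B")
        assert out["shared_specific"] == 7
        assert out["sp1&sp2"] == 7

    def test_complement_filter(self):
        # g1 shared-missing in A but ALSO missing in sp2's B -> not specific
        missing = {
            ("sp1", "A"): {"g1", "g2"}, ("sp2", "A"): {"g1", "g2"},
            ("sp1", "B"): set(), ("sp2", "B"): {"g1"},
        }
        out = overlap_counts(missing, ["sp1", "sp2"], "A", complement_unit="B")
        assert out["shared_specific"] == 1

    def test_simulated_shared_fraction(self):
        """With half of losses ancestral, the cross-species shared count
        tracks the configured fraction."""
        spec = GeneLossSpec(
            p_a=0.13, p_b=0.08, p_hap=0.0, shared_fraction=0.5,
            complementarity=True,
        )
        st = simulate_structure(SimulationConfig(n_groups=2), seed=0)
        m = simulate_gene_complement(st, spec, 2, seed=7)
        by_sub = missing_sets(m, SUBGENOME_PARTITION)
        shared = overlap_counts(by_sub, ["sp1", "sp2"], "A")["sp1&sp2"]
        # ancestral A losses: 0.5 x 0.13 x n; independent co-loss adds
        # 0.5 x 0.13^2 x n
        expect = (0.5 * 0.13 + 0.5 * 0.13**2) * m.n_genes
        assert abs(shared - expect) < 3 * np.sqrt(expect)


class TestComplementarity:
    def test_enforced_zero_combined_missing(self):
        spec = GeneLossSpec(p_a=0.13, p_b=0.08, complementarity=True)
        st = simulate_structure(SimulationConfig(n_groups=2), seed=0)
        m = simulate_gene_complement(st, spec, 2, seed=11)
        for sp in m.species:
            assert complementarity(m, sp).combined_missing == set()

    def test_gene_missing_everywhere_counted(self):
        m = matrix_from({"g1": set(), "g2": ALL})
        rep = complementarity(m, "sp1")
        assert rep.combined_missing == {"g1"}
        assert rep.combined_missing_pct == pytest.approx(50.0)

    def test_independent_losses_product(self):
        """Without complementarity, combined missing ~ pA x pB."""
        spec = GeneLossSpec(
            p_a=0.13, p_b=0.08, p_hap=0.0, complementarity=False,
            shared_fraction=0.0,
        )
        st = simulate_structure(SimulationConfig(n_groups=2), seed=0)
        m = simulate_gene_complement(st, spec, 1, seed=23)
        rep = complementarity(m, "sp1")
        expect = 0.13 * 0.08 * m.n_genes
        assert abs(len(rep.combined_missing) - expect) < 3 * np.sqrt(expect) + 1

    def test_unsatisfiable_config_rejected(self):
        with pytest.raises(ValueError):
            GeneLossSpec(p_a=0.7, p_b=0.5, complementarity=True)


class TestDeletionCandidates:
    def cov(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "mean_haploid_cov"])

    def base_matrix(self):
        return matrix_from(
            {
                "g1": ALL - {("sp1", "A", "c"), ("sp1", "B", "c")},  # c-absent
                "g2": ALL,
                "g3": ALL
                - {("sp1", "A", "c"), ("sp1", "B", "c"),
                   ("sp1", "A", "b"), ("sp1", "B", "b")},  # two haps absent
            }
        )

    def test_single_copy_coverage_is_candidate(self):
        cov = self.cov(
            [("g1", "1Aa", 1.0), ("g1", "1Ab", 1.1), ("g2", "1Aa", 1.0),
             ("g2", "1Ab", 0.9), ("g2", "1Ba", 1.0)]
        )
        out = deletion_candidates(
            self.base_matrix(), "sp1", {"c": {"g1"}}, cov
        )
        assert out["gene"].tolist() == ["g1"]
        assert out["missing_haplotype"].tolist() == ["c"]

    def test_collapsed_assembly_rejected(self):
        cov = self.cov([("g1", "1Aa", 2.4), ("g1", "1Ab", 1.0), ("g2", "1Aa", 1.0),
                        ("g2", "1Ab", 1.0), ("g2", "1Ba", 1.0)])
        out = deletion_candidates(
            self.base_matrix(), "sp1", {"c": {"g1"}}, cov
        )
        assert out.empty

    def test_two_haplotypes_absent_excluded(self):
        cov = self.cov([("g3", "1Aa", 1.0), ("g2", "1Aa", 1.0)])
        out = deletion_candidates(
            self.base_matrix(), "sp1", {"c": {"g3"}, "b": {"g3"}}, cov
        )
        assert out.empty

    def test_annotation_disagreement_excluded(self):
        # presence matrix says c-absent but annotation does not confirm
        cov = self.cov([("g1", "1Aa", 1.0), ("g2", "1Aa", 1.0)])
        out = deletion_candidates(self.base_matrix(), "sp1", {"c": set()}, cov)
        assert out.empty


class TestParameterRecovery:
    def test_loss_ratio_recovery_unbiased(self):
        """With pA = 2 pB the estimated A/B loss ratio is an unbiased
        estimator of 2: the mean over seeds sits well inside [1.9, 2.1]
        and the spread matches the binomial sampling expectation."""
        spec = GeneLossSpec(
            n_genes=4584, p_a=0.16, p_b=0.08, p_hap=0.0, shared_fraction=0.0
        )
        st = simulate_structure(SimulationConfig(n_groups=1), seed=0)
        ratios = []
        for seed in range(50):
            m = simulate_gene_complement(st, spec, 1, seed=seed)
            by_sub = missing_sets(m, SUBGENOME_PARTITION)
            r = loss_ratio(
                len(by_sub[("sp1", "A")]), len(by_sub[("sp1", "B")])
            )
            ratios.append(r.ratio)
        assert 1.9 <= np.mean(ratios) <= 2.1
        # ratio-of-binomials sd at these rates is ~0.12
        assert np.std(ratios) < 0.2
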