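import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hexkit.orthology import (
    CalibrationRange,
    backtranslate,
    calibrate_time,
    homeolog_components,
    ks_ng86,
    median_ks,
    reciprocal_best_hits,
    synteny_filter,
)
from hexkit.simulate import ClockSpec, simulate_ortholog_ks


def hits_frame(rows):
    """rows: (query, subject, evalue, bitscore)."""
    return pd.DataFrame(
        [
            {
                "query": q, "subject": s, "pident": 90.0, "length": 100,
                "mismatches": 10, "gapopens": 0, "qstart": 1, "qend": 100,
                "sstart": 1, "send": 100, "evalue": e, "bitscore": b,
            }
            for q, s, e, b in rows
        ]
    )


class TestRBH:
    def test_mutual_best_pairs(self):
        fwd = hits_frame([("x1", "y1", 1e-50, 500), ("x1", "y2", 1e-10, 100)])
        rev = hits_frame([("y1", "x1", 1e-50, 500), ("y2", "x1", 1e-10, 100)])
        pairs = reciprocal_best_hits(fwd, rev)
        assert pairs.values.tolist() == [["x1", "y1"]]

    def test_non_reciprocal_excluded(self):
        fwd = hits_frame([("x1", "y1", 1e-50, 500)])
        rev = hits_frame([("y1", "x2", 1e-60, 600), ("y1", "x1", 1e-50, 500)])
        assert reciprocal_best_hits(fwd, rev).empty

    def test_tie_break_by_evalue(self):
        fwd = hits_frame([("x1", "y2", 1e-40, 500), ("x1", "y1", 1e-50, 500)])
        rev = hits_frame([("y1", "x1", 1e-50, 500)])
        pairs = reciprocal_best_hits(fwd, rev)
        assert pairs.values.tolist() == [["x1", "y1"]]

    def test_empty_tables(self):
        assert reciprocal_best_hits(hits_frame([]), hits_frame([])).empty

    def test_output_is_matching(self):
        rng = np.random.default_rng(5)
        xs = [f"x{i}" for i in range(20)]
        ys = [f"y{i}" for i in range(20)]
        fwd = hits_frame(
            [
                (x, ys[rng.integers(0, 20)], 1e-20, float(rng.uniform(100, 500)))
                for x in xs
                for _ in range(3)
            ]
        )
        rev = hits_frame(
            [
                (y, xs[rng.integers(0, 20)], 1e-20, float(rng.uniform(100, 500)))
                for y in ys
                for _ in range(3)
            ]
        )
        pairs = reciprocal_best_hits(fwd, rev)
        assert pairs["gene_x"].is_unique and pairs["gene_y"].is_unique


def make_orders(genes_by_chrom):
    return {
        g: (chrom, rank)
        for chrom, genes in genes_by_chrom.items()
        for rank, g in enumerate(genes)
    }


def simple_chain_oracle(anchors, min_run, max_gap):
    """Split the x-sorted anchor list at every invalid or direction-flip
    step; runs of length >= min_run are confirmed."""
    anchors = sorted(anchors, key=lambda a: a[1])
    runs, current, direction = [], [], 0
    for prev, cur in zip([None] + anchors, anchors):
        if prev is None:
            current = [cur]
            direction = 0
            continue
        dy = cur[2] - prev[2]
        ok = (
            cur[1] - prev[1] - 1 <= max_gap
            and abs(dy) - 1 <= max_gap
            and dy != 0
        )
        step_dir = 1 if dy > 0 else -1
        if ok and (direction == 0 or step_dir == direction):
            current.append(cur)
            direction = step_dir
        else:
            runs.append(current)
            current = [cur]
            direction = 0
    runs.append(current)
    confirmed = set()
    for run in runs:
        if len(run) >= min_run:
            confirmed.update(a[0] for a in run)
    return confirmed


class TestSyntenyFilter:
    def run_filter(self, positions, min_run=5, max_gap=4, n_fill=30):
        """positions: list of (x_rank, y_rank) anchor placements on one
        chromosome pair; filler genes occupy the remaining ranks."""
        xs = [f"x{i}" for i in range(n_fill)]
        ys = [f"y{i}" for i in range(n_fill)]
        order_x = make_orders({"cx": xs})
        order_y = make_orders({"cy": ys})
        pairs = pd.DataFrame(
            [(xs[rx], ys[ry]) for rx, ry in positions],
            columns=["gene_x", "gene_y"],
        )
        return synteny_filter(pairs, order_x, order_y, min_run, max_gap)

    def test_five_adjacent_confirmed(self):
        out = self.run_filter([(i, i) for i in range(5)])
        assert out["synteny_confirmed"].all()

    def test_four_adjacent_not_confirmed(self):
        out = self.run_filter([(i, i) for i in range(4)])
        assert not out["synteny_confirmed"].any()

    def test_gap_of_five_splits_gap_of_four_chains(self):
        # anchors at x ranks 0,1,2 then 8,9,10: internal gap of 5 genes
        split = self.run_filter([(i, i) for i in [0, 1, 2, 8, 9, 10]])
        assert not split["synteny_confirmed"].any()
        # gap of 4 genes (ranks 0,1,2,7,8,9) chains all six
        joined = self.run_filter([(i, i) for i in [0, 1, 2, 7, 8, 9]])
        assert joined["synteny_confirmed"].all()

    def test_inverted_block_chains(self):
        out = self.run_filter([(i, 10 - i) for i in range(6)])
        assert out["synteny_confirmed"].all()

    def test_missing_gene_rejected(self):
        pairs = pd.DataFrame([("ghost", "y0")], columns=["gene_x", "gene_y"])
        with pytest.raises(KeyError):
            synteny_filter(pairs, {}, {"y0": ("cy", 0)})

    def test_confirmed_subset_of_input(self):
        out = self.run_filter([(2 * i, i) for i in range(8)])
        assert set(out[out["synteny_confirmed"]].index) <= set(out.index)

    def test_matches_oracle_on_random_toys(self, rng):
        for trial in range(300):
            n = int(rng.integers(2, 12))
            xr = rng.choice(20, size=n, replace=False)
            yr = rng.choice(20, size=n, replace=False)
            min_run = int(rng.integers(2, 5))
            max_gap = int(rng.integers(0, 5))
            anchors = [((int(a), int(b)), int(a), int(b)) for a, b in zip(xr, yr)]
            expected = simple_chain_oracle(anchors, min_run, max_gap)
            out = self.run_filter(
                [(a, b) for (_p, a, b) in anchors], min_run, max_gap, n_fill=20
            )
            got = {
                (int(r.gene_x[1:]), int(r.gene_y[1:]))
                for r in out.itertuples(index=False)
                if r.synteny_confirmed
            }
            assert got == expected, f"trial {trial}"


class TestBacktranslate:
    def test_simple(self):
        cx, cy = backtranslate("MK", "MK", "ATGAAA", "ATGAAG")
        assert (cx, cy) == ("ATGAAA", "ATGAAG")

    def test_gap_propagation(self):
        cx, cy = backtranslate("M-K", "MQK", "ATGAAA", "ATGCAGAAG")
        assert cx == "ATG---AAA"
        assert cy == "ATGCAGAAG"

    def test_translation_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backtranslate("MK", "MK", "ATGCCC", "ATGAAG")  # CCC is P, not K

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backtranslate("MK", "MK", "ATGAA", "ATGAAG")


def ng86_path_oracle(c1, c2):
    """Independent recursion over mutation orders, using Biopython
    translation, for the (Sd, Nd) of one codon pair."""
    stops = {"TAA", "TAG", "TGA"}

    def walk(cur, remaining):
        if not remaining:
            return [(0.0, 0.0, False)]
        results = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            syn = (
                nxt not in stops
                and cur not in stops
                and str(Seq(cur).translate()) == str(Seq(nxt).translate())
            )
            for sd, nd, hit_stop in walk(nxt, [p for p in remaining if p != pos]):
                results.append(
                    (sd + (1 if syn else 0), nd + (0 if syn else 1),
                     hit_stop or nxt in stops)
                )
        return results

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    paths = walk(c1, diffs)
    clean = [(s, n) for s, n, stop in paths if not stop] or [
        (s, n) for s, n, _ in paths
    ]
    return (
        sum(s for s, _ in clean) / len(clean),
        sum(n for _, n in clean) / len(clean),
    )


class TestNG86:
    def test_identical_sequences(self):
        est = ks_ng86("ATGAAA", "ATGAAA")
        assert est.ks == 0.0 and est.Sd == 0.0

    def test_worked_example(self):
        # TTT/TTC synonymous third-position difference over three codons
        est = ks_ng86("TTTGGGAAA", "TTCGGGAAA")
        assert est.S == pytest.approx(5.0 / 3.0)
        assert est.Sd == pytest.approx(1.0)
        assert est.ps == pytest.approx(0.6)
        assert est.ks == pytest.approx(-0.75 * math.log(0.2))
        assert est.ks == pytest.approx(1.2071, abs=1e-4)

    def test_symmetry(self):
        x, y = "TTTGGGAAACCC", "TTCGGAAAACCA"
        ex, ey = ks_ng86(x, y), ks_ng86(y, x)
        assert ex.ks == pytest.approx(ey.ks)
        assert ex.S == pytest.approx(ey.S)

    def test_site_conservation_random_pairs(self, rng):
        codons = [
            a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        for _ in range(50):
            n = int(rng.integers(1, 20))
            x = "".join(rng.choice(codons, size=n))
            y = "".join(rng.choice(codons, size=n))
            est = ks_ng86(x, y)
            assert est.S + est.N == pytest.approx(3 * est.n_codons)

    def test_pathway_averaging_matches_oracle(self, rng):
        codons = [
            a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        for _ in range(200):
            c1, c2 = rng.choice(codons, size=2)
            est = ks_ng86(c1, c2)
            sd, nd = ng86_path_oracle(c1, c2)
            assert est.Sd == pytest.approx(sd)
            assert est.Nd == pytest.approx(nd)

    def test_saturation_flagged_not_raised(self):
        est = ks_ng86("GGA", "GGC")
        assert est.ps == pytest.approx(1.0)  # Sd=1 on S=1
        assert est.ks is None

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ks_ng86("TAAGGG", "TAAGGG")

    def test_gapped_columns_skipped(self):
        est = ks_ng86("---GGGAAA", "TTCGGGAAA")
        assert est.n_codons == 2

    def test_end_to_end_target_recovery(self):
        """Sequences simulated to target Ks 0.05-0.3 recover the target
        within 10% (median over 200 pairs)."""
        for t_ks in (0.05, 0.15, 0.3):
            clock = ClockSpec(rate=t_ks / 2.0, dispersion=0.0)
            table, seqs = simulate_ortholog_ks(
                clock, 200, 1.0, seed=17, with_sequences=True
            )
            est = [
                ks_ng86(seqs[r.gene_x], seqs[r.gene_y]).ks
                for r in table.itertuples(index=False)
            ]
            assert np.median(est) == pytest.approx(t_ks, rel=0.10)


class TestMedianAndDating:
    def test_median_odd(self):
        assert median_ks([0.1, 0.2, 0.9]) == pytest.approx(0.2)

    def test_median_even(self):
        assert median_ks([0.1, 0.3]) == pytest.approx(0.2)

    def test_undefined_excluded(self):
        assert median_ks([0.1, None, 0.3]) == pytest.approx(0.2)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            median_ks([None, None])

    def test_monte_carlo_median_near_clock(self):
        clock = ClockSpec(rate=0.005, dispersion=0.2)
        table, _ = simulate_ortholog_ks(clock, 1000, 15.0, seed=3)
        assert np.median(table["true_ks"]) == pytest.approx(0.15, rel=0.02)

    def test_calibration_identity(self):
        cal = CalibrationRange("cal", 10.0, 20.0, 0.10)
        res = calibrate_time(0.10, cal)
        assert (res.t_lo, res.t_hi) == (10.0, 20.0)

    def test_calibration_scaling(self):
        cal = CalibrationRange("cal", 10.0, 20.0, 0.10)
        res = calibrate_time(0.01, cal)
        assert (res.t_lo, res.t_hi) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_zero_ks(self):
        cal = CalibrationRange("cal", 10.0, 20.0, 0.10)
        res = calibrate_time(0.0, cal)
        assert (res.t_lo, res.t_hi) == (0.0, 0.0)

    @given(k=st.floats(0.001, 0.5), scale=st.floats(1.5, 4.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity(self, k, scale):
        cal = CalibrationRange("cal", 8.0, 18.0, 0.2)
        r1 = calibrate_time(k, cal)
        r2 = calibrate_time(scale * k, cal)
        assert r2.t_lo == pytest.approx(scale * r1.t_lo)
        assert r2.t_hi == pytest.approx(scale * r1.t_hi)

    def test_union_envelope(self):
        cals = [
            CalibrationRange("c1", 10.0, 15.0, 0.10),
            CalibrationRange("c2", 8.0, 20.0, 0.10),
        ]
        res = calibrate_time(0.10, cals)
        assert (res.t_lo, res.t_hi) == (8.0, 20.0)


class TestHomeologComponents:
    def test_disconnected_pairs(self):
        pairs = pd.DataFrame(
            [("x1", "y1"), ("x2", "y2")], columns=["gene_x", "gene_y"]
        )
        comps = homeolog_components(
            pairs, {"x1": "c1", "x2": "c3"}, {"y1": "c2", "y2": "c4"}
        )
        assert len(comps) == 2
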