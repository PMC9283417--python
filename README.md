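# hexkit

Subgenome and haplotype analysis for hexaploid genomes that mix
allopolyploid and autopolyploid ancestry — the situation of the asexual
Prussian carp (*Carassius gibelio*), whose 150 chromosomes form 25
homeologous groups, each present in two anciently diverged subgenomes
(A, B) and three recent haplotypes (a, b, c). Every chromosome is
addressed as `<group><subgenome><haplotype>` (e.g. `22Ba`).

`hexkit` implements the bespoke statistics such an analysis needs, plus a
seeded synthetic-data generator so every stage can be exercised and
validated end-to-end without multi-gigabase assemblies:

- **TE densities and the subgenome-biased index (SBI).** For a TE family
  with copy counts *f<sub>a</sub>, f<sub>b</sub>, f<sub>c</sub>* on the
  haplotype triplet of each group/subgenome *i* (50 triplets in the full
  karyotype), with *D<sub>ab,i</sub>* = |*f<sub>a</sub>* − *f<sub>b</sub>*|
  and *D<sub>ac,i</sub>* = |*f<sub>a</sub>* − *f<sub>c</sub>*|:

  SBI = Σ<sub>i</sub> |D<sub>ab,i</sub> − D<sub>ac,i</sub>| / Σ<sub>i</sub> (D<sub>ab,i</sub> + D<sub>ac,i</sub>)

  SBI ∈ [0, 1]; values near 1 mean the family is enriched on one haplotype
  of every triplet (an allopolyploid signature), values near 0 mean no
  haplotype specificity (autopolyploid-like). An A-vs-B analog flags
  subgenome-biased families.
- **Haplotype-c assignment.** The autopolyploid-added outgroup haplotype
  of each group is chosen by majority vote over three evidence lines
  (many-taxon tree, 4-taxon tree, pairwise divergences), with a
  deterministic tie-break cascade (best support, then the many-taxon tree).
- **Orthology and Ks dating.** Reciprocal-best-hit pairs, strict synteny
  confirmation (≥ 5 collinear pairs, gaps ≤ 4 genes on both genomes),
  Nei–Gojobori (1986) Ks with Jukes–Cantor correction, median-Ks
  summarization and linear-clock calibration to time intervals.
- **Duplicate-loss accounting.** Missing-gene sets per subgenome/haplotype
  over a conserved (BUSCO-style) catalog, A/B loss ratios, cross-species
  overlaps, A+B complementarity and coverage-checked deletion candidates.
- **Homeolog expression bias.** Per-chromosome read-count totals per organ
  and dominance labels across the six copies of each homeolog group.

## Worked example

Run the full pipeline on the default synthetic genome:

```bash
hexkit run --outdir demo --seed 42
```

`demo/summary.json` (excerpt) from that exact command:

```json
"te_bias":   {"TE_Abiased": {"ab_index": 0.829, "label": "A-biased"},
              "TE_neutral": {"ab_index": 0.078, "label": "unbiased"}},
"assign_haplotypes": {"n_assigned": 25, "n_correct": 25,
                      "rules": {"majority": 25}},
"ks_date":   {"median_ks": 0.2281, "t_lo": 14.88, "t_hi": 27.77},
"gene_loss": {"missing_pct": {"CarGib:A": 12.89, "CarGib:B": 7.35},
              "loss_ratio_AB": 1.8, "combined_missing_pct": 0.0}
```

Reading it: the two TE families simulated with a 10× subgenome bias are
recovered as A-/B-biased while the neutral family is not; all 25
haplotype-c assignments are recovered by simple majority; the median Ks
of ortholog pairs simulated at a 23-My divergence (0.228) calibrates to a
14.9–27.8 My interval; and the gene-loss stage recovers the configured
asymmetric loss (≈13% vs ≈8% per subgenome, ratio ≈ 1.8–2.0) with zero
genes lost from both subgenomes, the complementarity signature.

Library use mirrors the CLI:

```python
from hexkit import SimulationConfig, run_pipeline
summary = run_pipeline(SimulationConfig(), "demo", seed=42)
```

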