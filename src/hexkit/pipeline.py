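"""End-to-end orchestration: simulate → TE bias → haplotype vote →
orthologs → Ks dating → gene loss → expression, from one config.

Each stage writes its tabular output under the run directory and
contributes to a consolidated ``summary.json``.  Stage failures are
recorded and halt dependent stages only; the summary is written with
sorted keys so that re-running an identical (config, seed) is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gene_loss as gl
from . import simulate as sim
from .expression import bias_summary, chrom_totals
from .haplotype import assign_haplotype_c
from .io import write_chromosome_table
from .orthology import (
    CalibrationRange,
    calibrate_time,
    homeolog_components,
    ks_ng86,
    median_ks,
    reciprocal_best_hits,
    synteny_filter,
)
from .te_bias import bias_report, bias_report_frame, te_density

log = logging.getLogger(__name__)

STAGES = (
    "structure",
    "te_bias",
    "assign_haplotypes",
    "orthologs",
    "ks_date",
    "gene_loss",
    "expression",
)


def load_config(path: str | Path) -> sim.SimulationConfig:
    """Read a YAML simulate-config; omitted fields keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = sim.SimulationConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config field: {key}")
        current = getattr(cfg, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            setattr(cfg, key, type(current)(**value))
        elif key == "te_specs":
            setattr(cfg, key, [sim.TESpec(**v) for v in value])
        else:
            setattr(cfg, key, value)
    return cfg


def run_pipeline(
    config: sim.SimulationConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run every stage on a synthetic dataset; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, np.random.SeedSequence(seed).spawn(len(STAGES)))
    }
    summary: dict = {"seed": seed, "config": config.to_dict(), "stages": {}}

    structure = None
    try:
        structure = sim.simulate_structure(config, seed=stage_seeds["structure"])
        write_chromosome_table(structure, outdir / "chromosomes.tsv")
        report = structure.validate()
        summary["stages"]["structure"] = {
            "status": "ok",
            "n_chromosomes": len(structure),
            "n_groups": structure.n_groups,
            "valid": report.ok,
        }
    except Exception as exc:  # noqa: BLE001 - stage isolation
        log.exception("structure stage failed")
        summary["stages"]["structure"] = {"status": "failed", "error": str(exc)}

    if structure is not None:
        try:
            te_table = sim.simulate_te(
                structure, config.te_specs, stage_seeds["te_bias"]
            )
            reports = bias_report(te_table)
            frame = bias_report_frame(reports)
            frame.to_csv(outdir / "te_bias.tsv", sep="\t", index=False)
            te_density(te_table).to_csv(outdir / "te_density.tsv", sep="\t")
            summary["stages"]["te_bias"] = {
                "status": "ok",
                "labels": {
                    r.family: {
                        "sbi": r.sbi,
                        "ab_index": r.ab_index,
                        "label": r.label,
                    }
                    for r in reports
                },
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("te_bias stage failed")
            summary["stages"]["te_bias"] = {"status": "failed", "error": str(exc)}

        try:
            rng = np.random.default_rng(stage_seeds["assign_haplotypes"])
            true_c = {
                g: "abc"[rng.integers(0, 3)]
                for g in range(1, config.n_groups + 1)
            }
            evidence = sim.simulate_tree_evidence(
                config.n_groups, true_c, config.tree_noise,
                stage_seeds["assign_haplotypes"],
            )
            assignments = [assign_haplotype_c(evidence[g]) for g in sorted(evidence)]
            pd.DataFrame(
                [
                    {
                        "group": a.group,
                        "chosen_c": a.chosen_c or "",
                        "rule": a.rule_used,
                        "correct": a.chosen_c == true_c[a.group],
                    }
                    for a in assignments
                ]
            ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
            summary["stages"]["assign_haplotypes"] = {
                "status": "ok",
                "n_assigned": sum(a.chosen_c is not None for a in assignments),
                "n_correct": sum(a.chosen_c == true_c[a.group] for a in assignments),
                "rules": {
                    rule: sum(a.rule_used == rule for a in assignments)
                    for rule in {a.rule_used for a in assignments}
                },
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("assign_haplotypes stage failed")
            summary["stages"]["assign_haplotypes"] = {
                "status": "failed", "error": str(exc),
            }

        try:
            anchor_data = sim.simulate_anchor_map(
                structure, stage_seeds["orthologs"]
            )
            anchors = anchor_data["anchors"]
            ab = anchors[anchors["relation"] == "Ac-Ba"][["gene_x", "gene_y"]]
            hits_fwd, hits_rev = sim.simulate_hits_from_pairs(
                ab, stage_seeds["orthologs"]
            )
            rbh = reciprocal_best_hits(hits_fwd, hits_rev)
            confirmed = synteny_filter(
                rbh, anchor_data["orders"], anchor_data["orders"]
            )
            confirmed.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
            components = homeolog_components(
                anchors, anchor_data["gene_chrom"], anchor_data["gene_chrom"]
            )
            summary["stages"]["orthologs"] = {
                "status": "ok",
                "n_rbh": len(rbh),
                "n_confirmed": int(confirmed["synteny_confirmed"].sum()),
                "n_homeolog_groups": len(components),
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("orthologs stage failed")
            summary["stages"]["orthologs"] = {"status": "failed", "error": str(exc)}

    try:
        table, seqs = sim.simulate_ortholog_ks(
            config.clock, 200, config.t_subgenome, stage_seeds["ks_date"],
            with_sequences=True,
        )
        estimates = [
            ks_ng86(seqs[r.gene_x], seqs[r.gene_y])
            for r in table.itertuples(index=False)
        ]
        med = median_ks(estimates)
        expected = 2.0 * config.clock.rate * config.t_subgenome
        calibration = CalibrationRange("subgenome_AB", 15.0, 28.0, expected)
        dating = calibrate_time(med, calibration, pair_id="A_vs_B")
        pd.DataFrame(
            {
                "gene_x": table["gene_x"],
                "gene_y": table["gene_y"],
                "true_ks": table["true_ks"],
                "ks_ng86": [e.ks for e in estimates],
            }
        ).to_csv(outdir / "ks.tsv", sep="\t", index=False)
        summary["stages"]["ks_date"] = {
            "status": "ok",
            "median_ks": med,
            "t_lo": dating.t_lo,
            "t_hi": dating.t_hi,
        }
    except Exception as exc:  # noqa: BLE001
        log.exception("ks_date stage failed")
        summary["stages"]["ks_date"] = {"status": "failed", "error": str(exc)}

    if structure is not None:
        try:
            matrix = sim.simulate_gene_complement(
                structure, config.gene_loss, 2, stage_seeds["gene_loss"],
                species_names=["CarGib", "CarAur"],
            )
            gl.loss_report(matrix).to_csv(
                outdir / "gene_loss.tsv", sep="\t", index=False
            )
            by_sub = gl.missing_sets(matrix, gl.SUBGENOME_PARTITION)
            shared_a = gl.overlap_counts(
                by_sub, matrix.species, "A", complement_unit="B"
            )["shared_specific"]
            shared_b = gl.overlap_counts(
                by_sub, matrix.species, "B", complement_unit="A"
            )["shared_specific"]
            ratio = gl.loss_ratio(shared_a, shared_b)
            comp = gl.complementarity(matrix, "CarGib")
            summary["stages"]["gene_loss"] = {
                "status": "ok",
                "missing_pct": {
                    f"{sp}:{unit}": 100.0 * len(genes) / matrix.n_genes
                    for (sp, unit), genes in sorted(by_sub.items())
                },
                "shared_specific_A": shared_a,
                "shared_specific_B": shared_b,
                "loss_ratio_AB": ratio.rounded,
                "combined_missing_pct": comp.combined_missing_pct,
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("gene_loss stage failed")
            summary["stages"]["gene_loss"] = {"status": "failed", "error": str(exc)}

        try:
            em = sim.simulate_expression(
                structure, config.expression, stage_seeds["expression"]
            )
            raw, cpm = chrom_totals(em)
            cpm.to_csv(outdir / "expression_cpm.tsv", sep="\t")
            groups = _homeolog_groups_from_map(em.gene_chrom, structure.n_groups)
            contingency, flags = bias_summary(groups, em)
            summary["stages"]["expression"] = {
                "status": "ok",
                "dominance_flags": flags,
                "label_counts": {
                    organ: {
                        str(k): int(v) for k, v in contingency.loc[organ].items()
                    }
                    for organ in contingency.index
                },
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("expression stage failed")
            summary["stages"]["expression"] = {"status": "failed", "error": str(exc)}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary


def _homeolog_groups_from_map(gene_chrom, n_groups):
    """One HomeologGroup per group, taking each chromosome's first gene as
    the group's member copy."""
    from .expression import HomeologGroup

    members: dict[int, dict] = {g: {} for g in range(1, n_groups + 1)}
    for gid, cid in gene_chrom.items():
        key = (cid.subgenome, cid.haplotype)
        members[cid.group].setdefault(key, gid)
    return [HomeologGroup(g, m) for g, m in sorted(members.items())]
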