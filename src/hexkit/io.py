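"""Readers and writers for the pipeline's tabular, FASTA, GFF3 and Newick inputs.

All tabular formats are plain TSV.  GFF3 and RepeatMasker-style tables are
1-based inclusive; BED is 0-based half-open and converted on read.  Feature
rows on chromosomes that cannot be parsed into the canonical naming scheme
are collected into an ``unassigned`` bucket rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .core import ChromosomeID, ChromosomeNameError, FeatureRecord, GenomeStructure

log = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

BUSCO_STATUSES = {"Complete", "Duplicated", "Fragmented", "Missing"}


@dataclass
class FeatureReadResult:
    """Features keyed to the known inventory, plus anything unplaceable."""

    features: list[FeatureRecord] = field(default_factory=list)
    unassigned: list[tuple[str, int, int, str]] = field(default_factory=list)
    n_malformed: int = 0


# ---------------------------------------------------------------------------
# chromosome table


def read_chromosome_table(path: str | Path, n_groups: int = 25) -> GenomeStructure:
    """Read a TSV ``chrom  group  subgenome  haplotype  length_bp``."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        cid = ChromosomeID(int(row.group), str(row.subgenome), str(row.haplotype))
        entries.append((cid, int(row.length_bp)))
    return GenomeStructure(entries, n_groups=n_groups)


def write_chromosome_table(structure: GenomeStructure, path: str | Path) -> None:
    rows = [
        {
            "chrom": str(cid),
            "group": cid.group,
            "subgenome": cid.subgenome,
            "haplotype": cid.haplotype,
            "length_bp": structure.length(cid),
        }
        for cid in structure
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TE features (TSV or BED)


def _bucket_features(
    rows: Iterable[tuple[str, int, int, str, str]], max_group: int
) -> FeatureReadResult:
    out = FeatureReadResult()
    for chrom, start, end, kind, strand in rows:
        try:
            cid = ChromosomeID.parse(str(chrom), max_group=max_group)
        except ChromosomeNameError:
            out.unassigned.append((str(chrom), start, end, kind))
            continue
        try:
            out.features.append(FeatureRecord(cid, start, end, kind, strand))
        except ValueError:
            out.n_malformed += 1
    if out.unassigned:
        log.info("%d features on unrecognized chromosomes", len(out.unassigned))
    if out.n_malformed:
        log.warning("%d malformed feature rows rejected", out.n_malformed)
    return out


def read_te_table(path: str | Path, max_group: int = 25) -> FeatureReadResult:
    """Read TE copies from a TSV ``chrom  start  end  te_family`` (1-based
    inclusive, RepeatMasker-.out convertible)."""
    df = pd.read_csv(path, sep="\t")
    rows = (
        (r.chrom, int(r.start), int(r.end), str(r.te_family), ".")
        for r in df.itertuples(index=False)
    )
    return _bucket_features(rows, max_group)


def read_te_bed(path: str | Path, max_group: int = 25) -> FeatureReadResult:
    """Read TE copies from 4-column BED (0-based half-open → 1-based closed)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    rows = (
        (r.chrom, int(r.start) + 1, int(r.end), str(r.name), ".")
        for r in df.itertuples(index=False)
    )
    return _bucket_features(rows, max_group)


# ---------------------------------------------------------------------------
# GFF3 genes


def read_gff3_genes(path: str | Path, max_group: int = 25) -> FeatureReadResult:
    """Read gene features from GFF3; ``kind`` is the gene ID attribute."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("Name", "unknown"))
            rows.append((parts[0], int(parts[3]), int(parts[4]), gid, parts[6]))
    return _bucket_features(rows, max_group)


def write_gff3_genes(
    features: Iterable[FeatureRecord], path: str | Path, source: str = "hexkit"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chromosome}\t{source}\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand if f.strand in '+-' else '.'}\t.\tID={f.kind}\n"
            )


# ---------------------------------------------------------------------------
# BUSCO-style presence tables


def read_busco_table(path: str | Path) -> pd.DataFrame:
    """Read a BUSCO full_table-style TSV with columns
    ``busco_id  status  sequence [...]`` (comment lines allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None).iloc[:, :3]
    df.columns = ["busco_id", "status", "sequence"]
    bad = set(df["status"]) - BUSCO_STATUSES
    if bad:
        raise ValueError(f"unknown BUSCO statuses: {sorted(bad)}")
    return df


def busco_present(df: pd.DataFrame, fragmented_counts: bool = True) -> pd.Series:
    """Boolean presence per busco_id; 'Fragmented' counts as present by
    default."""
    present = {"Complete", "Duplicated"}
    if fragmented_counts:
        present.add("Fragmented")
    return df.set_index("busco_id")["status"].isin(present)


# ---------------------------------------------------------------------------
# similarity hits


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular similarity hits (outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    if (df["bitscore"] < 0).any():
        raise ValueError("negative bitscore in hits table")
    return df


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# simple TSV matrices


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Gene × organ raw counts, genes in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """TSV ``gene  chrom  mean_haploid_cov``."""
    return pd.read_csv(path, sep="\t")


def read_divergence_table(path: str | Path) -> pd.DataFrame:
    """TSV of pairwise haplotype divergences:
    ``group  hap1  hap2  divergence_pct``."""
    return pd.read_csv(path, sep="\t")
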