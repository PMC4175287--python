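"""Readers and writers for the plain-text formats the pipeline consumes.

BED and bedGraph are 0-based half-open. TSS annotations travel as TSV with a
``gene_id/chrom/strand/tss/expression`` header; a GTF import helper extracts
the strand-aware transcript 5' end.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomeLayout, Peak, PeakSet

TSS_COLUMNS = ["gene_id", "chrom", "strand", "tss", "expression"]


def read_bed(path, layout: GenomeLayout | None = None) -> PeakSet:
    """Read peaks from BED3/BED6 (score taken from column 5 when present)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = None
            if len(parts) >= 5 and parts[4] not in (".", ""):
                score = float(parts[4])
            peaks.append(Peak(chrom, start, end, score))
    return PeakSet(peaks, layout=layout)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\n")


def read_tss_table(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TSS table missing columns: {missing}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            expression=float(r.expression),
        )
        for r in df.itertuples()
    ]


def write_tss_table(genes: Sequence[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "expression": [g.expression for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def tss_from_gtf(path, feature: str = "transcript") -> list[GeneAnnotation]:
    """Extract TSSs from a GTF: 5' end of each ``feature`` row, per gene_id.

    For genes with several transcripts the 5'-most TSS (strand-aware) is
    kept. Expression is initialised to 0 and must be joined separately.
    """
    best: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                continue
            tss = start - 1 if strand == "+" else end - 1  # GTF is 1-based
            prev = best.get(gene_id)
            if prev is None or (strand == "+" and tss < prev.tss) or (
                strand == "-" and tss > prev.tss
            ):
                best[gene_id] = GeneAnnotation(gene_id, chrom, strand, tss)
    return sorted(best.values(), key=lambda g: g.gene_id)


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.append((chrom, int(start), int(end), float(value)))
    return out


def write_bedgraph(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_histogram(hist: pd.DataFrame, path) -> None:
    hist.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes-in-rows, samples-in-columns TSV with gene ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return df


def read_tf_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"probe_id", "gene_id", "beta"}
    if not need.issubset(df.columns):
        raise ValueError(f"probe table requires columns {sorted(need)}")
    return df


def read_annotation_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> term_id -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.term_id), set()).add(str(r.gene_id))
    return out
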