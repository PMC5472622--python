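"""Readers and writers for the tab-separated formats the pipeline touches.

Internal coordinates are always 0-based half-open; 1-based coordinates
appear only at the methylKit-TSV boundary.  Readers do not assume sorted
input and sort by (chrom, pos) on load.  Lines starting with ``#`` are
treated as comments everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import as_set, subtract

__all__ = [
    "CpGRecord",
    "ProbeBeta",
    "GenomicInterval",
    "GeneModel",
    "MalformedRowError",
    "read_methylkit_tsv",
    "write_methylkit_tsv",
    "read_bedgraph_coverage",
    "write_bedgraph_coverage",
    "read_bed",
    "write_bed",
    "read_refflat",
    "write_refflat",
    "derive_segments",
    "promoter_interval",
    "read_deseq_tsv",
    "write_deseq_tsv",
    "read_gene_list",
    "read_manifest",
    "write_manifest",
]


class MalformedRowError(ValueError):
    """A data row violates the format's internal consistency rules."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class CpGRecord:
    """One CpG site: strand-aware position with methylated/total read counts."""

    chrom: str
    pos: int  # 0-based
    strand: str = "."
    coverage: int = 0
    meth_count: int = 0

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError(f"negative coverage at {self.chrom}:{self.pos}")
        if not (0 <= self.meth_count <= self.coverage):
            raise ValueError(
                f"meth_count {self.meth_count} outside [0, coverage={self.coverage}] "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def proportion(self) -> float:
        return self.meth_count / self.coverage if self.coverage else float("nan")


@dataclass(frozen=True, order=True)
class ProbeBeta:
    """One 450K-style array probe with its beta value (methylation proportion)."""

    probe_id: str
    chrom: str
    pos: int  # 0-based
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta {self.beta} outside [0,1] for {self.probe_id}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end} ({self.name})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple = field(default_factory=tuple)
    exon_ends: tuple = field(default_factory=tuple)

    def __post_init__(self):
        es, ee = tuple(self.exon_starts), tuple(self.exon_ends)
        object.__setattr__(self, "exon_starts", es)
        object.__setattr__(self, "exon_ends", ee)
        if len(es) != len(ee):
            raise ValueError(f"{self.gene_id}: exon start/end lists of unequal length")
        prev_end = self.tx_start
        for s, e in zip(es, ee):
            if s >= e or s < prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted, disjoint")
            prev_end = e
        if es and (es[0] < self.tx_start or ee[-1] > self.tx_end):
            raise ValueError(f"{self.gene_id}: exons outside transcript bounds")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS interval outside transcript")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand != "-" else self.tx_end

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end


def _data_lines(path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


_STRAND_MAP = {"F": "+", "R": "-", "+": "+", "-": "-", ".": ".", "*": "."}


def _round_half_away(x: float) -> int:
    # freqC is a percentage with limited precision; round half away from zero
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def read_methylkit_tsv(path) -> list[CpGRecord]:
    """Read a methylKit-style CpG table (1-based ``base``, freqC/freqT percentages)."""
    records = []
    header_seen = False
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields[0] != "chrBase":
                raise MalformedRowError(path, line_no, "expected methylKit header 'chrBase...'")
            header_seen = True
            continue
        if len(fields) != 7:
            raise MalformedRowError(path, line_no, f"expected 7 columns, got {len(fields)}")
        _, chrom, base, strand, coverage, freq_c, freq_t = fields
        coverage = int(coverage)
        freq_c, freq_t = float(freq_c), float(freq_t)
        if coverage < 0:
            raise MalformedRowError(path, line_no, "negative coverage")
        if abs(freq_c + freq_t - 100.0) > 0.5:
            raise MalformedRowError(
                path, line_no, f"freqC+freqT = {freq_c + freq_t:g}, deviates from 100 by > 0.5"
            )
        records.append(
            CpGRecord(
                chrom=chrom,
                pos=int(base) - 1,
                strand=_STRAND_MAP.get(strand, "."),
                coverage=coverage,
                meth_count=min(coverage, _round_half_away(coverage * freq_c / 100.0)),
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_methylkit_tsv(path, records: Iterable[CpGRecord]) -> None:
    inv = {"+": "F", "-": "R", ".": "*"}
    with open(path, "w") as fh:
        fh.write("chrBase\tchr\tbase\tstrand\tcoverage\tfreqC\tfreqT\n")
        for r in sorted(records):
            freq_c = 100.0 * r.meth_count / r.coverage if r.coverage else 0.0
            fh.write(
                f"{r.chrom}.{r.pos + 1}\t{r.chrom}\t{r.pos + 1}\t{inv[r.strand]}\t"
                f"{r.coverage}\t{freq_c:.6f}\t{100.0 - freq_c:.6f}\n"
            )


def read_bedgraph_coverage(path) -> list[CpGRecord]:
    """Read a Bismark-coverage-style bedGraph (0-based start, percent, meth/unmeth counts)."""
    records = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise MalformedRowError(path, line_no, f"expected 6 columns, got {len(fields)}")
        chrom, start, _end, percent, n_meth, n_unmeth = fields
        n_meth, n_unmeth = int(n_meth), int(n_unmeth)
        coverage = n_meth + n_unmeth
        percent = float(percent)
        implied = 100.0 * n_meth / coverage if coverage else 0.0
        if abs(percent - implied) > 0.5:
            raise MalformedRowError(
                path, line_no,
                f"percent column says {percent:g} but counts imply {implied:g}",
            )
        records.append(CpGRecord(chrom, int(start), ".", coverage, n_meth))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_bedgraph_coverage(path, records: Iterable[CpGRecord]) -> None:
    with open(path, "w") as fh:
        for r in sorted(records):
            pct = 100.0 * r.meth_count / r.coverage if r.coverage else 0.0
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{pct:.6f}\t"
                f"{r.meth_count}\t{r.coverage - r.meth_count}\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    out = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise MalformedRowError(path, line_no, "BED needs >= 3 columns")
        name = fields[3] if len(fields) > 3 else "."
        strand = fields[5] if len(fields) > 5 else "."
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name, strand))
    out.sort()
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], extra_cols=None) -> None:
    """Write BED6; ``extra_cols`` maps an interval's index to extra fields (BED6+)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name, "0", iv.strand]
            if extra_cols is not None:
                row.extend(str(x) for x in extra_cols[i])
            fh.write("\t".join(row) + "\n")


def read_refflat(path) -> list[GeneModel]:
    genes = []
    for line_no, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 11:
            raise MalformedRowError(path, line_no, "refFlat needs 11 columns")
        starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
        ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
        if len(starts) != len(ends):
            raise MalformedRowError(path, line_no, "exon start/end lists of unequal length")
        genes.append(
            GeneModel(
                gene_id=f[0], chrom=f[2], strand=f[3],
                tx_start=int(f[4]), tx_end=int(f[5]),
                cds_start=int(f[6]), cds_end=int(f[7]),
                exon_starts=tuple(starts), exon_ends=tuple(ends),
            )
        )
    return genes


def write_refflat(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id, g.gene_id, g.chrom, g.strand,
                        str(g.tx_start), str(g.tx_end),
                        str(g.cds_start), str(g.cds_end),
                        str(len(g.exon_starts)),
                        ",".join(str(x) for x in g.exon_starts) + ",",
                        ",".join(str(x) for x in g.exon_ends) + ",",
                    ]
                )
                + "\n"
            )


def promoter_interval(gene: GeneModel, halfwidth: int = 1000, chrom_size: int | None = None):
    """Promoter = ``halfwidth`` bp on each side of the TSS, clipped at chromosome bounds."""
    start = max(0, gene.tss - halfwidth)
    end = gene.tss + halfwidth
    if chrom_size is not None:
        end = min(end, chrom_size)
    return start, end


def derive_segments(
    gene: GeneModel, promoter_halfwidth: int = 1000, chrom_size: int | None = None
) -> dict[str, np.ndarray]:
    """Split a gene model into promoter / 5'UTR / CDS / 3'UTR / intron / gene body.

    UTRs are exonic sequence outside the CDS interval, oriented by strand;
    introns are the gaps between exons; gene body is the transcribed interval.
    A non-coding gene (cds_start == cds_end) has no UTR or CDS segments.
    """
    exonic = as_set(zip(gene.exon_starts, gene.exon_ends)) if gene.exon_starts \
        else as_set([(gene.tx_start, gene.tx_end)])
    tx = as_set([(gene.tx_start, gene.tx_end)])
    introns = subtract(tx, exonic)
    seg: dict[str, np.ndarray] = {
        "gene body": tx,
        "intron": introns,
        "promoter": as_set([promoter_interval(gene, promoter_halfwidth, chrom_size)]),
    }
    if gene.is_coding:
        from .intervals import intersect

        cds_set = as_set([(gene.cds_start, gene.cds_end)])
        upstream = as_set([(gene.tx_start, gene.cds_start)]) if gene.tx_start < gene.cds_start \
            else np.empty((0, 2), dtype=np.int64)
        downstream = as_set([(gene.cds_end, gene.tx_end)]) if gene.cds_end < gene.tx_end \
            else np.empty((0, 2), dtype=np.int64)
        five = intersect(exonic, upstream if gene.strand != "-" else downstream)
        three = intersect(exonic, downstream if gene.strand != "-" else upstream)
        seg["5'UTR"] = five
        seg["3'UTR"] = three
        seg["CDS"] = intersect(exonic, cds_set)
    return seg


def read_deseq_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "log2FoldChange", "pval", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedRowError(path, 1, f"missing columns: {sorted(missing)}")
    return df


def write_deseq_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["id", "log2FoldChange", "pval", "padj"])


def read_gene_list(path) -> list[str]:
    names = []
    for _line_no, line in _data_lines(path):
        names.append(line.split("\t")[0].strip())
    return names


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")


def read_manifest(path) -> dict[str, str]:
    out = {}
    for _line_no, line in _data_lines(path):
        key, _, value = line.partition("=")
        out[key] = value
    return out
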