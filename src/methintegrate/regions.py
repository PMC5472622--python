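"""Six-region CGI/shore/promoter partition, feature assignment, region
methylation profiles, and DMR-TSG segment overlap.

The six regions follow the set formulas (P = merged promoters, CGI =
merged islands, S = shores, i.e. 1 kb flanks of each island minus island
bases):

    I   CGI.NP   = CGI \\ P      islands outside promoters
    II  CGIS.NP  = S \\ P        shores outside promoters
    III P.CGI    = CGI ∩ P      islands inside promoters
    IV  P.CGIS   = S ∩ P        shores inside promoters
    V   P.NCGI   = P \\ CGI      promoter bases outside islands
    VI  P.NCGIS  = P \\ (S u CGI)  promoter bases outside shores and islands

Region VI removes island bases as well as shore bases: a CpG island is not
its own shore, but a promoter base inside an island is not "out of the
island neighbourhood" either, and VI is meant to capture open-sea promoter
sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import GeneModel, GenomicInterval, derive_segments, promoter_interval

__all__ = [
    "REGION_NAMES",
    "RegionPartition",
    "build_partition",
    "assign_features",
    "region_methylation_profiles",
    "overlap_tsg",
    "annotate_genes_to_dmrs",
]

REGION_NAMES = ("CGI.NP", "CGIS.NP", "P.CGI", "P.CGIS", "P.NCGI", "P.NCGIS")


@dataclass
class RegionPartition:
    """Per-chromosome interval sets for the six regions plus the P/CGI/S inputs."""

    regions: dict = field(default_factory=dict)   # name -> {chrom -> (n,2) array}
    promoters: dict = field(default_factory=dict)  # chrom -> array
    cgis: dict = field(default_factory=dict)
    shores: dict = field(default_factory=dict)

    def intervals(self, name: str) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.regions[name]):
            for s, e in self.regions[name][chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e), name))
        return out


def _by_chrom(items) -> dict[str, np.ndarray]:
    acc: dict[str, list] = defaultdict(list)
    for it in items:
        acc[it.chrom].append((it.start, it.end))
    return {c: iv.as_set(v) for c, v in acc.items()}


def build_partition(
    cgis,
    genes,
    shore_flank: int = 1000,
    promoter_halfwidth: int = 1000,
    chrom_sizes: dict | None = None,
) -> RegionPartition:
    """Compute the six-region partition from CGI intervals and gene models.

    CGIs are merged before shores are computed, and shore bases overlapping
    any island are removed, so islands and shores are disjoint by
    construction.  Promoters are the merged union of TSS +/- halfwidth.
    """
    cgi_by = _by_chrom(cgis)
    prom_items = []
    for g in genes:
        s, e = promoter_interval(
            g, promoter_halfwidth, None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        )
        if s < e:
            prom_items.append(GenomicInterval(g.chrom, s, e, g.gene_id, g.strand))
    prom_by = _by_chrom(prom_items)

    part = RegionPartition()
    chroms = sorted(set(cgi_by) | set(prom_by))
    empty = np.empty((0, 2), dtype=np.int64)
    for name in REGION_NAMES:
        part.regions[name] = {}
    for chrom in chroms:
        cgi = cgi_by.get(chrom, empty)
        p = prom_by.get(chrom, empty)
        flanks = []
        for s, e in cgi:
            lo = max(0, s - shore_flank)
            if lo < s:
                flanks.append((lo, s))
            hi = e + shore_flank
            if chrom_sizes is not None and chrom in chrom_sizes:
                hi = min(hi, chrom_sizes[chrom])
            if e < hi:
                flanks.append((e, hi))
        shore = iv.subtract(iv.as_set(flanks), cgi) if flanks else empty
        part.promoters[chrom] = p
        part.cgis[chrom] = cgi
        part.shores[chrom] = shore
        part.regions["CGI.NP"][chrom] = iv.subtract(cgi, p)
        part.regions["CGIS.NP"][chrom] = iv.subtract(shore, p)
        part.regions["P.CGI"][chrom] = iv.intersect(cgi, p)
        part.regions["P.CGIS"][chrom] = iv.intersect(shore, p)
        part.regions["P.NCGI"][chrom] = iv.subtract(p, cgi)
        part.regions["P.NCGIS"][chrom] = iv.subtract(p, iv.union(shore, cgi))
    return part


_GENE_PRECEDENCE = ("promoter", "exon", "intron", "intergenic")
_CPG_PRECEDENCE = ("CGI", "shore", "open sea")


def assign_features(
    sites,
    cgis,
    genes,
    shore_flank: int = 1000,
    promoter_halfwidth: int = 1000,
    chrom_sizes: dict | None = None,
):
    """Assign each site one gene-context and one CpG-context label.

    Precedence: promoter > exon > intron > intergenic, and
    CGI > shore > open sea, so every site gets exactly one label per
    hierarchy.  Sites may be (chrom, pos) pairs or objects with
    ``.chrom``/``.pos``.  Returns ``(assignments, fractions)``: a DataFrame
    with one row per site and a dict of per-label fractions.
    """
    part = build_partition(cgis, genes, shore_flank, promoter_halfwidth, chrom_sizes)
    exon_by = _by_chrom(
        GenomicInterval(g.chrom, s, e, g.gene_id)
        for g in genes
        for s, e in zip(g.exon_starts, g.exon_ends)
    )
    intron_items = []
    for g in genes:
        for s, e in derive_segments(g, promoter_halfwidth)["intron"]:
            intron_items.append(GenomicInterval(g.chrom, int(s), int(e), g.gene_id))
    intron_by = _by_chrom(intron_items)

    empty = np.empty((0, 2), dtype=np.int64)
    rows = []
    for site in sites:
        chrom, pos = (site.chrom, site.pos) if hasattr(site, "chrom") else site
        pos_a = np.array([pos])
        if iv.positions_in(pos_a, part.promoters.get(chrom, empty))[0]:
            gene_label = "promoter"
        elif iv.positions_in(pos_a, exon_by.get(chrom, empty))[0]:
            gene_label = "exon"
        elif iv.positions_in(pos_a, intron_by.get(chrom, empty))[0]:
            gene_label = "intron"
        else:
            gene_label = "intergenic"
        if iv.positions_in(pos_a, part.cgis.get(chrom, empty))[0]:
            cpg_label = "CGI"
        elif iv.positions_in(pos_a, part.shores.get(chrom, empty))[0]:
            cpg_label = "shore"
        else:
            cpg_label = "open sea"
        rows.append((chrom, pos, gene_label, cpg_label))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "gene_context", "cpg_context"])
    n = max(len(df), 1)
    fractions = {
        **{lab: float((df["gene_context"] == lab).sum()) / n for lab in _GENE_PRECEDENCE},
        **{lab: float((df["cpg_context"] == lab).sum()) / n for lab in _CPG_PRECEDENCE},
    }
    return df, fractions


def region_methylation_profiles(
    methylome,
    partition: RegionPartition,
    tf_peaks=None,
    n_bins: int = 20,
):
    """Per-region histograms (and quartiles) of methylation percent.

    With ``tf_peaks`` given, only CpGs inside region intervals that overlap
    at least one peak are profiled.  Returns a dict
    region -> {"counts", "bin_edges", "quartiles", "n"}.
    """
    peaks_by = _by_chrom(tf_peaks) if tf_peaks is not None else None
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    empty = np.empty((0, 2), dtype=np.int64)
    recs_by: dict[str, list] = defaultdict(list)
    for r in methylome:
        if r.coverage > 0:
            recs_by[r.chrom].append(r)
    out = {}
    for name in REGION_NAMES:
        values = []
        for chrom, regions in partition.regions[name].items():
            if peaks_by is not None:
                keep = [row for row in regions
                        if iv.total_length(iv.intersect(np.array([row]),
                                                        peaks_by.get(chrom, empty))) > 0]
                regions = np.asarray(keep, dtype=np.int64).reshape(-1, 2)
            if len(regions) == 0 or chrom not in recs_by:
                continue
            pos = np.array([r.pos for r in recs_by[chrom]])
            mask = iv.positions_in(pos, regions)
            values.extend(100.0 * r.meth_count / r.coverage
                          for r, m in zip(recs_by[chrom], mask) if m)
        values = np.asarray(values)
        counts, _ = np.histogram(values, bins=edges) if len(values) else (np.zeros(n_bins, int), edges)
        out[name] = {
            "counts": counts,
            "bin_edges": edges,
            "quartiles": np.percentile(values, [25, 50, 75]) if len(values) else None,
            "n": len(values),
        }
    return out


@dataclass(frozen=True)
class TSGOverlap:
    dmr_name: str
    gene_id: str
    segment: str  # promoter | 5'UTR | 3'UTR | CDS | intron
    direction: str


def overlap_tsg(dmrs, tsg_gene_ids, genes, promoter_halfwidth: int = 1000):
    """Overlap DMRs with tumor-suppressor genes' segment intervals.

    Emits one record per (DMR, gene, segment) sharing >= 1 base; the returned
    per-direction counts deduplicate genes.  TSG ids absent from the gene
    catalogue are skipped.
    """
    catalogue = {g.gene_id: g for g in genes}
    tsgs = [catalogue[t] for t in tsg_gene_ids if t in catalogue]
    seg_names = ("promoter", "5'UTR", "3'UTR", "CDS", "intron")
    records = []
    for dmr in dmrs:
        d = dmr.interval
        for g in tsgs:
            if g.chrom != d.chrom:
                continue
            segs = derive_segments(g, promoter_halfwidth)
            for name in seg_names:
                if name not in segs:
                    continue
                if any(s < d.end and d.start < e for s, e in segs[name]):
                    records.append(TSGOverlap(d.name, g.gene_id, name, dmr.direction))
    counts = {
        "hyper": len({r.gene_id for r in records if r.direction == "hyper"}),
        "hypo": len({r.gene_id for r in records if r.direction == "hypo"}),
    }
    return records, counts


def annotate_genes_to_dmrs(dmrs, genes, promoter_halfwidth: int = 1000) -> pd.DataFrame:
    """One row per (gene, hosting DMR): the DMR with the largest overlap of
    the gene's segments, with the segment label chosen by largest overlap
    (ties broken alphabetically).  Feeds the expression regression design.
    """
    fine = ("promoter", "5'UTR", "3'UTR", "CDS", "intron")
    rows = []
    for g in genes:
        segs = derive_segments(g, promoter_halfwidth)
        best = None  # (total_overlap, dmr, segment)
        for dmr in dmrs:
            d = dmr.interval
            if d.chrom != g.chrom:
                continue
            total = max(0, min(d.end, g.tx_end) - max(d.start, g.tx_start))
            ps, pe = promoter_interval(g, promoter_halfwidth)
            total += max(0, min(d.end, pe) - max(d.start, ps))
            if total <= 0:
                continue
            # most specific segment by largest overlap, ties alphabetical;
            # a DMR inside the transcript but in no finer class is "gene body"
            seg_best = None
            for name in fine:
                if name not in segs:
                    continue
                ov = sum(min(d.end, int(e)) - max(d.start, int(s))
                         for s, e in segs[name]
                         if s < d.end and d.start < e)
                if ov > 0 and (seg_best is None or ov > seg_best[0] or
                               (ov == seg_best[0] and name < seg_best[1])):
                    seg_best = (ov, name)
            segment = seg_best[1] if seg_best is not None else "gene body"
            if best is None or total > best[0]:
                best = (total, dmr, segment)
        if best is not None:
            _, dmr, segment = best
            rows.append((g.gene_id, dmr.interval.name, segment, dmr.mean_diff, dmr.direction))
    return pd.DataFrame(rows, columns=["gene", "dmr", "segment", "methy", "direction"])
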