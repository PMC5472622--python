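"""DMC/DMR calling between a reference cell type and a comparator, plus
cell-type-specific DMR sets by set deduction.

Per shared CpG passing the coverage filter in both samples, a two-sided
Fisher exact test on the 2x2 methylated/unmethylated table decides
differential methylation; Benjamini-Hochberg controls the FDR across all
tested sites.  DMRs are built on a fixed tiling (default 1,000 bp windows),
testing pooled counts per window, with adjacent qualifying same-direction
windows merged.  A DMR is *candidate* at |mean diff| >= 20 points and
q <= 0.01 and *significant* when additionally q <= 0.001 with >= 5
qualifying DMCs inside.

Cell-type specificity follows pure set subtraction: a reference DMR is
cell-type-specific iff it overlaps (by >= 1 base, direction-agnostic) no
DMR of any other cell type in the comparison set.

The hyper/hypo sign convention is reference minus comparator: *hyper*
means more methylated in the reference cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CpGRecord, GenomicInterval

__all__ = [
    "DMC",
    "DMR",
    "CellSpecificDMRSet",
    "benjamini_hochberg",
    "call_dmcs",
    "call_dmrs",
    "cell_specific_subtraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DMC:
    chrom: str
    pos: int
    meth_diff: float  # percentage points, reference minus comparator
    p_value: float
    q_value: float

    @property
    def direction(self) -> str:
        return "hyper" if self.meth_diff > 0 else "hypo"


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    mean_diff: float  # percentage points
    q_value: float
    n_dmcs: int
    direction: str
    tier: str  # candidate | significant


@dataclass
class CellSpecificDMRSet:
    reference_cell: str
    dmrs: list = field(default_factory=list)
    removed: list = field(default_factory=list)  # (DMR, blocking cell)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _aligned_counts(ref, other, min_coverage):
    """Join two record lists on (chrom, pos), keeping sites covered in both."""
    ref_map = {(r.chrom, r.pos): r for r in ref if r.coverage >= min_coverage}
    rows = []
    for o in other:
        if o.coverage < min_coverage:
            continue
        r = ref_map.get((o.chrom, o.pos))
        if r is not None:
            rows.append((r.chrom, r.pos, r.meth_count, r.coverage, o.meth_count, o.coverage))
    rows.sort(key=lambda t: (t[0], t[1]))
    return rows


def _fisher_many(tables):
    """Two-sided Fisher exact p for each (a, b, c, d) table, deduplicated."""
    cache: dict[tuple, float] = {}
    out = np.empty(len(tables))
    for i, tab in enumerate(tables):
        p = cache.get(tab)
        if p is None:
            p = stats.fisher_exact([[tab[0], tab[1]], [tab[2], tab[3]]])[1]
            cache[tab] = p
        out[i] = p
    return out


def call_dmcs(
    ref,
    other,
    min_coverage: int = 10,
    diff_min: float = 25.0,
    q_max: float = 0.01,
    return_all: bool = False,
):
    """Call differentially-methylated CpGs, reference vs comparator.

    With ``return_all`` the full tested-site table is returned (all shared
    sites passing coverage with their diff/p/q), otherwise only the DMCs
    passing ``|diff| >= diff_min`` and ``q <= q_max``.
    """
    rows = _aligned_counts(ref, other, min_coverage)
    if not rows:
        logger.warning("call_dmcs: zero shared sites passing coverage >= %d", min_coverage)
        return []
    tables = [(mr, cr - mr, mo, co - mo) for _, _, mr, cr, mo, co in rows]
    p = _fisher_many(tables)
    q = benjamini_hochberg(p)
    out = []
    for (chrom, pos, mr, cr, mo, co), pi, qi in zip(rows, p, q):
        diff = 100.0 * (mr / cr - mo / co)
        dmc = DMC(chrom, pos, diff, float(pi), float(qi))
        if return_all or (abs(diff) >= diff_min and qi <= q_max):
            out.append(dmc)
    return out


def call_dmrs(
    dmcs,
    ref,
    other,
    min_coverage: int = 10,
    window: int = 1000,
    step: int = 1000,
    diff_min: float = 20.0,
    q_candidate: float = 0.01,
    q_significant: float = 0.001,
    min_dmcs: int = 5,
):
    """Tile the tested sites into windows, test pooled counts, merge, and tier.

    Windows with >= 1 tested CpG are Fisher-tested on pooled per-sample
    counts and BH-adjusted across windows.  Qualifying windows
    (|mean diff| >= diff_min, q <= q_candidate) that are adjacent with the
    same direction merge into one DMR whose mean diff is recomputed from the
    merged pooled counts (q = the most significant member window's).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    rows = _aligned_counts(ref, other, min_coverage)
    if not rows:
        return []
    dmc_keys = {(d.chrom, d.pos) for d in dmcs}
    # bucket tested sites into tiling windows
    buckets: dict[tuple, list] = {}
    for chrom, pos, mr, cr, mo, co in rows:
        w = pos // step
        buckets.setdefault((chrom, w), []).append((pos, mr, cr, mo, co))
    keys = sorted(buckets)
    tables, stats_rows = [], []
    for key in keys:
        sites = buckets[key]
        mr = sum(s[1] for s in sites)
        cr = sum(s[2] for s in sites)
        mo = sum(s[3] for s in sites)
        co = sum(s[4] for s in sites)
        tables.append((mr, cr - mr, mo, co - mo))
        stats_rows.append((key, mr, cr, mo, co))
    p = _fisher_many(tables)
    q = benjamini_hochberg(p)

    qualifying = []
    for (key, mr, cr, mo, co), qi in zip(stats_rows, q):
        diff = 100.0 * (mr / cr - mo / co)
        if abs(diff) >= diff_min and qi <= q_candidate:
            qualifying.append((key, mr, cr, mo, co, qi, "hyper" if diff > 0 else "hypo"))

    # merge runs of adjacent qualifying same-direction windows
    dmrs = []
    run: list = []

    def flush(run):
        if not run:
            return
        chrom = run[0][0][0]
        start = run[0][0][1] * step
        end = run[-1][0][1] * step + window
        mr = sum(r[1] for r in run)
        cr = sum(r[2] for r in run)
        mo = sum(r[3] for r in run)
        co = sum(r[4] for r in run)
        mean_diff = 100.0 * (mr / cr - mo / co)
        q_best = min(r[5] for r in run)
        n_in = sum(
            1 for (c, pp) in dmc_keys if c == chrom and start <= pp < end
        )
        direction = run[0][6]
        tier = "candidate"
        if q_best <= q_significant and n_in >= min_dmcs and abs(mean_diff) >= diff_min:
            tier = "significant"
        dmrs.append(
            DMR(GenomicInterval(chrom, start, end, f"dmr_{chrom}_{start}"),
                mean_diff, q_best, n_in, direction, tier)
        )

    for item in qualifying:
        if run and item[0][0] == run[-1][0][0] and item[0][1] == run[-1][0][1] + 1 \
                and item[6] == run[-1][6]:
            run.append(item)
        else:
            flush(run)
            run = [item]
    flush(run)
    return dmrs


def cell_specific_subtraction(dmr_sets: dict, reference: str) -> CellSpecificDMRSet:
    """Cell-type-specific DMRs of ``reference`` by set deduction.

    A reference DMR survives iff it overlaps (>= 1 base) no DMR of any other
    cell in the mapping — the subtraction of the union of all other cells'
    DMR sets.  Removed DMRs record the first blocking cell (cells in sorted
    order).
    """
    if reference not in dmr_sets:
        raise KeyError(f"reference cell {reference!r} missing from DMR mapping")
    others = sorted(c for c in dmr_sets if c != reference)
    result = CellSpecificDMRSet(reference_cell=reference)
    for dmr in dmr_sets[reference]:
        iv = dmr.interval
        blocker = None
        for cell in others:
            for o in dmr_sets[cell]:
                if o.interval.chrom == iv.chrom and o.interval.start < iv.end \
                        and iv.start < o.interval.end:
                    blocker = cell
                    break
            if blocker:
                break
        if blocker is None:
            result.dmrs.append(dmr)
        else:
            result.removed.append((dmr, blocker))
    return result
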