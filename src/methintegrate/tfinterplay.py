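"""TF-methylation interplay: Beta background model of promoter methylation,
one-sample Kolmogorov-Smirnov tests per (cell type, TF) combination, BH
correction, and a tri-state classification.

The background aggregates CpG methylation proportions from all (cell, TF)
combinations' peak-covered promoter windows and fits a Beta distribution
(method of moments by default).  Each combination's own distribution is
then K-S-tested against that background CDF; combinations with adjusted
p <= alpha are *highly-differentiated*, tested ones above it
*lowly-differentiated*, and those with too few measured CpGs *null*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize

from . import intervals as iv
from .diffmeth import benjamini_hochberg
from .io import GenomicInterval, GeneModel, promoter_interval

__all__ = [
    "BackgroundModel",
    "TFMethylationCall",
    "promoter_windows",
    "extract_tf_methylation",
    "fit_background",
    "ks_test_against_background",
    "classify_interplay",
]


@dataclass(frozen=True)
class BackgroundModel:
    alpha: float
    beta: float
    n_points: int
    fit_method: str = "moments"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be > 0")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def cdf(self, x):
        return special.betainc(self.alpha, self.beta, np.clip(x, 0.0, 1.0))


@dataclass(frozen=True)
class TFMethylationCall:
    cell: str
    tf: str
    n_cpgs: int
    ks_statistic: float
    p_value: float
    adj_p: float
    klass: str  # highly-differentiated | lowly-differentiated | null


def promoter_windows(genes, halfwidth: int = 1000, chrom_sizes=None):
    """TSS +/- halfwidth windows, one per gene (clipped at chromosome edges)."""
    out = []
    for g in genes:
        size = None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        s, e = promoter_interval(g, halfwidth, size)
        if s < e:
            out.append(GenomicInterval(g.chrom, s, e, g.gene_id, g.strand))
    return out


def extract_tf_methylation(methylome, peaks, windows, min_coverage: int = 10) -> np.ndarray:
    """Methylation proportions of covered CpGs inside peak-overlapping windows.

    A promoter window counts as soon as any peak overlaps it by >= 1 base;
    all the window's qualifying CpGs are then included.
    """
    peaks_by: dict[str, list] = {}
    for p in peaks:
        peaks_by.setdefault(p.chrom, []).append((p.start, p.end))
    active = []
    for w in windows:
        chrom_peaks = peaks_by.get(w.chrom)
        if chrom_peaks and any(s < w.end and w.start < e for s, e in chrom_peaks):
            active.append(w)
    if not active:
        return np.empty(0)
    active_by: dict[str, np.ndarray] = {}
    for w in active:
        active_by.setdefault(w.chrom, []).append((w.start, w.end))
    active_by = {c: iv.as_set(v) for c, v in active_by.items()}
    values = []
    for r in methylome:
        if r.coverage < min_coverage or r.chrom not in active_by:
            continue
        if iv.positions_in(np.array([r.pos]), active_by[r.chrom])[0]:
            values.append(r.meth_count / r.coverage)
    return np.asarray(values)


def fit_background(
    all_proportions, method: str = "moments", epsilon: float = 1e-6, min_n: int = 100
) -> BackgroundModel:
    """Fit the Beta background to aggregated methylation proportions.

    Method of moments: with sample mean m and variance v,
    k = m(1-m)/v - 1, alpha = m k, beta = (1-m) k.  ``method="mle"``
    refines the moment fit by maximum likelihood.
    """
    x = np.clip(np.asarray(all_proportions, dtype=float), epsilon, 1.0 - epsilon)
    if len(x) < min_n:
        raise ValueError(f"need >= {min_n} values to fit the background, got {len(x)}")
    m = float(np.mean(x))
    v = float(np.var(x))
    if v >= m * (1.0 - m):
        raise ValueError(
            "sample variance exceeds Beta support (v >= m(1-m)); "
            "review clamping or use method='mle'"
        )
    k = m * (1.0 - m) / v - 1.0
    alpha, beta = m * k, (1.0 - m) * k
    if method == "moments":
        return BackgroundModel(alpha, beta, len(x), "moments")
    if method == "mle":
        def nll(theta):
            a, b = np.exp(theta)
            return -np.sum(stats.beta.logpdf(x, a, b))

        res = minimize(nll, np.log([alpha, beta]), method="Nelder-Mead")
        a, b = np.exp(res.x)
        return BackgroundModel(float(a), float(b), len(x), "mle")
    raise ValueError(f"unknown fit method {method!r}")


def ks_test_against_background(values, background: BackgroundModel,
                               epsilon: float = 1e-6):
    """One-sample K-S statistic and asymptotic p against the Beta background.

    D is the supremum over sample points of |ECDF - BetaCDF|, checking the
    gap on both sides of each jump; p comes from the asymptotic Kolmogorov
    distribution evaluated at sqrt(n) * D.
    """
    x = np.sort(np.clip(np.asarray(values, dtype=float), epsilon, 1.0 - epsilon))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    cdf = background.cdf(x)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d = float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))
    p = float(special.kolmogorov(np.sqrt(n) * d))
    return d, min(p, 1.0)


def classify_interplay(
    values_by_combo: dict,
    background: BackgroundModel,
    min_sites: int = 50,
    alpha: float = 0.05,
) -> list[TFMethylationCall]:
    """Classify every (cell, TF) combination against the background.

    Combinations with fewer than ``min_sites`` measured CpGs (or none at
    all) are *null*; the rest are K-S tested, BH-corrected across the tested
    combinations only, and split at adjusted p <= alpha.
    """
    combos = sorted(values_by_combo)
    tested, null_combos = [], []
    for key in combos:
        vals = np.asarray(values_by_combo[key], dtype=float) \
            if values_by_combo[key] is not None else np.empty(0)
        if len(vals) < min_sites:
            null_combos.append((key, len(vals)))
        else:
            tested.append((key, vals))
    raw = [ks_test_against_background(vals, background) for _, vals in tested]
    adj = benjamini_hochberg([p for _, p in raw]) if raw else []
    calls = []
    for (key, vals), (d, p), q in zip(tested, raw, adj):
        klass = "highly-differentiated" if q <= alpha else "lowly-differentiated"
        calls.append(TFMethylationCall(key[0], key[1], len(vals), d, p, float(q), klass))
    for key, n in null_combos:
        calls.append(TFMethylationCall(key[0], key[1], n, float("nan"), float("nan"),
                                       float("nan"), "null"))
    calls.sort(key=lambda c: (c.cell, c.tf))
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.cell, c.tf, c.n_cpgs, c.ks_statistic, c.p_value, c.adj_p, c.klass)
         for c in calls],
        columns=["cell", "tf", "n_cpgs", "D", "p", "adj_p", "class"],
    )


def class_grid(calls) -> pd.DataFrame:
    """Cells x TFs grid of class labels (the heat-map layout)."""
    df = calls_to_frame(calls)
    return df.pivot(index="cell", columns="tf", values="class")
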