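"""Platform-comparison analytics: KDE modality of methylation distributions
and Pearson correlation of methylation profiles (array vs RRBS per cell,
and RRBS pairwise across cells)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ModalityCall",
    "CorrelationMatrix",
    "InsufficientDataError",
    "kde_modality",
    "platform_correlation",
    "pairwise_cell_matrix",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ModalityCall:
    cell: str
    n_modes: int
    mode_locations: tuple
    bandwidth: float


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray   # Pearson r, NaN where a pair had < 3 shared sites
    n_shared: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def kde_modality(
    values,
    cell: str = "",
    bandwidth: float | None = None,
    prominence_min: float = 0.05,
    min_n: int = 100,
    grid_size: int = 512,
) -> ModalityCall:
    """Classify a methylation distribution as uni-/bi-/tri-/multi-modal.

    A Gaussian KDE (Silverman bandwidth unless overridden) is evaluated on a
    grid spanning [-0.05, 1.05] and truncated to [0, 1]; modes are local
    maxima whose prominence is at least ``prominence_min`` of the global
    peak height.  The slight over-span avoids spurious boundary modes at
    exactly 0 or 1.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < min_n:
        raise InsufficientDataError(f"need >= {min_n} values, got {len(x)}")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("methylation proportions must lie in [0, 1]")
    if np.std(x) == 0:
        raise InsufficientDataError("zero variance: KDE bandwidth undefined")
    kde = stats.gaussian_kde(x, bw_method=bandwidth if bandwidth is not None else "silverman")
    span = np.linspace(-0.05, 1.05, int(grid_size * 1.1 / 1.0))
    dens = kde(span)
    keep = (span >= 0.0) & (span <= 1.0)
    grid, dens = span[keep], dens[keep]
    peaks, _ = signal.find_peaks(dens, prominence=prominence_min * dens.max())
    # a maximum at the grid edge has no left/right neighbour for find_peaks;
    # treat a strictly decreasing/increasing boundary as a mode only if the
    # interior has none at all
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    locs = tuple(sorted(float(grid[i]) for i in peaks))
    return ModalityCall(cell=cell, n_modes=len(peaks), mode_locations=locs,
                        bandwidth=float(kde.factor * np.std(x)))


def platform_correlation(rrbs, probes, min_coverage: int = 10):
    """Pearson r between RRBS proportions and array betas on shared sites.

    RRBS sites must pass the coverage filter; the join is on exact
    (chrom, pos).  Returns ``(r, n_shared)``.
    """
    rec = {(r.chrom, r.pos): r.meth_count / r.coverage
           for r in rrbs if r.coverage >= min_coverage}
    pairs = [(rec[(p.chrom, p.pos)], p.beta) for p in probes if (p.chrom, p.pos) in rec]
    if len(pairs) < 3:
        raise InsufficientDataError(f"only {len(pairs)} shared sites; correlation undefined")
    a, b = np.array(pairs).T
    return float(stats.pearsonr(a, b)[0]), len(pairs)


def pairwise_cell_matrix(methylomes: dict, min_coverage: int = 10) -> CorrelationMatrix:
    """Symmetric Pearson-r matrix across cells' RRBS proportions.

    Each pair is correlated on the intersection of sites passing coverage in
    both; pairs with < 3 shared sites are flagged NaN rather than fabricated.
    """
    if len(methylomes) < 2:
        raise InsufficientDataError("need >= 2 cells")
    labels = sorted(methylomes)
    props = {
        cell: {(r.chrom, r.pos): r.meth_count / r.coverage
               for r in methylomes[cell] if r.coverage >= min_coverage}
        for cell in labels
    }
    k = len(labels)
    values = np.eye(k)
    n_shared = np.zeros((k, k), dtype=int)
    for i in range(k):
        n_shared[i, i] = len(props[labels[i]])
        for j in range(i + 1, k):
            shared = props[labels[i]].keys() & props[labels[j]].keys()
            n_shared[i, j] = n_shared[j, i] = len(shared)
            if len(shared) < 3:
                values[i, j] = values[j, i] = np.nan
                continue
            keys = sorted(shared)
            a = np.array([props[labels[i]][key] for key in keys])
            b = np.array([props[labels[j]][key] for key in keys])
            if np.std(a) == 0 or np.std(b) == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            r = float(stats.pearsonr(a, b)[0])
            values[i, j] = values[j, i] = r
    return CorrelationMatrix(labels=labels, values=values, n_shared=n_shared)
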