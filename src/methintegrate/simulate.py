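"""Synthetic multi-cell-type genomes, methylomes, expression tables and TF peak sets.

The generators emulate the statistical structure of an RRBS-centred
multi-omics compendium: a single CpG site catalogue shared across cell
types (RRBS enriches the same MspI fragments in every sample), per-CpG
coverage drawn from a negative binomial, methylated counts drawn
binomially around a latent per-site proportion, uni-/bi-/tri-modal
beta-mixture methylation landscapes, planted cell-type-specific
hyper/hypo DMRs with known direction, expression generated from the
linear methylation->expression model with known coefficients, and TF
peak sets whose promoter methylation comes either from the global
background or from a shifted beta.

Cross-cell dependence: each site carries one shared uniform quantile
that is pushed through every cell's own mixture quantile function
(a comonotone coupling).  Each cell keeps its specified marginal
modality, while cells with identical specs receive identical latent
proportions — so in the absence of planted DMRs the between-cell null
is exactly calibrated, which is what the downstream Fisher tests assume.

Every generator owns an RNG stream seeded by (master seed, stream name),
so adding one generator call never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .io import CpGRecord, GeneModel, GenomicInterval

__all__ = [
    "GenomeSpec",
    "MethylomeSpec",
    "PlantedDMR",
    "ExpressionTruth",
    "TFPeakSimResult",
    "GENOMIC_SEGMENTS",
    "simulate_gene_annotation",
    "simulate_methylomes",
    "simulate_expression",
    "simulate_tf_peaks",
]

GENOMIC_SEGMENTS = ("gene body", "intron", "promoter", "5'UTR", "3'UTR", "CDS")

_P_CLAMP = (0.01, 0.99)  # latent proportions kept off exact 0/1


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG stream derived from the master seed."""
    digest = np.frombuffer(name.encode(), dtype=np.uint8).astype(np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(seed), *digest.tolist()]))


@dataclass(frozen=True)
class GenomeSpec:
    """Miniature genome layout: chromosome sizes plus gene/CGI counts."""

    chrom_sizes: Mapping[str, int]
    n_genes: int = 50
    n_cgis: int = 40
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_sizes or any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if self.n_genes < 0 or self.n_cgis < 0:
            raise ValueError("n_genes and n_cgis must be >= 0")


@dataclass(frozen=True)
class MethylomeSpec:
    """Beta-mixture methylation landscape plus negative-binomial coverage."""

    modality: str = "bimodal"  # unimodal | bimodal | trimodal
    mixture_weights: tuple = (0.5, 0.5)
    component_params: tuple = ((2.0, 10.0), (10.0, 2.0))
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    min_coverage_floor: int = 1

    _MODALITY_K = {"unimodal": 1, "bimodal": 2, "trimodal": 3}

    def __post_init__(self):
        if self.modality not in self._MODALITY_K:
            raise ValueError(f"unknown modality {self.modality!r}")
        k = self._MODALITY_K[self.modality]
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != k or len(self.component_params) != k:
            raise ValueError(f"{self.modality} requires exactly {k} components")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1 (tol 1e-9)")
        if any(a <= 0 or b <= 0 for a, b in self.component_params):
            raise ValueError("beta shape parameters must be > 0")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be > 0")

    def mixture_ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the beta mixture (grid-interpolated)."""
        grid = np.linspace(0.0, 1.0, 4001)
        cdf = np.zeros_like(grid)
        for w, (a, b) in zip(self.mixture_weights, self.component_params):
            cdf += w * special.betainc(a, b, grid)
        # cdf is monotone on the grid; invert by interpolation
        return np.interp(u, cdf, grid)


@dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth cell-type-specific DMR planted into the methylomes."""

    chrom: str
    start: int
    end: int
    target_cell: str
    direction: str  # hyper | hypo
    effect_size: float
    n_cpgs: int = 8
    baseline: float | None = None  # default 0.2 (hyper) / 0.8 (hypo)

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper/hypo, got {self.direction!r}")
        if not (0.0 < self.effect_size <= 1.0):
            raise ValueError("effect_size must be in (0, 1]")
        if self.n_cpgs < 5:
            raise ValueError("n_cpgs must be >= 5 so the planted DMR is recoverable")
        if self.start >= self.end:
            raise ValueError("planted interval must satisfy start < end")

    @property
    def base_p(self) -> float:
        if self.baseline is not None:
            return self.baseline
        return 0.2 if self.direction == "hyper" else 0.8

    @property
    def shifted_p(self) -> float:
        p = self.base_p + (self.effect_size if self.direction == "hyper" else -self.effect_size)
        return float(np.clip(p, *_P_CLAMP))


def simulate_gene_annotation(genome: GenomeSpec):
    """Lay out non-overlapping gene models, CpG islands and a TSG subset.

    Returns ``(genes, cgis, tsg_ids)``.  Genes are two-exon coding models on
    alternating strands; CGIs are 300-800 bp islands, roughly half of them
    dropped near a TSS so the six-region partition is non-trivial.
    """
    rng = _stream(genome.seed, "annotation")
    genes: list[GeneModel] = []
    cgis: list[GenomicInterval] = []
    chroms = sorted(genome.chrom_sizes)
    sizes = genome.chrom_sizes
    # genes on a regular raster with jitter, so they never overlap
    slots = []
    for c in chroms:
        n_slots = max(1, sizes[c] // 12000)
        for k in range(n_slots):
            slots.append((c, 12000 * k))
    rng.shuffle(slots)
    for i in range(genome.n_genes):
        if i >= len(slots):
            break
        chrom, base = slots[i]
        span = int(rng.integers(4000, 9000))
        tx_start = base + 2000
        tx_end = min(tx_start + span, sizes[chrom] - 1)
        if tx_end - tx_start < 3000:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        exon1_end = tx_start + int(rng.integers(500, 1500))
        exon2_start = exon1_end + int(rng.integers(500, 1500))
        exon2_start = min(exon2_start, tx_end - 500)
        cds_start = tx_start + int(rng.integers(100, 400))
        cds_end = tx_end - int(rng.integers(100, 400))
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}", chrom=chrom, strand=strand,
                tx_start=tx_start, tx_end=tx_end,
                cds_start=cds_start, cds_end=cds_end,
                exon_starts=(tx_start, exon2_start),
                exon_ends=(exon1_end, tx_end),
            )
        )
    n_near_tss = genome.n_cgis // 2
    for j in range(genome.n_cgis):
        width = int(rng.integers(300, 800))
        if j < n_near_tss and genes:
            g = genes[int(rng.integers(len(genes)))]
            start = max(0, g.tss - int(rng.integers(0, 400)))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, max(1, sizes[chrom] - width)))
            g = None
        chrom = g.chrom if g is not None else chrom
        end = min(start + width, sizes[chrom])
        if end > start:
            cgis.append(GenomicInterval(chrom, start, end, f"cgi{j:04d}"))
    n_tsg = max(1, len(genes) // 4)
    tsg_ids = sorted(rng.choice([g.gene_id for g in genes], size=n_tsg, replace=False).tolist()) \
        if genes else []
    return genes, sorted(cgis), tsg_ids


def _validate_planted(genome: GenomeSpec, planted: Sequence[PlantedDMR]):
    for d in planted:
        if d.chrom not in genome.chrom_sizes:
            raise ValueError(f"planted DMR on unknown chromosome {d.chrom!r}")
        if d.start < 0 or d.end > genome.chrom_sizes[d.chrom]:
            raise ValueError(
                f"planted DMR {d.chrom}:{d.start}-{d.end} outside chromosome bounds"
            )


def simulate_methylomes(
    genome: GenomeSpec,
    per_cell_specs: Mapping[str, MethylomeSpec],
    planted: Sequence[PlantedDMR] = (),
    n_sites: int | None = None,
    dropout: float = 0.10,
    region_length: int = 1000,
    site_jitter: float = 0.02,
):
    """Simulate per-cell CpG record lists on a shared site catalogue.

    Methylation is regionally autocorrelated, as in real methylomes: the
    shared latent quantile is drawn once per ``region_length`` block and
    per-site jitter (``site_jitter`` on the quantile scale) perturbs it, so
    CpGs in the same window share their methylation state rather than
    scattering independently across the mixture's modes.

    Returns ``(methylomes, manifest)`` where ``methylomes`` maps cell name to a
    sorted list of :class:`CpGRecord` and ``manifest`` is a flat dict recording
    every planted DMR with its true direction and effect.
    """
    _validate_planted(genome, planted)
    if not per_cell_specs:
        raise ValueError("need at least one cell")
    rng = _stream(genome.seed, "methylome")
    chroms = sorted(genome.chrom_sizes)
    if n_sites is None:
        n_sites = sum(genome.chrom_sizes.values()) // 100

    # --- shared site catalogue -------------------------------------------
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(n_sites * lengths / lengths.sum()).astype(int))
    site_chrom, site_pos = [], []
    for c, n_c in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(genome.chrom_sizes[c], size=min(n_c, genome.chrom_sizes[c]),
                                 replace=False))
        site_chrom.extend([c] * len(pos))
        site_pos.append(pos)
    # guarantee each planted interval holds >= n_cpgs shared sites
    extra_by_chrom: dict[str, list[int]] = {}
    pos_by_chrom = {c: set(p.tolist()) for c, p in zip(chroms, site_pos)}
    for d in planted:
        have = sum(1 for p in pos_by_chrom[d.chrom] if d.start <= p < d.end)
        need = d.n_cpgs - have
        if need > 0:
            candidates = np.array(
                sorted(set(range(d.start, d.end)) - pos_by_chrom[d.chrom]), dtype=np.int64
            )
            if len(candidates) < need:
                raise ValueError(
                    f"planted DMR {d.chrom}:{d.start}-{d.end} too small for {d.n_cpgs} CpGs"
                )
            add = rng.choice(candidates, size=need, replace=False)
            pos_by_chrom[d.chrom].update(add.tolist())
            extra_by_chrom.setdefault(d.chrom, []).extend(add.tolist())
    chrom_arr, pos_arr = [], []
    for c in chroms:
        pos = np.array(sorted(pos_by_chrom[c]), dtype=np.int64)
        chrom_arr.extend([c] * len(pos))
        pos_arr.append(pos)
    chrom_arr = np.array(chrom_arr)
    pos_arr = np.concatenate(pos_arr) if pos_arr else np.empty(0, dtype=np.int64)
    n = len(pos_arr)

    # --- latent proportions ----------------------------------------------
    # shared quantile across cells (comonotone coupling), constant per
    # region block up to per-site jitter
    block_u: dict[tuple, float] = {}
    u = np.empty(n)
    for i in range(n):
        key = (chrom_arr[i], pos_arr[i] // region_length)
        if key not in block_u:
            block_u[key] = rng.random()
        u[i] = block_u[key]
    if site_jitter > 0:
        u = np.clip(u + rng.normal(0.0, site_jitter, size=n), 0.0, 1.0)
    planted_mask = {}
    for k, d in enumerate(planted):
        planted_mask[k] = (chrom_arr == d.chrom) & (pos_arr >= d.start) & (pos_arr < d.end)

    cells = sorted(per_cell_specs)
    methylomes: dict[str, list[CpGRecord]] = {}
    for cell in cells:
        spec = per_cell_specs[cell]
        cell_rng = _stream(genome.seed, f"methylome:{cell}")
        p = np.clip(spec.mixture_ppf(u), *_P_CLAMP)
        for k, d in enumerate(planted):
            mask = planted_mask[k]
            p[mask] = d.shifted_p if cell == d.target_cell else np.clip(d.base_p, *_P_CLAMP)
        nb_p = spec.coverage_dispersion / (spec.coverage_dispersion + spec.coverage_mean)
        coverage = cell_rng.negative_binomial(spec.coverage_dispersion, nb_p, size=n)
        coverage = np.maximum(coverage, spec.min_coverage_floor)
        meth = cell_rng.binomial(coverage, p)
        keep = cell_rng.random(n) >= dropout
        methylomes[cell] = [
            CpGRecord(str(chrom_arr[i]), int(pos_arr[i]), "+", int(coverage[i]), int(meth[i]))
            for i in np.flatnonzero(keep)
        ]

    manifest = {"n_sites": str(n), "n_planted": str(len(planted)), "seed": str(genome.seed)}
    for k, d in enumerate(planted):
        manifest[f"planted.{k}.interval"] = f"{d.chrom}:{d.start}-{d.end}"
        manifest[f"planted.{k}.target_cell"] = d.target_cell
        manifest[f"planted.{k}.direction"] = d.direction
        manifest[f"planted.{k}.effect_size"] = f"{d.effect_size:g}"
        manifest[f"planted.{k}.n_cpgs"] = str(int(planted_mask[k].sum()))
    return methylomes, manifest


@dataclass
class ExpressionTruth:
    """True coefficients and per-gene bookkeeping behind a simulated DGE table."""

    beta_methy: float
    beta_tsg: float
    beta_segment: Mapping[str, float]
    sigma: float
    gene_table: "object" = None  # pandas DataFrame filled by simulate_expression

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        unknown = set(self.beta_segment) - set(GENOMIC_SEGMENTS)
        if unknown:
            raise ValueError(f"unknown segment name(s): {sorted(unknown)}")


def simulate_expression(
    truth: ExpressionTruth,
    n_per_segment: Mapping[str, int],
    seed: int = 0,
    tsg_fraction: float = 0.2,
    hpro_effect: float = 0.0,
):
    """Generate a DESeq-style differential-expression table from the linear model.

    Each gene gets a signed methylation difference (percentage points), a TSG
    flag and one genomic segment; log2FC is the linear predictor
    ``Methy*b1 + TSG*b2 + b3[segment]`` plus Gaussian noise (plus an optional
    hyper/hypo intercept ``hpro_effect`` for model-comparison experiments).
    Residuals are recorded so the identity log2FC = predictor + residual is
    exact.  Returns ``(dge_table, truth)`` with ``truth.gene_table`` filled.
    """
    import pandas as pd

    unknown = set(n_per_segment) - set(GENOMIC_SEGMENTS)
    if unknown:
        raise ValueError(f"unknown segment name(s): {sorted(unknown)}")
    if any(v < 0 for v in n_per_segment.values()):
        raise ValueError("segment counts must be >= 0")
    rng = _stream(seed, "expression")
    rows = []
    idx = 0
    for segment in GENOMIC_SEGMENTS:
        for _ in range(int(n_per_segment.get(segment, 0))):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            methy = sign * rng.uniform(20.0, 80.0)
            tsg = bool(rng.random() < tsg_fraction)
            rows.append((f"gene{idx:05d}", methy, tsg, segment))
            idx += 1
    table = pd.DataFrame(rows, columns=["gene", "methy", "tsg", "segment"])
    n = len(table)
    predictor = (
        table["methy"].to_numpy() * truth.beta_methy
        + table["tsg"].to_numpy(dtype=float) * truth.beta_tsg
        + np.array([truth.beta_segment.get(s, 0.0) for s in table["segment"]])
        + hpro_effect * (table["methy"].to_numpy() > 0)
    )
    residual = rng.normal(0.0, truth.sigma, size=n) if truth.sigma > 0 else np.zeros(n)
    table["log2FC"] = predictor + residual
    table["residual"] = residual
    truth.gene_table = table
    # DESeq-style columns: emulate p-values from the standardized effect
    scale = max(truth.sigma, 1e-6)
    z = np.abs(table["log2FC"].to_numpy()) / scale
    pval = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(pval, method="fdr_bh")[1] if n else pval
    dge = pd.DataFrame(
        {"id": table["gene"], "log2FoldChange": table["log2FC"], "pval": pval, "padj": padj}
    )
    return dge, truth


@dataclass
class TFPeakSimResult:
    peaks: dict          # (cell, tf) -> list[GenomicInterval]; absent key = no data
    values: dict         # (cell, tf) -> np.ndarray of methylation proportions
    records: dict        # cell -> list[CpGRecord] covering that cell's peak windows
    truth: dict          # (cell, tf) -> "true-interplay" | "null-interplay" | "no-data"


def simulate_tf_peaks(
    promoters: Sequence[GenomicInterval],
    n_tfs: int,
    cells: Sequence[str] | int,
    fraction_shifted: float,
    shift_params: tuple = (1.0, 9.0),
    background_params: tuple = (2.0, 2.0),
    promoters_per_combo: int = 4,
    cpgs_per_window: int = 75,
    fraction_empty: float = 0.1,
    coverage_mean: float = 50.0,
    coverage_dispersion: float = 10.0,
    seed: int = 0,
) -> TFPeakSimResult:
    """Simulate per-(cell, TF) ChIP peak sets with known methylation interplay.

    Each combination either draws its peak-window CpG methylation from the
    global Beta background ("null-interplay") or from a shifted beta
    ("true-interplay"); a ``fraction_empty`` of combinations emits no peaks at
    all and is labelled "no-data".  Promoter windows are assigned to
    combinations without replacement within a cell, so each cell's CpG record
    list reproduces exactly the per-combination values when re-extracted.
    """
    if not (0.0 <= fraction_shifted <= 1.0):
        raise ValueError("fraction_shifted must be in [0, 1]")
    if not (0.0 <= fraction_empty <= 1.0):
        raise ValueError("fraction_empty must be in [0, 1]")
    if isinstance(cells, int):
        cells = [f"cell{i:02d}" for i in range(cells)]
    if len(promoters) < n_tfs * promoters_per_combo:
        raise ValueError(
            f"need >= n_tfs*promoters_per_combo = {n_tfs * promoters_per_combo} promoters, "
            f"got {len(promoters)}"
        )
    rng = _stream(seed, "tfpeaks")
    result = TFPeakSimResult({}, {}, {}, {})
    for cell in cells:
        order = rng.permutation(len(promoters))
        cursor = 0
        cell_records: list[CpGRecord] = []
        for t in range(n_tfs):
            tf = f"TF{t:03d}"
            if rng.random() < fraction_empty:
                result.truth[(cell, tf)] = "no-data"
                continue
            shifted = rng.random() < fraction_shifted
            a, b = shift_params if shifted else background_params
            result.truth[(cell, tf)] = "true-interplay" if shifted else "null-interplay"
            windows = [promoters[i] for i in order[cursor:cursor + promoters_per_combo]]
            cursor += promoters_per_combo
            peak_ivs, combo_values = [], []
            for w in windows:
                mid = (w.start + w.end) // 2
                half = max(50, (w.end - w.start) // 4)
                peak_ivs.append(
                    GenomicInterval(w.chrom, max(w.start, mid - half), min(w.end, mid + half),
                                    f"{cell}.{tf}")
                )
                n_cpg = min(cpgs_per_window, w.end - w.start)
                pos = np.sort(rng.choice(np.arange(w.start, w.end), size=n_cpg, replace=False))
                p = np.clip(rng.beta(a, b, size=n_cpg), *_P_CLAMP)
                nb_p = coverage_dispersion / (coverage_dispersion + coverage_mean)
                cov = np.maximum(rng.negative_binomial(coverage_dispersion, nb_p, size=n_cpg), 10)
                meth = rng.binomial(cov, p)
                combo_values.append(meth / cov)
                cell_records.extend(
                    CpGRecord(w.chrom, int(pos[i]), "+", int(cov[i]), int(meth[i]))
                    for i in range(n_cpg)
                )
            result.peaks[(cell, tf)] = peak_ivs
            result.values[(cell, tf)] = np.concatenate(combo_values)
        result.records[cell] = sorted(cell_records)
    return result
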