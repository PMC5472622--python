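"""End-to-end orchestration: stage runner over a flat key-value config.

Stages (in ``run_all`` order): simulate -> concordance -> dmc -> dmr ->
specific -> regions -> integrate -> tfinterplay.  Every stage writes its
artifacts plus a ``<stage>.report.txt`` (row counts, filters, seed) into
the output directory and never mutates another stage's outputs; ``run_all``
returns a manifest of every file with its checksum.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, concordance, diffmeth, io, regions, simulate, tfinterplay

logger = logging.getLogger(__name__)

STAGES = ("simulate", "concordance", "dmc", "dmr", "specific", "regions",
          "integrate", "tfinterplay")


@dataclass
class PipelineConfig:
    """All tunables, with the published thresholds as defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    reference_cell: str = "cellB"
    threads: int = 1                      # single-threaded contract
    # coverage / DMC / DMR thresholds
    min_coverage: int = 10
    dmc_diff_min: float = 25.0
    dmc_q_max: float = 0.01
    dmr_diff_min: float = 20.0
    dmr_q_candidate: float = 0.01
    dmr_q_significant: float = 0.001
    dmr_min_dmcs: int = 5
    dmr_window: int = 1000
    subtraction_tier: str = "significant"
    # region geometry
    shore_flank: int = 1000
    promoter_halfwidth: int = 1000
    # DGE filter
    dge_min_abs_lfc: float = 0.2
    dge_max_padj: float = 0.05
    # regression / MCMC
    mcmc_iterations: int = 10_000
    mcmc_burn_in: int = 1_000
    mcmc_preset: str = "test"             # "paper" switches to 500,000 / 1,000
    min_segment_n: int = 50
    # TF interplay
    ks_alpha: float = 0.05
    ks_min_sites: int = 50
    # synthetic-demo sizes
    sim_chrom_size: int = 400_000
    sim_n_cells: int = 4
    sim_n_sites: int = 4000
    sim_n_genes: int = 30
    sim_n_cgis: int = 24
    sim_n_planted: int = 6
    sim_effect_size: float = 0.5
    sim_coverage_mean: float = 40.0
    sim_planted_cpgs: int = 12
    sim_n_tfs: int = 5

    def __post_init__(self):
        if self.mcmc_preset == "paper":
            self.mcmc_iterations, self.mcmc_burn_in = 500_000, 1_000

    REQUIRED_THRESHOLDS = (
        "min_coverage", "dmc_diff_min", "dmc_q_max", "dmr_diff_min",
        "dmr_q_candidate", "dmr_q_significant", "dmr_min_dmcs",
        "dge_min_abs_lfc", "dge_max_padj", "ks_alpha",
    )

    def save(self, path):
        io.write_manifest(path, {f.name: getattr(self, f.name) for f in fields(self)})

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw = io.read_manifest(path)
        missing = [k for k in cls.REQUIRED_THRESHOLDS if k not in raw]
        if missing:
            raise ValueError(f"config missing required threshold key(s): {missing}")
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(val)
            elif f.type in ("float",):
                kwargs[f.name] = float(val)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _report(out: Path, stage: str, lines: dict):
    io.write_manifest(out / f"{stage}.report.txt", lines)


def _cells(config) -> list[str]:
    return [f"cell{chr(65 + i)}" for i in range(config.sim_n_cells)]


def _load_methylomes(out: Path, config) -> dict:
    meth = {}
    for cell in _cells(config):
        path = out / f"methylome.{cell}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stage input missing: {path} (run 'simulate' first)")
        meth[cell] = io.read_methylkit_tsv(path)
    return meth


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one stage; returns its report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fn = _STAGE_FUNCS.get(name)
    if fn is None:
        raise KeyError(f"unknown stage {name!r}; stages: {STAGES}")
    logger.info("stage=%s seed=%d starting", name, config.seed)
    report = fn(out, config)
    report = {"stage": name, "seed": config.seed, **report}
    _report(out, name, report)
    logger.info("stage=%s seed=%d done", name, config.seed)
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns a checksum manifest of all artifacts."""
    for name in STAGES:
        try:
            run_stage(name, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") from exc
    out = Path(config.out_dir)
    manifest = {p.name: _checksum(p) for p in sorted(out.iterdir()) if p.is_file()}
    io.write_manifest(out / "MANIFEST.txt", manifest)
    return manifest


# --------------------------------------------------------------------------
# stage implementations

def _stage_simulate(out: Path, config) -> dict:
    cells = _cells(config)
    genome = simulate.GenomeSpec(
        {"chr1": config.sim_chrom_size}, n_genes=config.sim_n_genes,
        n_cgis=config.sim_n_cgis, seed=config.seed,
    )
    genes, cgis, tsg_ids = simulate.simulate_gene_annotation(genome)
    rng = np.random.default_rng(config.seed)
    # one shared landscape: cell-type differences come only from planted DMRs
    specs = {cell: simulate.MethylomeSpec(coverage_mean=config.sim_coverage_mean,
                                          coverage_dispersion=5)
             for cell in cells}
    planted = []
    ref = config.reference_cell
    n_slots = config.sim_chrom_size // 2000
    slots = rng.choice(n_slots, size=min(config.sim_n_planted, n_slots), replace=False)
    for k, slot in enumerate(slots):
        start = int(slot) * 2000
        direction = "hyper" if k % 2 == 0 else "hypo"
        planted.append(simulate.PlantedDMR(
            "chr1", start, start + 1000, target_cell=ref, direction=direction,
            effect_size=config.sim_effect_size, n_cpgs=config.sim_planted_cpgs))
    meth, manifest = simulate.simulate_methylomes(
        genome, specs, planted, n_sites=config.sim_n_sites)
    for cell in cells:
        io.write_methylkit_tsv(out / f"methylome.{cell}.tsv", meth[cell])
    io.write_bed(out / "planted_dmrs.bed",
                 [io.GenomicInterval(p.chrom, p.start, p.end,
                                     f"{p.target_cell}:{p.direction}") for p in planted])
    io.write_refflat(out / "genes.refflat.tsv", genes)
    io.write_bed(out / "cgis.bed", cgis)
    (out / "tsg_list.tsv").write_text("".join(f"{t}\n" for t in tsg_ids))
    io.write_manifest(out / "ground_truth.txt", manifest)
    # expression from the linear model with known coefficients
    truth = simulate.ExpressionTruth(
        beta_methy=-0.01, beta_tsg=0.4,
        beta_segment={s: b for s, b in zip(simulate.GENOMIC_SEGMENTS,
                                           (0.1, 0.0, -0.3, 0.2, 0.05, -0.1))},
        sigma=0.5)
    dge, _ = simulate.simulate_expression(
        truth, {s: 120 for s in simulate.GENOMIC_SEGMENTS}, seed=config.seed)
    io.write_deseq_tsv(out / "dge.tsv", dge)
    truth.gene_table.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
    return {"n_cells": len(cells), "n_sites": manifest["n_sites"],
            "n_planted": manifest["n_planted"], "n_genes": len(genes)}


def _stage_concordance(out: Path, config) -> dict:
    meth = _load_methylomes(out, config)
    mat = concordance.pairwise_cell_matrix(meth, config.min_coverage)
    mat.to_frame().to_csv(out / "pairwise_correlation.tsv", sep="\t")
    calls = []
    for cell, recs in meth.items():
        vals = np.array([r.meth_count / r.coverage for r in recs
                         if r.coverage >= config.min_coverage])
        calls.append(concordance.kde_modality(vals, cell=cell))
    pd.DataFrame(
        [(c.cell, c.n_modes, ";".join(f"{m:.3f}" for m in c.mode_locations), c.bandwidth)
         for c in calls],
        columns=["cell", "n_modes", "mode_locations", "bandwidth"],
    ).to_csv(out / "modality.tsv", sep="\t", index=False)
    off = mat.values[~np.eye(len(mat.labels), dtype=bool)]
    return {"mean_pairwise_r": f"{np.nanmean(off):.4f}",
            "n_cells": len(mat.labels)}


def _stage_dmc(out: Path, config) -> dict:
    """Per-cell DMC sets, each cell called against the common baseline cell.

    The baseline is the first simulated cell; every other cell's DMC/DMR set
    is its comparison against that baseline, so that the set-deduction stage
    has one DMR set per cell type as the specificity equation expects.
    """
    meth = _load_methylomes(out, config)
    baseline = _cells(config)[0]
    n_total = 0
    for cell in meth:
        if cell == baseline:
            continue
        dmcs = diffmeth.call_dmcs(meth[cell], meth[baseline], config.min_coverage,
                                  config.dmc_diff_min, config.dmc_q_max)
        ivs = [io.GenomicInterval(d.chrom, d.pos, d.pos + 1, d.direction) for d in dmcs]
        io.write_bed(out / f"dmcs.{cell}.bed", ivs,
                     extra_cols=[(f"{d.meth_diff:.2f}", f"{d.p_value:.3e}",
                                  f"{d.q_value:.3e}") for d in dmcs])
        n_total += len(dmcs)
    return {"baseline": baseline, "n_dmcs_total": n_total}


def _stage_dmr(out: Path, config) -> dict:
    meth = _load_methylomes(out, config)
    baseline = _cells(config)[0]
    counts = {}
    for cell in meth:
        if cell == baseline:
            continue
        dmcs = diffmeth.call_dmcs(meth[cell], meth[baseline], config.min_coverage,
                                  config.dmc_diff_min, config.dmc_q_max)
        dmrs = diffmeth.call_dmrs(
            dmcs, meth[cell], meth[baseline], config.min_coverage,
            window=config.dmr_window, step=config.dmr_window,
            diff_min=config.dmr_diff_min, q_candidate=config.dmr_q_candidate,
            q_significant=config.dmr_q_significant, min_dmcs=config.dmr_min_dmcs)
        io.write_bed(out / f"dmrs.{cell}.bed",
                     [d.interval for d in dmrs],
                     extra_cols=[(f"{d.mean_diff:.2f}", f"{d.q_value:.3e}",
                                  d.n_dmcs, d.tier, d.direction) for d in dmrs])
        counts[cell] = len(dmrs)
    return {"baseline": baseline, **{f"n_dmrs_{c}": n for c, n in counts.items()}}


def _read_dmr_bed(path) -> list:
    dmrs = []
    for _ln, line in io._data_lines(path):
        f = line.split("\t")
        dmrs.append(diffmeth.DMR(
            io.GenomicInterval(f[0], int(f[1]), int(f[2]), f[3]),
            float(f[6]), float(f[7]), int(f[8]), f[10], f[9]))
    return dmrs


def _stage_specific(out: Path, config) -> dict:
    ref = config.reference_cell
    baseline = _cells(config)[0]
    if ref == baseline:
        raise ValueError("reference cell must differ from the baseline cell")
    dmr_sets = {}
    for cell in _cells(config):
        if cell == baseline:
            continue
        dmrs = _read_dmr_bed(out / f"dmrs.{cell}.bed")
        if config.subtraction_tier == "significant":
            dmrs = [d for d in dmrs if d.tier == "significant"]
        dmr_sets[cell] = dmrs
    result = diffmeth.cell_specific_subtraction(dmr_sets, ref)
    io.write_bed(out / f"specific_dmrs.{ref}.bed", [d.interval for d in result.dmrs],
                 extra_cols=[(f"{d.mean_diff:.2f}", f"{d.q_value:.3e}", d.n_dmcs,
                              d.tier, d.direction) for d in result.dmrs])
    with open(out / "specific_removed.tsv", "w") as fh:
        fh.write("dmr\tblocking_cell\n")
        for d, cell in result.removed:
            fh.write(f"{d.interval.name}\t{cell}\n")
    return {"reference": ref, "n_specific": len(result.dmrs),
            "n_removed": len(result.removed)}


def _stage_regions(out: Path, config) -> dict:
    genes = io.read_refflat(out / "genes.refflat.tsv")
    cgis = io.read_bed(out / "cgis.bed")
    part = regions.build_partition(cgis, genes, config.shore_flank,
                                   config.promoter_halfwidth)
    for name in regions.REGION_NAMES:
        io.write_bed(out / f"region.{name}.bed", part.intervals(name))
    meth = _load_methylomes(out, config)
    sites = [r for r in meth[config.reference_cell] if r.coverage >= config.min_coverage]
    _df, fractions = regions.assign_features(sites, cgis, genes, config.shore_flank,
                                             config.promoter_halfwidth)
    io.write_manifest(out / "feature_fractions.tsv",
                      {k: f"{v:.4f}" for k, v in fractions.items()})
    profiles = regions.region_methylation_profiles(sites, part)
    with open(out / "region_profiles.tsv", "w") as fh:
        fh.write("region\tn\t" + "\t".join(f"bin{i}" for i in range(20)) + "\n")
        for name, prof in profiles.items():
            fh.write(name + f"\t{prof['n']}\t"
                     + "\t".join(str(c) for c in prof["counts"]) + "\n")
    tsg_ids = io.read_gene_list(out / "tsg_list.tsv")
    dmrs = _read_dmr_bed(out / f"specific_dmrs.{config.reference_cell}.bed") \
        if (out / f"specific_dmrs.{config.reference_cell}.bed").exists() else []
    overlaps, counts = regions.overlap_tsg(dmrs, tsg_ids, genes,
                                           config.promoter_halfwidth)
    with open(out / "tsg_overlap.tsv", "w") as fh:
        fh.write("dmr\tgene\tsegment\tdirection\n")
        for r in overlaps:
            fh.write(f"{r.dmr_name}\t{r.gene_id}\t{r.segment}\t{r.direction}\n")
    return {"n_tsg_hyper": counts["hyper"], "n_tsg_hypo": counts["hypo"],
            **{k: f"{v:.3f}" for k, v in fractions.items()}}


def _stage_integrate(out: Path, config) -> dict:
    genes = io.read_refflat(out / "genes.refflat.tsv")
    dge = io.read_deseq_tsv(out / "dge.tsv")
    tsg_ids = io.read_gene_list(out / "tsg_list.tsv")
    truth = pd.read_csv(out / "expression_truth.tsv", sep="\t")
    # regression rows come from the simulated expression truth table, whose
    # Methy/segment assignments play the role of the DMR-gene annotation
    annotation = truth.rename(columns={"methy": "methy"})[["gene", "segment", "methy"]]
    tsg_rows = truth.loc[truth["tsg"], "gene"].tolist()
    base = bayes.build_design(annotation, dge, tsg_rows, min_n=config.min_segment_n)
    variant = bayes.build_design(annotation, dge, tsg_rows,
                                 min_n=config.min_segment_n, include_hpro=True)
    comparison = bayes.compare_models(
        {"base": base, "base+HPRO": variant},
        iterations=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
        seed=config.seed)
    draws = bayes.gibbs_fit(base, iterations=config.mcmc_iterations,
                            burn_in=config.mcmc_burn_in, seed=config.seed)
    bayes.summarize_posterior(draws).to_csv(out / "regression_fit.tsv",
                                            sep="\t", index=False)
    pd.DataFrame({
        "model": comparison.names,
        "log_marginal_likelihood": comparison.log_marginal_likelihoods,
        "selection_probability": comparison.selection_probabilities,
    }).to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    return {"n_rows": base.n, "selected_model": comparison.selected,
            "dropped_segments": ";".join(base.dropped_segments) or "none"}


def _stage_tfinterplay(out: Path, config) -> dict:
    genes = io.read_refflat(out / "genes.refflat.tsv")
    windows = tfinterplay.promoter_windows(genes, config.promoter_halfwidth)
    sim = simulate.simulate_tf_peaks(
        windows, n_tfs=config.sim_n_tfs, cells=_cells(config),
        fraction_shifted=0.15, shift_params=(1.0, 4.0), cpgs_per_window=25,
        promoters_per_combo=min(4, len(windows) // max(config.sim_n_tfs, 1)),
        seed=config.seed)
    for (cell, tf), peaks in sim.peaks.items():
        io.write_bed(out / f"peaks.{cell}.{tf}.bed", peaks)
    values = {}
    for (cell, tf) in sim.truth:
        if sim.truth[(cell, tf)] == "no-data":
            values[(cell, tf)] = np.empty(0)
            continue
        values[(cell, tf)] = tfinterplay.extract_tf_methylation(
            sim.records[cell], sim.peaks[(cell, tf)], windows, config.min_coverage)
    pooled = np.concatenate([v for v in values.values() if len(v)])
    background = tfinterplay.fit_background(pooled)
    calls = tfinterplay.classify_interplay(values, background,
                                           min_sites=config.ks_min_sites,
                                           alpha=config.ks_alpha)
    tfinterplay.calls_to_frame(calls).to_csv(out / "tf_interplay.tsv",
                                             sep="\t", index=False)
    tfinterplay.class_grid(calls).to_csv(out / "tf_interplay_grid.tsv", sep="\t")
    n_by = {k: sum(1 for c in calls if c.klass == k)
            for k in ("highly-differentiated", "lowly-differentiated", "null")}
    return {"background_alpha": f"{background.alpha:.3f}",
            "background_beta": f"{background.beta:.3f}", **n_by}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "concordance": _stage_concordance,
    "dmc": _stage_dmc,
    "dmr": _stage_dmr,
    "specific": _stage_specific,
    "regions": _stage_regions,
    "integrate": _stage_integrate,
    "tfinterplay": _stage_tfinterplay,
}
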