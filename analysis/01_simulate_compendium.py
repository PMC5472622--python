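#!/usr/bin/env python
"""Generate the synthetic multi-cell-type compendium every later step consumes.

Writes per-cell methylKit-style methylomes on a shared CpG catalogue (with
six DMRs planted for the reference cell), a refFlat gene table, CpG-island
BED, TSG list, a DESeq-style differential-expression table generated from
the linear methylation->expression model with known coefficients, and the
ground-truth manifest, all under results/pipeline/.
"""

import logging

from _common import CONFIG, announce

from methintegrate.pipeline import run_stage

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

report = run_stage("simulate", CONFIG)
announce(
    "simulated compendium",
    f"{report['n_cells']} cell types on {report['n_sites']} shared CpG sites; "
    f"{report['n_planted']} DMRs planted for {CONFIG.reference_cell}; "
    f"{report['n_genes']} gene models",
)
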