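#!/usr/bin/env python
"""Classify TF-methylation interplay per (cell type, TF) combination.

Aggregates promoter-window CpG methylation over all combinations, fits the
Beta background by moments, K-S-tests each combination against it, applies
BH correction and splits combinations into highly-differentiated /
lowly-differentiated / null. The long-format calls and the cells x TFs
class grid land under results/pipeline/.
"""

import logging

from _common import CONFIG, announce

from methintegrate.pipeline import run_stage

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

report = run_stage("tfinterplay", CONFIG)
announce(
    "TF-methylation interplay classification",
    f"background Beta(alpha={report['background_alpha']}, "
    f"beta={report['background_beta']}); "
    f"{report['highly-differentiated']} highly-differentiated, "
    f"{report['lowly-differentiated']} lowly-differentiated, "
    f"{report['null']} null combinations "
    "(grid in results/pipeline/tf_interplay_grid.tsv)",
)
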