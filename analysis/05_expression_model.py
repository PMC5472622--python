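#!/usr/bin/env python
"""Fit the Bayesian Gaussian regression of differential expression on
methylation, TSG status and genomic segment, and run the Bayes-factor
comparison against the variant model with the redundant hyper/hypo
indicator (HPRO).

Gibbs posterior summaries go to results/pipeline/regression_fit.tsv and the
model comparison (log marginal likelihoods + selection probabilities) to
results/pipeline/model_comparison.tsv.
"""

import logging

import pandas as pd
from _common import CONFIG, announce

from methintegrate.pipeline import run_stage

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

report = run_stage("integrate", CONFIG)
fit = pd.read_csv(f"{CONFIG.out_dir}/regression_fit.tsv", sep="\t")
cmp = pd.read_csv(f"{CONFIG.out_dir}/model_comparison.tsv", sep="\t")

announce(
    "posterior summaries (median [95% CI])",
    fit.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
)
announce(
    "Bayes-factor model selection",
    cmp.to_string(index=False, float_format=lambda v: f"{v: .4f}")
    + f"\nselected: {report['selected_model']} on {report['n_rows']} gene rows "
    f"(dropped segments: {report['dropped_segments']})",
)
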