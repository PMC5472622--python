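#!/usr/bin/env python
"""Partition the genome into the six CGI/shore/promoter regions, annotate the
reference methylome by genomic feature, and overlap the cell-type-specific
DMRs with tumor-suppressor gene segments.

Writes the six region BED files, feature fractions, per-region methylation
histograms and the DMR-TSG overlap table under results/pipeline/.
"""

import logging

from _common import CONFIG, announce

from methintegrate.pipeline import run_stage

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

report = run_stage("regions", CONFIG)
announce(
    "feature distribution of reference CpGs",
    f"promoter {report['promoter']}, exon {report['exon']}, intron "
    f"{report['intron']}, intergenic {report['intergenic']}; "
    f"CGI {report['CGI']}, shore {report['shore']}, open sea {report['open sea']}",
)
announce(
    "tumor-suppressor gene overlap of specific DMRs",
    f"{report['n_tsg_hyper']} TSGs hit by hyper DMRs, "
    f"{report['n_tsg_hypo']} by hypo DMRs "
    "(per-segment records in results/pipeline/tsg_overlap.tsv)",
)
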