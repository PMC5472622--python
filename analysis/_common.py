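"""Shared configuration for the numbered analysis drivers.

One pipeline output directory (results/pipeline) and one seed, so the
scripts can be run in order: 01 -> 02 -> ... -> 06.
"""

from pathlib import Path

from methintegrate.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = PipelineConfig(
    out_dir=str(RESULTS / "pipeline"),
    seed=1,
    mcmc_iterations=10_000,
    mcmc_burn_in=1_000,
)


def announce(title: str, finding: str) -> None:
    print(f"== {title} ==")
    print(finding)
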