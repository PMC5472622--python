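import numpy as np
import pytest

from methintegrate.io import CpGRecord, GeneModel, GenomicInterval


@pytest.fixture
def plus_gene():
    """Two-exon coding gene on the plus strand with hand-checkable segments."""
    return GeneModel(
        gene_id="gplus", chrom="chr1", strand="+",
        tx_start=1000, tx_end=9000, cds_start=2000, cds_end=8000,
        exon_starts=(1000, 5000), exon_ends=(3000, 9000),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gminus", chrom="chr1", strand="-",
        tx_start=1000, tx_end=9000, cds_start=2000, cds_end=8000,
        exon_starts=(1000, 5000), exon_ends=(3000, 9000),
    )


def make_methylome(props, coverage=20, chrom="chr1", start=100, spacing=50):
    """CpGRecords at evenly spaced positions with the given proportions."""
    return [
        CpGRecord(chrom, start + i * spacing, "+", coverage, int(round(p * coverage)))
        for i, p in enumerate(props)
    ]


@pytest.fixture
def toy_regression():
    """Tiny 1-predictor dataset with a proper prior, for marginal-likelihood work."""
    from methintegrate.bayes import PriorSpec, RegressionDataset

    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array([1.1, 1.9, 3.2, 3.9])
    data = RegressionDataset(X=X, y=y, coefficient_names=["b"],
                             gene_ids=["a", "b", "c", "d"])
    prior = PriorSpec(b0=0.0, B0=1.0, c0=2.0, d0=2.0)
    return data, prior
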