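import pandas as pd
import pytest

from mitoedit import EditingModel
from mitoedit.synthetic_data import (
    SimulationConfig,
    matr_like_model,
    matr_like_transcript,
    simulate_study,
)

TISSUES = ("N", "SR", "UR")


@pytest.fixture(scope="session")
def matr_model():
    """Minus-strand single-exon maturase gene anchored at the published
    genome coordinates (genome + transcript position = 340,037)."""
    return matr_like_model()


@pytest.fixture(scope="session")
def matr_transcript():
    return matr_like_transcript()


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 3 tissues x 3 replicates, 50 editing
    sites at mean depth 200, 8 germline SNPs."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def germline_keys(study):
    g = study.germline
    return set(zip(g["chrom"], g["pos"], g["alt"]))


@pytest.fixture(scope="session")
def editing_results(study, germline_keys):
    model = EditingModel(study.pileups, study.design, study.genes, germline=germline_keys)
    return model.fit()


def moment_matched_triple(mean: float, sd: float):
    """Three replicate values with exactly the given mean and sample SD."""
    return [mean - sd, mean, mean + sd]
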