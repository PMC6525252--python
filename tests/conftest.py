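import numpy as np
import pytest

from cosem.rate_model import SENSE_CODONS, CodonRateTable
from cosem.synthetic import make_benchmark, make_genes, make_rate_table


@pytest.fixture(scope="session")
def uniform_table():
    """All 61 sense codons at 22/s, accuracy 0.99."""
    return CodonRateTable(
        organism_label="uniform",
        rates={c: 22.0 for c in SENSE_CODONS},
        accuracies={c: 0.99 for c in SENSE_CODONS},
    )


@pytest.fixture(scope="session")
def random_table():
    return make_rate_table(42)


@pytest.fixture(scope="session")
def toy_genes():
    return make_genes(7, 6, (40, 80))


@pytest.fixture(scope="session")
def benchmark_small():
    """Small benchmark shared across the statistical tests."""
    return make_benchmark(11, n=300)


@pytest.fixture(scope="session")
def fitted_small(benchmark_small):
    from cosem.boosting import fit_expression_model

    model, r2, tr, te = fit_expression_model(
        benchmark_small.features, benchmark_small.y, seed=0, max_iter=150
    )
    return model, r2
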