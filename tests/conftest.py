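import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from netstrat.containers import ExpressionMatrix
from netstrat.synthetic import generate_clinical_cohort, generate_reference_cohort


@pytest.fixture(scope="session")
def small_reference():
    """Compact reference cohort: 60 samples, 300 genes, 2 planted modules."""
    return generate_reference_cohort(
        n_samples=60,
        n_genes=300,
        module_sizes=(60, 40),
        seed=11,
        response_module=1,
    )


@pytest.fixture(scope="session")
def default_reference():
    """Full-scale default reference (150 x 2000, five planted modules)."""
    return generate_reference_cohort(seed=7)


@pytest.fixture(scope="session")
def small_clinical(small_reference):
    _, truth = small_reference
    bx1, bx2, clinical = generate_clinical_cohort(truth, n_patients=13, seed=3)
    return bx1, bx2, clinical, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_expression(rng, n_genes=20, n_samples=12, prefix="g"):
    values = pd.DataFrame(
        rng.normal(5, 1, (n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values, scale="log2")
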