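import numpy as np
import pandas as pd
import pytest

from rccpsa.signature import build_signature_matrix, select_subtype_specific_genes
from rccpsa.synthetic import SimulationConfig, simulate_reference_profiles


@pytest.fixture(scope="session")
def training_cohort():
    """Labeled reference cohort with planted markers (45 samples, 1200 genes)."""
    cfg = SimulationConfig(n_genes=1200, k_specific=60, n_samples=45, seed=101)
    profiles, labels, truth = simulate_reference_profiles(cfg)
    return cfg, profiles, labels, truth


@pytest.fixture(scope="session")
def signature(training_cohort):
    """A 174-gene (58 per subtype) signature built from the training cohort."""
    _cfg, profiles, labels, _truth = training_cohort
    selected = select_subtype_specific_genes(profiles, labels)
    return build_signature_matrix(profiles, labels, selected, k=58)


@pytest.fixture()
def toy_expression():
    """9 genes × 15 samples, 5 per subtype; g1–g3/g4–g6/g7–g9 are 8-fold markers."""
    from rccpsa.expression import ExpressionMatrix

    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1, 10)]
    labels = ["ccRCC"] * 5 + ["pRCC"] * 5 + ["chRCC"] * 5
    samples = [f"s{i}" for i in range(15)]
    base = np.full((9, 15), 10.0) * rng.lognormal(0, 0.05, (9, 15))
    for block, subtype in enumerate(("ccRCC", "pRCC", "chRCC")):
        rows = np.arange(3 * block, 3 * block + 3)
        cols = np.flatnonzero([lab == subtype for lab in labels])
        base[np.ix_(rows, cols)] *= 8.0
    matrix = ExpressionMatrix(pd.DataFrame(base, index=genes, columns=samples))
    return matrix, pd.Series(labels, index=samples)
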