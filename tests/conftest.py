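import numpy as np
import pandas as pd
import pytest

import canalkit as ck


@pytest.fixture(scope="session")
def design_full():
    """The study layout: 6 human + 4 chimp lines over 4 days with replicates."""
    return ck.generate_design(6, 4, 4, seed=1)


@pytest.fixture(scope="session")
def small_study(design_full):
    """A small simulated study with variance-reduction ground truth."""
    params = ck.SimParams(n_genes=1200, f_human=0.5, f_chimp=0.3, shared_fraction=0.5)
    counts, truth = ck.simulate_counts(design_full, params, seed=2)
    return counts, truth, design_full


@pytest.fixture(scope="session")
def normalized_study(small_study):
    counts, truth, design = small_study
    expr = ck.log2_cpm(counts, ck.tmm_factors(counts).factors)
    combined, reduced = ck.combine_replicates(expr, design)
    return expr, combined, reduced, truth


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 400, size=(50, 4))
    counts[5, 1] *= 12
    return ck.CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(50)], columns=list("ABCD"))
    )
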