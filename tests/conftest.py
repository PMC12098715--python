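import numpy as np
import pandas as pd
import pytest

from frogclock.synthdata import (
    SynthConfig,
    generate_cohort,
    generate_context_fixtures,
    generate_methylation,
)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_tanks=10, frogs_per_tank=6, n_sites=400,
        frac_pos=0.1, frac_neg=0.1, frac_artifact=0.05, seed=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    samples = generate_cohort(small_config)
    matrix, truth = generate_methylation(samples, small_config)
    return samples, matrix, truth


@pytest.fixture(scope="session")
def small_context(small_config, small_cohort):
    _, matrix, truth = small_cohort
    return generate_context_fixtures(matrix, truth, small_config)


@pytest.fixture()
def toy_matrix():
    """A tiny hand-built matrix: 4 sites x 5 samples."""
    from frogclock.io_formats import MethylationMatrix

    rng = np.random.default_rng(0)
    beta = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(4, 5)),
        index=pd.Index([f"s{i}" for i in range(4)], name="site_id"),
        columns=[f"F{i}" for i in range(5)],
    )
    cov = pd.DataFrame(
        200, index=beta.index, columns=beta.columns
    )
    return MethylationMatrix(
        chrom=np.array(["chr1", "chr1", "chr2", "chr2"], dtype=object),
        pos=np.array([100, 500, 100, 900]),
        beta=beta,
        coverage=cov,
    )
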