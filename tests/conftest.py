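import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tme_profiler.cohort_io import ExpressionMatrix
from tme_profiler.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("tme_profiler").setLevel(logging.ERROR)


def small_config(**overrides) -> GeneratorConfig:
    defaults = dict(
        n_per_group={"PCM": 40, "MBM": 30, "ECM": 40},
        n_genes=400,
        seed=11,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced three-group cohort with all default planted effects."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort: 350 PCM + 94 MBM + 870 ECM."""
    return generate_cohort(GeneratorConfig(seed=20))


@pytest.fixture()
def random_expr():
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{j}" for j in range(8)]
    return ExpressionMatrix(
        pd.DataFrame(rng.lognormal(3, 1, size=(10, 8)), index=genes, columns=samples)
    )
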