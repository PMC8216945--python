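import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msytools import simdata

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """A compact mixed-origin scaffold pool with one X-homologous Y scaffold."""
    spec = simdata.GenomeSpec(
        n_auto_scaffolds=3,
        n_x_scaffolds=2,
        n_y_scaffolds=3,
        scaffold_len_range=(3_000, 5_000),
        xy_homology_fraction=0.5,
        xy_identity=0.99,
        seed=42,
    )
    return simdata.make_genome(spec)


@pytest.fixture(scope="session")
def plain_genome():
    """A pool without any X-homologous block."""
    spec = simdata.GenomeSpec(
        n_auto_scaffolds=3,
        n_x_scaffolds=2,
        n_y_scaffolds=2,
        scaffold_len_range=(2_000, 3_000),
        seed=7,
    )
    return simdata.make_genome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
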