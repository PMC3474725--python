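import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_parents():
    """Equal-length parent operons at 10% divergence, desk scale (~2 kb)."""
    from sipmosaic import synthetic_community as synth

    return synth.generate_parent_pair(
        synth.scaled_gene_layout(0.2), per_gene_divergence=0.1, seed=11
    )


@pytest.fixture(scope="session")
def small_mosaic(small_parents):
    from sipmosaic import synthetic_community as synth

    pa, pb = small_parents
    n = len(pa)
    plan = synth.MosaicPlan(
        (("A", n // 3), ("B", n // 3), ("A", n - 2 * (n // 3))),
        novel_rate=0.005,
        seed=12,
    )
    mosaic, truth = synth.generate_mosaic((pa, pb), plan)
    return mosaic, truth, plan
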