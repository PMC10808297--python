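import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microfoodweb.io import AnnotatedNematodeTable, CommunityTable, annotate_nematodes
from microfoodweb.traits import packaged_traits

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trait_db():
    return packaged_traits()


@pytest.fixture(scope="session")
def annotated_factory(trait_db):
    """Factory: genus → per-sample counts mapping → AnnotatedNematodeTable.

    Scalar values are treated as a single-sample community.
    """

    def make(counts, samples=None) -> AnnotatedNematodeTable:
        counts = {
            g: ([v] if np.isscalar(v) else list(v)) for g, v in counts.items()
        }
        n = len(next(iter(counts.values())))
        index = samples or [f"S{i + 1}" for i in range(n)]
        table = CommunityTable(pd.DataFrame(counts, index=index, dtype=float))
        return annotate_nematodes(table, trait_db)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)
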