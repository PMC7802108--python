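import hypothesis
import pytest

import stainscore as ss

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def worked_records():
    return ss.worked_example_fixture()


@pytest.fixture(scope="session")
def worked_query():
    return ss.parse_query("PRSS1, PNLIP CELA3A\nPRL")


@pytest.fixture(scope="session")
def small_atlas():
    """Uniform single-class atlas, small enough for brute-force oracles."""
    spec = ss.uniform_atlas_spec(
        seed=42, n_tissues=6, cells_per_tissue=2, n_genes=40, coverage=0.7
    )
    return ss.generate_atlas(spec)


@pytest.fixture(scope="session")
def hetero_atlas():
    """The default two-class heterogeneous atlas (permutation-study conditions)."""
    return ss.generate_atlas(ss.heterogeneous_atlas_spec(seed=11))
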