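import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deltatrimax import ExpressionTensor

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_tensor(values: np.ndarray, mask=None) -> ExpressionTensor:
    """Wrap a raw array in a labelled tensor for tests."""
    G, C, T = values.shape
    return ExpressionTensor(
        values=values,
        gene_ids=tuple(f"g{i}" for i in range(G)),
        sample_ids=tuple(f"s{j}" for j in range(C)),
        time_labels=tuple(float(k) for k in range(T)),
        missing_mask=mask,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tensor_factory():
    return make_tensor
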