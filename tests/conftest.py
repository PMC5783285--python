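import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from irappa.decoyset_io import CapriCategory, DecoySet
from irappa.synthetic import SyntheticSpec, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


CAT = {
    "i": CapriCategory.INCORRECT,
    "a": CapriCategory.ACCEPTABLE,
    "m": CapriCategory.MEDIUM,
    "h": CapriCategory.HIGH,
}


def make_decoyset(features, labels, complex_id="cx", initial_ranks=None, **kw):
    """Hand-build a DecoySet from a feature matrix and short label codes."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    if initial_ranks is None:
        initial_ranks = np.arange(1, n + 1)
    return DecoySet(
        complex_id=complex_id,
        decoy_ids=[f"{complex_id}_d{i}" for i in range(n)],
        features=features,
        labels=[CAT[code] for code in labels],
        initial_ranks=np.asarray(initial_ranks),
        **kw,
    )


@pytest.fixture
def decoyset_factory():
    return make_decoyset


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Six 40-decoy synthetic complexes with coordinates (session-cached)."""
    spec = SyntheticSpec(n_complexes=6, decoys_per_complex=40, noise_sigma=0.05, seed=42)
    return generate(spec)
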