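import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from raecg.synthetic import SyntheticSpec, make_synthetic_record, write_fixture

MIX = {"N": 0.70, "S": 0.10, "V": 0.15, "F": 0.05}


@pytest.fixture(scope="session")
def mixed_record():
    """A 60-beat synthetic record containing all four classes."""
    return make_synthetic_record(
        SyntheticSpec(n_beats=60, class_mix=MIX, seed=11, record_id="synmix"))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, mixed_record):
    """The mixed record written as WFDB files on disk."""
    d = tmp_path_factory.mktemp("wfdb")
    write_fixture(mixed_record, d / mixed_record.record_id)
    return d


@pytest.fixture(scope="session")
def separable_images():
    """200 trivially separable images: each class lights its own quadrant."""
    rng = np.random.default_rng(7)
    n = 200
    X = np.zeros((n, 3, 32, 32), dtype=np.float32)
    y = np.array(["N", "S", "V", "F"] * (n // 4))
    corner = {"N": (4, 4), "S": (4, 20), "V": (20, 4), "F": (20, 20)}
    for i, c in enumerate(y):
        r0, c0 = corner[c]
        X[i, :, r0 : r0 + 8, c0 : c0 + 8] = 1.0
    X += rng.normal(0.0, 0.05, X.shape).astype(np.float32)
    return X, y
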