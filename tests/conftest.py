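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


@pytest.fixture(scope="session")
def db():
    from msimet.annotation import load_compound_db

    return load_compound_db()


@pytest.fixture(scope="session")
def rules():
    from msimet.annotation import load_fragmentation_rules

    return load_fragmentation_rules()


def make_sample(mz, intensity, pixel_index=None, n_pixels=None, sample_id="S1",
                group="control", age=40.0):
    """Small flat-array sample for unit tests (grid nx x 1)."""
    from msimet.dataset import Sample

    mz = np.asarray(mz, float)
    if pixel_index is None:
        pixel_index = np.zeros(len(mz), int)
    pixel_index = np.asarray(pixel_index, int)
    n_px = n_pixels if n_pixels is not None else int(pixel_index.max()) + 1
    coords = np.array([(x, 0) for x in range(n_px)])
    return Sample(
        sample_id=sample_id,
        group=group,
        age=age,
        shape=(n_px, 1),
        coords=coords,
        mz=mz,
        intensity=np.asarray(intensity, float),
        pixel_index=pixel_index,
    )
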