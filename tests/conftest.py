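import numpy as np
import pytest

from phmrikit.simulate import make_atlas
from phmrikit.types import Bold4D


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(shape=(12, 12, 4), n_regions=4)


def bold_from_series(series, tr=1.0, subject_id="s1", group="g"):
    """Wrap a (..., t) array (or a single 1D series) as a Bold4D volume."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, None, None, :]
    while arr.ndim < 4:
        arr = arr[None]
    return Bold4D(arr, tr, subject_id, group)
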