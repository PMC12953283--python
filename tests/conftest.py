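import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from rtctqa.landmark_engine import LabelMap
from rtctqa.sop_registry import default_registry

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def label_ids():
    from rtctqa.synthetic_data import LABEL_IDS

    return LABEL_IDS


def make_label_map(slice_spans, slice_thickness=3.0, n_xy=8, z0=0.0):
    """Tiny label map: ``slice_spans`` maps structure -> (k_first, k_last).

    Slice ``k`` has its centre at ``z0 + k * slice_thickness``; structures
    fill a small in-plane square.
    """
    n_z = 1 + max(hi for _, hi in slice_spans.values())
    grid = np.zeros((n_xy, n_xy, n_z), dtype=np.int16)
    names = {}
    for i, (name, (lo, hi)) in enumerate(sorted(slice_spans.items()), start=1):
        grid[2:6, 2:6, lo : hi + 1] = i
        names[i] = name
    affine = np.diag([2.0, 2.0, slice_thickness, 1.0])
    affine[2, 3] = z0
    return LabelMap(grid=grid, affine=affine, label_names=names)


@pytest.fixture
def label_map_factory():
    return make_label_map
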