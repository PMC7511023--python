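import numpy as np
import pytest

from alveomorph import (
    FieldCounts,
    FieldImage,
    RoiSet,
    build_test_system,
)


@pytest.fixture(scope="session")
def ts():
    """The default test system: 8+8 lines, 64 points, d = 104 um."""
    return build_test_system()


@pytest.fixture()
def empty_rois():
    return RoiSet()


@pytest.fixture()
def uniform_field():
    def make(value: int, source_id: str = "uniform") -> FieldImage:
        return FieldImage(
            pixels=np.full((680, 680), value, dtype=np.uint8),
            source_id=source_id,
        )

    return make


def make_counts(p_ref=64, p_sep=0, i=0, p_nonpar=None):
    """Shorthand FieldCounts builder for stereology tests."""
    if p_nonpar is None:
        p_nonpar = 64 - p_ref
    return FieldCounts(
        p_nonpar=p_nonpar, p_ref=p_ref, p_sep=p_sep, i_h=i, i_v=0
    )
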