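import numpy as np
import pytest

from petradiomics import PhantomSpec, make_tumor_phantom, segment_fixed_threshold
from petradiomics.quantize import QuantizedROI


@pytest.fixture
def make_q():
    """Factory wrapping a raw level array (0 = unmasked) as a QuantizedROI."""

    def _make(levels, Ng=None, bin_width=1.0):
        levels = np.asarray(levels, dtype=np.int64)
        if levels.ndim < 3:
            levels = levels.reshape((1,) * (3 - levels.ndim) + levels.shape)
        mask = levels > 0
        if Ng is None:
            Ng = int(levels.max())
        return QuantizedROI(
            levels=levels, mask=mask, Ng=Ng, bin_width=bin_width,
            range_min=0.0, range_max=Ng * bin_width,
        )

    return _make


@pytest.fixture
def q_1x1x4(make_q):
    """The canonical tiny ROI: collinear levels 1,1,2,2."""
    return make_q([1, 1, 2, 2], Ng=2)


@pytest.fixture(scope="session")
def hetero_case():
    """A heterogeneous spherical phantom with its segmentation."""
    spec = PhantomSpec(
        semi_axes=(25.0, 25.0, 25.0), base_suv=8.0, heterogeneity_sd=0.4, seed=7
    )
    vol, gt = make_tumor_phantom(spec)
    seg = segment_fixed_threshold(vol)
    return spec, vol, gt, seg


@pytest.fixture(scope="session")
def constant_case():
    """A constant-uptake (heterogeneity 0) phantom with its segmentation."""
    spec = PhantomSpec(
        semi_axes=(20.0, 20.0, 20.0), base_suv=8.0, heterogeneity_sd=0.0, seed=1
    )
    vol, gt = make_tumor_phantom(spec)
    seg = segment_fixed_threshold(vol)
    return spec, vol, gt, seg
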