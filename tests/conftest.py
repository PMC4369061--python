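import numpy as np
import pytest

from phenoshoot import segmentation as seg
from phenoshoot import synthetic as syn


@pytest.fixture(scope="session")
def default_params() -> seg.SegmentationParams:
    return seg.SegmentationParams()


@pytest.fixture(scope="session")
def noiseless_render() -> syn.ViewRender:
    """One noiseless plant view with exact ground truth."""
    return syn.make_plant_views(syn.PlantSpec(seed=3, noise_sd=0.0))["top"]


@pytest.fixture(scope="session")
def erasure_fixture() -> tuple[syn.ViewRender, np.ndarray]:
    """Plant view with one whole 1-px tendril chromatically erased."""
    render = syn.make_plant_views(
        syn.PlantSpec(seed=3, tendril_width_px=1, noise_sd=0.0)
    )["top"]
    return syn.erase_tendril_hue(render)
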