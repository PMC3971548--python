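import numpy as np
import pytest

import infarctseg as iseg


@pytest.fixture(scope="session")
def default_bundle():
    """The standard four-blob phantom (one per screening decision)."""
    return iseg.generate_phantom(iseg.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def normalized_triple(default_bundle):
    """Phantom volumes min-max normalized the way scanner data would be."""
    dwi = iseg.normalize_intensity(default_bundle.dwi)
    adc = iseg.normalize_intensity(default_bundle.adc)
    return dwi, adc, default_bundle.mask


@pytest.fixture(scope="session")
def segresult(normalized_triple):
    """One full pipeline run on the default phantom, shared across tests."""
    dwi, adc, mask = normalized_triple
    return iseg.segment_infarct(dwi, adc, mask, iseg.PipelineConfig(seed=1))


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return iseg.NormalizedVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return iseg.BrainMask(data=np.asarray(data), spacing=spacing)
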