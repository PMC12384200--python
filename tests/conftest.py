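import numpy as np
import pytest

from dsca import FlowParams, OpticalProperties, SemiInfiniteGeometry


@pytest.fixture(scope="session")
def tissue_optics() -> OpticalProperties:
    """Typical tissue-mimicking optics: 785 nm, mua=0.01/mm, musp=1/mm, n=1.33."""
    return OpticalProperties.typical_tissue()


@pytest.fixture(scope="session")
def geom20(tissue_optics) -> SemiInfiniteGeometry:
    """Semi-infinite geometry at 20 mm source-detector separation."""
    return SemiInfiniteGeometry.for_separation(20.0, tissue_optics)


@pytest.fixture(scope="session")
def brownian_flow() -> FlowParams:
    return FlowParams(alpha_db=1e-6, beta=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250926)
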