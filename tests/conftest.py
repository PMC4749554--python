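import numpy as np
import pytest

from migmode import synthetic
from migmode.config import AnalysisConfig


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rendered_movie():
    """Small rendered single-cell movie with prescribed event areas."""
    gen = np.random.default_rng(5)
    protrusion_px = gen.integers(0, 12, size=29)
    retraction_px = gen.integers(0, 12, size=29)
    movies = synthetic.render_mask_movie(protrusion_px, retraction_px, seed=5)
    return movies, protrusion_px, retraction_px
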