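import numpy as np
import pytest

from castream import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def textured_image(rng):
    """Smooth textured image for registration fixtures (no sharp aliasing)."""
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.random((128, 128)), 3.0)
    img = (img - img.min()) / (img.max() - img.min())
    return 200.0 + 800.0 * img


@pytest.fixture(scope="session")
def mini_session(tmp_path_factory):
    """Small rendered session (8 cells, 96x96, 40 s) shared across tests."""
    out = tmp_path_factory.mktemp("mini_session")
    cfg = synthetic.SyntheticConfig(
        height=96, width=96, n_cells=8, duration_s=40.0,
        min_center_spacing_px=16.0,
    )
    paths = synthetic.write_fixture_bundle(cfg, seed=7, out_dir=out)
    return cfg, paths
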