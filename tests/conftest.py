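import numpy as np
import pytest

from dabdepth import BlobSpec, LabelMask, SkinPhantomConfig, generate_phantom


def make_flat_mask(
    n_rows=60, n_cols=40, outside=10, squamous=5, epidermis=20, pixel_size_um=1.0
) -> LabelMask:
    """Horizontal-band label mask: outside / squamous / epidermis / dermis."""
    labels = np.zeros((n_rows, n_cols), dtype=np.uint8)
    r0 = outside
    labels[r0 : r0 + squamous] = 1
    labels[r0 + squamous : r0 + squamous + epidermis] = 2
    labels[r0 + squamous + epidermis :] = 3
    return LabelMask(labels, pixel_size_um)


@pytest.fixture
def flat_mask():
    return make_flat_mask()


@pytest.fixture(scope="session")
def small_phantom():
    """300×300 µm flat-band phantom with 12 planted blobs (shared, read-only)."""
    cfg = SkinPhantomConfig(
        width_um=300.0, height_um=300.0,
        blobs=BlobSpec(count=12, depth_distribution=("uniform", 0.15, 0.85)),
        noise_sd=5.0, seed=11,
    )
    return cfg, *generate_phantom(cfg)
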