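import numpy as np
import pytest

from epimorph import MonolayerParams, generate_monolayer


@pytest.fixture(scope="session")
def small_monolayer():
    """Compact field: 110 cells in 384 px, cheap enough for many tests."""
    params = MonolayerParams(n_cells=110, field_size=384, seed=7)
    return generate_monolayer(params)


@pytest.fixture(scope="session")
def clean_monolayer():
    """Noise-free field for generator/oracle equivalence checks."""
    from epimorph import MarkParams

    params = MonolayerParams(
        n_cells=110, field_size=384, seed=19, pixel_noise_frac=0.0,
        dapi_level_sd=0.1,
        marks={"H3K27me3": MarkParams(slope=-0.3, noise_sd=0.0,
                                      radial_coupling=0.0)})
    return generate_monolayer(params)


def disk_mask(radius: int, size: int | None = None) -> np.ndarray:
    size = size or (2 * radius + 21)
    c = size // 2
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius ** 2
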