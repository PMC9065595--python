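import numpy as np
import pytest

from veinfem.image import LabelImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cylinder_mask(radius_mm: float, length_mm: float, vs: float = 0.33,
                       tilt: float = 0.0) -> LabelImage:
    """Rasterised finite cylinder (flat caps) along z, optional x-tilt."""
    n_xy = int((2 * radius_mm + 4 * vs + length_mm * abs(tilt)) / vs) + 8
    n_z = int((length_mm + 6 * vs) / vs) + 8
    ax = [np.arange(n) * vs for n in (n_xy, n_xy, n_z)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    c = ((n_xy // 2) * vs, (n_xy // 2) * vs)
    mask = (
        ((x - (c[0] + tilt * (z - 2 * vs))) ** 2 + (y - c[1]) ** 2) <= radius_mm**2
    ) & (z >= 2 * vs) & (z <= 2 * vs + length_mm)
    return LabelImage(mask.astype(np.int32), np.diag([vs, vs, vs, 1.0]), {1: "vein"})


@pytest.fixture
def cylinder_mask():
    return make_cylinder_mask


@pytest.fixture
def small_head():
    """Tiny nested-box head: scalp/skull/csf/brain with hemispheres."""
    vox = np.zeros((14, 14, 14), dtype=np.int32)
    vox[1:13, 1:13, 1:13] = 1          # scalp
    vox[2:12, 2:12, 2:12] = 2          # skull
    vox[3:11, 3:11, 3:11] = 3          # csf
    vox[4:10, 4:10, 4:10] = 4          # grey left
    vox[7:10, 4:10, 4:10] = 5          # grey right
    vox[6:8, 4:10, 4:10] = 3           # falx corridor
    table = {1: "scalp", 2: "skull", 3: "csf",
             4: "grey matter left hemisphere", 5: "grey matter right hemisphere"}
    return LabelImage(vox, np.eye(4), table)
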