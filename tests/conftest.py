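import numpy as np
import pytest

from aawall.contour_ops import Contour
from aawall.volume import MaskVolume


def circle_contour(r=10.0, center=(0.0, 0.0), n=256, slice_index=0, z=0.0):
    """Equally spaced polygonal circle starting at angle 0 (max +x)."""
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([center[0] + r * np.cos(theta),
                           center[1] + r * np.sin(theta)])
    return Contour(pts, slice_index=slice_index, z=z)


@pytest.fixture
def disk_mask():
    """64x64 binary disk of radius 20 px, 1 mm pixels."""
    Y, X = np.mgrid[0:64, 0:64]
    m = ((X + 0.5 - 32.0) ** 2 + (Y + 0.5 - 32.0) ** 2 <= 20.0 ** 2)
    return m.astype(np.uint8)


def mask_volume(arr, pixel_size=(1.0, 1.0), slice_spacing=1.0):
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[None]
    return MaskVolume(a, pixel_size=pixel_size, slice_spacing=slice_spacing)
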