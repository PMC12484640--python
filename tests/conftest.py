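import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from condquant import synthetic as syn


@pytest.fixture
def centered_spec():
    """A clean default scene: sigma 3 punctum at the image centre, no noise."""
    return syn.PunctumSpec(
        center_xy=(32.0, 32.0), z_index=4, sigma_px=3.0,
        amplitude_gfp=100.0, amplitude_mch=50.0,
        background_gfp=10.0, background_mch=10.0,
        noise_sd=0.0, image_shape=(9, 64, 64), seed=0,
    )


def quantize(scene):
    """Apply the 16-bit TIFF quantization the I/O layer performs on export.

    The analysis consumes acquired images, which are integer-valued; the
    radius rule in particular relies on the flat quantized background.
    """
    scene.gfp = np.clip(np.rint(scene.gfp), 0, 65535)
    scene.mch = np.clip(np.rint(scene.mch), 0, 65535)
    return scene
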