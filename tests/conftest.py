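import numpy as np
import pytest

import fundusseg as fs


@pytest.fixture(scope="session")
def tiny_cfg():
    return fs.ModelConfig.tiny()


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return fs.build_model(tiny_cfg, seed=42)


def make_phantom_set(n=8, size=64, seed0=100):
    """Small disc-centred phantoms rendered directly at the network input size."""
    imgs, masks = [], []
    for i in range(n):
        spec = fs.PhantomSpec(
            image_size=size,
            disc_radii=(14 + 2 * (i % 3), 12 + 1.5 * (i % 4)),
            cup_to_disc_ratio=0.4 + 0.05 * (i % 8),
            vessel_count=3, vessel_width=1.5, disc_center_jitter=6,
            seed=seed0 + i,
        )
        img, mask, _ = fs.generate_phantom(spec)
        imgs.append(img)
        masks.append(mask)
    return fs.SegmentationDataset(np.stack(imgs), np.stack(masks))


@pytest.fixture(scope="session")
def phantom_set_64():
    return make_phantom_set()
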