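import numpy as np
import pytest

import chromaderm as cd


@pytest.fixture(scope="session")
def tawny_system():
    return cd.VisualSystem.tawny_dragon()


@pytest.fixture(scope="session")
def scene_532():
    """Throat scene with exact 50/30/20 gray/orange/yellow construction."""
    return cd.generate_throat_image(
        cd.SceneSpec(proportions=(0.5, 0.3, 0.2), seed=11))


@pytest.fixture(scope="session")
def small_micrograph():
    """A compact labeled micrograph (fast to generate, full structure)."""
    return cd.generate_micrograph(cd.MicrographSpec(
        width_um=30.0, height_um=20.0, n_melanophores=2, seed=7))


def random_label_mask(seed, h=100, w=120, pixel_size_um=0.2):
    """An unstructured random label mask for brute-force oracle checks."""
    rng = np.random.default_rng(seed)
    from chromaderm.tem_morphometrics import DEFAULT_CLASS_MAP
    codes = list(DEFAULT_CLASS_MAP.values())
    labels = rng.choice(codes[1:], size=(h, w)).astype(np.uint8)  # no background
    boundary = np.full(w, 3, dtype=int)
    labels[:3, :] = DEFAULT_CLASS_MAP["epidermis"]
    return cd.LabeledMicrograph(labels=labels, pixel_size_um=pixel_size_um,
                                epidermis_boundary=boundary)
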