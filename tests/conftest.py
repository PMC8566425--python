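import numpy as np
import pytest

from mammilieu.simulate.scene import SceneSpec, generate_scene
from mammilieu.stains import load_stain_registry


@pytest.fixture(scope="session")
def registry():
    return load_stain_registry()


@pytest.fixture(scope="session")
def mixed_scene():
    """One moderately sized triple-panel scene with all classes planted,
    plus nucleus-free CD68 speckles and sub-15-um debris."""
    spec = SceneSpec(
        image_size_px=(1024, 1024),
        eer_fraction=0.9,
        pe_fraction_of_eer=0.3,
        planted_density={
            ("T", "PE"): 400.0,
            ("T", "ILS"): 259.0,
            ("B", "ILS"): 120.0,
            ("Mac", "PE"): 313.0,
            ("Mac", "ILS"): 101.0,
        },
        cd68_speckle_fraction=0.2,
        debris_per_mm2=30.0,
        seed=11,
    )
    rgb, truth = generate_scene(spec)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def training_scenes():
    """Small scenes for segmenter training/evaluation."""
    out = []
    for s in range(4):
        spec = SceneSpec(
            image_size_px=(448, 448),
            eer_fraction=0.55,
            pe_fraction_of_eer=0.35,
            seed=200 + s,
        )
        out.append(generate_scene(spec))
    return out
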