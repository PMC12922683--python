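import numpy as np
import pytest

from cytoplex.core import ImagePlane
from cytoplex.synthetic import CellClassSpec, TissueSimConfig, generate_tissue_image


@pytest.fixture(scope="session")
def two_class_scene():
    """Small noisy scene with two somatic classes of very different levels."""
    cfg = TissueSimConfig(
        cell_classes=[
            CellClassSpec("neuron", "NEURON_M", "somatic", 100.0, 50),
            CellClassSpec("microglia", "MG_M", "somatic", 5.0, 50),
        ],
        image_size_px=(512, 512),
        nucleus_area_um2_range=(20.0, 60.0),
        seed=3,
    )
    stack, gt, masks = generate_tissue_image(cfg)
    return cfg, stack, gt, masks


def plane(arr, pixel_size_um=0.5, name="test"):
    return ImagePlane(np.asarray(arr, dtype=float), pixel_size_um, name=name)
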