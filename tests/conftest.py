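import numpy as np
import pytest

from icebg.geometry import DetectorGeometry, PolarGrid, pixel_overlap_fractions
from icebg.simulate import scaled_preset, simulate_stack


@pytest.fixture(scope="session")
def geom64():
    """Small centred test geometry (64² pixels)."""
    return DetectorGeometry(
        n_slow=64, n_fast=64, pixel_size=0.2, distance=50.0,
        beam_centre=(32.5, 32.5), wavelength=1.0,
    )


@pytest.fixture(scope="session")
def overlap64(geom64):
    """Default polar overlap fractions for the 64² geometry."""
    return pixel_overlap_fractions(geom64)


@pytest.fixture(scope="session")
def diffuse_small():
    """A small diffuse-ring simulation: 128² pixels, 20 images, seeded.

    At this scale the 0.1 Å cubic-ice ring is ~1.5 px wide, comfortably
    resolvable by the default 1 px radial binning.
    """
    cfg = scaled_preset("diffuse", size=128, n_images=20, seed=3)
    return cfg, simulate_stack(cfg)
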