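import numpy as np
import pytest

from srhkit import PhantomSpec, archetype_spec, generate_phantom, tile_phantom


@pytest.fixture(scope="session")
def meningioma_phantom():
    """One mid-size meningioma phantom shared across read-only tests."""
    spec = archetype_spec("meningioma", seed=11, image_size=300)
    mosaic, truth = generate_phantom(spec)
    return spec, mosaic, truth


@pytest.fixture(scope="session")
def uniform_vignetted_tiles():
    """Nine tiles cut from a structure-free specimen under radial vignetting."""
    spec = PhantomSpec(
        archetype="generic",
        seed=3,
        image_size=522,
        nuclear_density=0,
        matrix_protein=5.0,
        matrix_lipid=2.0,
        illumination="radial",
        vignette_strength=0.3,
    )
    mosaic, truth = generate_phantom(spec)
    manifest, tiles = tile_phantom(mosaic, truth, tile_fov_um=180, overlap_fraction=0.05)
    assert len(tiles) == 9
    return spec, truth, tiles


def make_tile(pixels, row=0, col=0, stage_x=0.0, stage_y=0.0, pixel_size=1.0):
    from srhkit import SRSTile

    pixels = np.asarray(pixels, dtype=float)
    side = pixels.shape[1]
    return SRSTile(pixels, row, col, stage_x, stage_y, pixel_size, pixel_size * side)
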