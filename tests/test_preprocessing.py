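import copy

import numpy as np
import pytest

from srhkit import (
    StitchConfig,
    apply_flat_field,
    estimate_flat_field,
    generate_phantom,
    stitch_tiles,
    tile_phantom,
    archetype_spec,
)
from srhkit.errors import DegenerateFieldError, StitchError
from srhkit.phantom import radial_gain
from tests.conftest import make_tile


class TestFlatFieldEstimation:
    def test_constant_tiles_give_unit_gain(self):
        tiles = [make_tile(np.full((2, 32, 32), 3.7), col=i, stage_x=32.0 * i)
                 for i in range(4)]
        ff = estimate_flat_field(tiles)
        np.testing.assert_allclose(ff.gain, 1.0, atol=1e-9)

    def test_single_tile_is_smoothed_self(self):
        rng = np.random.default_rng(0)
        tile = make_tile(rng.uniform(1, 2, (2, 32, 32)))
        ff = estimate_flat_field([tile], smoothing_scale=4)
        assert ff.gain.shape == (2, 32, 32)
        np.testing.assert_allclose(ff.gain.reshape(2, -1).mean(axis=1), 1.0, atol=1e-9)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="at least one tile"):
            estimate_flat_field([])

    def test_all_zero_channel_is_degenerate(self):
        tiles = [make_tile(np.zeros((2, 16, 16)))]
        with pytest.raises(DegenerateFieldError):
            estimate_flat_field(tiles)

    def test_recovers_injected_radial_gain_within_1pct(self, uniform_vignetted_tiles):
        spec, truth, tiles = uniform_vignetted_tiles
        ff = estimate_flat_field(tiles)
        target = truth.injected_gain / truth.injected_gain.mean()
        for ch in range(2):
            rms = np.sqrt(np.mean((ff.gain[ch] - target) ** 2))
            assert rms < 0.01, f"channel {ch}: gain RMS error {rms:.4f}"

    def test_idempotence(self, uniform_vignetted_tiles):
        _, _, tiles = uniform_vignetted_tiles
        ff1 = estimate_flat_field(tiles)
        once = [apply_flat_field(t, ff1) for t in tiles]
        ff2 = estimate_flat_field(once)
        twice = [apply_flat_field(t, ff2) for t in once]
        for a, b in zip(once, twice):
            change = np.sqrt(np.mean((a.pixels - b.pixels) ** 2)) \
                / np.sqrt(np.mean(a.pixels ** 2))
            assert change < 1e-3


class TestFlatFieldApplication:
    def test_unit_gain_is_identity(self):
        tile = make_tile(np.random.default_rng(0).uniform(0, 5, (2, 16, 16)))
        ff = estimate_flat_field([make_tile(np.full((2, 16, 16), 2.0))])
        out = apply_flat_field(tile, ff)
        np.testing.assert_array_equal(out.pixels, tile.pixels)

    def test_division_recovers_uniform_content(self):
        g = radial_gain((64, 64), 0.4)
        gain = np.stack([g, g])
        c = 7.0
        tile = make_tile(gain * c)
        from srhkit import FlatField

        ff = FlatField(gain=gain / g.mean())
        out = apply_flat_field(tile, ff)
        np.testing.assert_allclose(out.pixels, c * g.mean(), rtol=1e-6)

    def test_zero_tile_stays_zero(self):
        from srhkit import FlatField

        tile = make_tile(np.zeros((2, 8, 8)))
        ff = FlatField(gain=np.ones((2, 8, 8)))
        assert apply_flat_field(tile, ff).pixels.sum() == 0

    def test_dimension_mismatch_rejected(self):
        from srhkit import FlatField

        tile = make_tile(np.ones((2, 8, 8)))
        ff = FlatField(gain=np.ones((2, 16, 16)))
        with pytest.raises(ValueError, match="does not match"):
            apply_flat_field(tile, ff)


def _cut_phantom(seed=2, size=300, tile_fov=150, overlap=0.1):
    spec = archetype_spec("meningioma", seed=seed, image_size=size)
    mosaic, truth = generate_phantom(spec)
    manifest, tiles = tile_phantom(mosaic, truth, tile_fov_um=tile_fov,
                                   overlap_fraction=overlap)
    return mosaic, tiles


class TestStitching:
    def test_single_tile_identity(self):
        tile = make_tile(np.random.default_rng(0).uniform(0, 5, (2, 32, 32)))
        mosaic = stitch_tiles([tile], StitchConfig(registration="positions_only"))
        np.testing.assert_array_equal(mosaic.pixels, tile.pixels)

    def test_cut_and_reassemble_bit_exact_overwrite(self):
        mosaic, tiles = _cut_phantom()
        rec = stitch_tiles(tiles, StitchConfig(overlap_fraction=0.1,
                                               registration="positions_only",
                                               blend="overwrite"))
        assert rec.shape == mosaic.shape
        np.testing.assert_array_equal(rec.pixels, mosaic.pixels)

    def test_cut_and_reassemble_feather_within_tolerance(self):
        mosaic, tiles = _cut_phantom()
        rec = stitch_tiles(tiles, StitchConfig(overlap_fraction=0.1,
                                               registration="positions_only",
                                               blend="feather"))
        rms = np.sqrt(np.mean((rec.pixels - mosaic.pixels) ** 2)) \
            / np.sqrt(np.mean(mosaic.pixels ** 2))
        assert rms < 0.005

    def test_phase_refinement_recovers_injected_shift(self):
        mosaic, tiles = _cut_phantom()
        tiles = [copy.deepcopy(t) for t in tiles]
        victim = next(t for t in tiles if (t.row_index, t.col_index) == (1, 1))
        victim.stage_x += 5 * mosaic.pixel_size   # tile recorded 5 px too far right
        victim.stage_y += -3 * mosaic.pixel_size  # and 3 px too far up
        rec = stitch_tiles(tiles, StitchConfig(overlap_fraction=0.1,
                                               registration="phase_refine",
                                               blend="overwrite"))
        placements = {(p["row"], p["col"]): p for p in rec.provenance["placements"]}
        assert placements[(1, 1)]["shift"] == [3, -5]
        assert all(p["shift"] == [0, 0] for k, p in placements.items() if k != (1, 1))
        np.testing.assert_allclose(rec.pixels, mosaic.pixels, atol=1e-6)

    def test_excessive_shift_falls_back_with_warning(self):
        mosaic, tiles = _cut_phantom()
        tiles = [copy.deepcopy(t) for t in tiles]
        victim = next(t for t in tiles if (t.row_index, t.col_index) == (1, 1))
        victim.stage_x += 40 * mosaic.pixel_size  # far beyond max_shift
        with pytest.warns(UserWarning, match="falling back"):
            rec = stitch_tiles(tiles, StitchConfig(overlap_fraction=0.1,
                                                   registration="phase_refine",
                                                   max_shift=3,
                                                   blend="overwrite"))
        assert rec.provenance["placements"] is not None

    def test_missing_grid_cell_reported(self):
        _, tiles = _cut_phantom()
        partial = [t for t in tiles if (t.row_index, t.col_index) != (0, 1)]
        with pytest.raises(StitchError, match=r"\(0, 1\)"):
            stitch_tiles(partial, StitchConfig(registration="positions_only"))

    def test_channels_get_identical_transform(self):
        mosaic, tiles = _cut_phantom()
        rec = stitch_tiles(tiles, StitchConfig(overlap_fraction=0.1,
                                               registration="phase_refine",
                                               blend="overwrite"))
        side = tiles[0].shape[0]
        for t, p in zip(sorted(tiles, key=lambda t: (t.row_index, t.col_index)),
                        rec.provenance["placements"]):
            y, x = p["y"], p["x"]
            crop = rec.pixels[:, y:y + side, x:x + side]
            # overwrite blending: the last-placed tile is verbatim on both channels
            if (t.row_index, t.col_index) == (1, 1):
                np.testing.assert_array_equal(crop, t.pixels)


class TestStitchConfig:
    def test_overlap_range_enforced(self):
        with pytest.raises(ValueError):
            StitchConfig(overlap_fraction=0.6)

    def test_unknown_modes_rejected(self):
        with pytest.raises(ValueError):
            StitchConfig(registration="homography")
        with pytest.raises(ValueError):
            StitchConfig(blend="pyramid")
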