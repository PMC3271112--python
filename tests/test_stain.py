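"""Stain normalization, optical density and color deconvolution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hemorph.stain import (
    DegenerateReferenceError,
    ODImage,
    RGBTile,
    StainBasis,
    deconvolve,
    normalize_stain,
    rgb_to_od,
)


def _random_tile(rng, shape=(40, 40)):
    return RGBTile(pixels=rng.integers(0, 256, size=(*shape, 3), dtype=np.uint8))


class TestNormalizeStain:
    def test_self_reference_is_fixed_point(self, rng):
        tile = _random_tile(rng)
        out = normalize_stain(tile, tile)
        np.testing.assert_array_equal(out.pixels, tile.pixels)

    def test_shifted_tile_recovers_reference_quantiles(self, rng):
        # keep values <= 200 so the +37 shift does not saturate (saturation
        # collapses the top quantiles and no monotone map can undo it)
        ref = RGBTile(pixels=rng.integers(0, 201, size=(64, 64, 3), dtype=np.uint8))
        shifted = RGBTile(
            pixels=np.clip(ref.pixels.astype(int) + 37, 0, 255).astype(np.uint8)
        )
        out = normalize_stain(shifted, ref)
        qs = np.linspace(0, 1, 21)
        for c in range(3):
            got = np.quantile(out.pixels[..., c], qs)
            want = np.quantile(ref.pixels[..., c], qs)
            assert np.abs(got - want).max() <= 1.0

    def test_point_mass_maps_to_reference_minimum(self, rng):
        ref = _random_tile(rng)
        zeros = RGBTile(pixels=np.zeros((8, 8, 3), dtype=np.uint8))
        out = normalize_stain(zeros, ref)
        for c in range(3):
            assert (out.pixels[..., c] == ref.pixels[..., c].min()).all()

    def test_idempotent_within_one_gray_level(self, rng):
        tile = _random_tile(rng, shape=(64, 64))
        ref = _random_tile(np.random.default_rng(1), shape=(64, 64))
        once = normalize_stain(tile, ref)
        twice = normalize_stain(once, ref)
        dev = np.abs(once.pixels.astype(int) - twice.pixels.astype(int))
        assert dev.max() <= 1

    def test_constant_reference_channel_rejected(self, rng):
        tile = _random_tile(rng)
        ref_px = _random_tile(rng).pixels.copy()
        ref_px[..., 1] = 128
        with pytest.raises(DegenerateReferenceError):
            normalize_stain(tile, RGBTile(pixels=ref_px))


class TestRGBToOD:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (255, 0.0),  # blank bright field
            (26, np.log10(255 / 26)),
            (0, np.log10(255.0)),  # the max(I, 1) floor
        ],
    )
    def test_pointwise_values(self, value, expected):
        tile = RGBTile(pixels=np.full((2, 2, 3), value, dtype=np.uint8))
        od = rgb_to_od(tile, background_intensity=255.0)
        np.testing.assert_allclose(od.od, expected, atol=1e-12)

    def test_od_25_5_gray_levels_is_one(self):
        # I0/I = 10 gives exactly one OD unit
        tile = RGBTile(pixels=np.full((1, 1, 3), 25, dtype=np.uint8))
        od = rgb_to_od(tile, background_intensity=250.0)
        np.testing.assert_allclose(od.od, 1.0)

    @given(
        pixels=hnp.arrays(
            np.uint8, (6, 6, 3), elements=st.integers(min_value=0, max_value=255)
        )
    )
    def test_antitone_in_intensity(self, pixels):
        """Brighter pixels never have larger optical density."""
        od = rgb_to_od(RGBTile(pixels=pixels)).od
        flat_i = pixels.ravel().astype(float)
        flat_od = od.ravel()
        order = np.argsort(flat_i, kind="stable")
        assert (np.diff(flat_od[order]) <= 1e-12).all()

    def test_rejects_nonpositive_background(self):
        tile = RGBTile(pixels=np.zeros((1, 1, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            rgb_to_od(tile, background_intensity=0.0)


class TestDeconvolve:
    def test_zero_od_gives_zero_concentrations(self, basis):
        od = ODImage(od=np.zeros((4, 4, 3)))
        ch = deconvolve(od, basis)
        assert not ch.hematoxylin.any() and not ch.eosin.any() and not ch.residual.any()

    def test_basis_vector_recovers_unit_concentration(self, basis):
        od_arr = np.zeros((1, 1, 3))
        od_arr[0, 0] = basis.vectors[:, 0]  # pure hematoxylin at unit strength
        ch = deconvolve(ODImage(od=od_arr), basis)
        np.testing.assert_allclose(ch.hematoxylin[0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(ch.eosin[0, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(ch.residual[0, 0], 0.0, atol=1e-12)

    def test_round_trip_on_random_concentrations(self, basis, rng):
        """basis @ c then deconvolve recovers c to 1e-9 (1000 triples)."""
        c = rng.uniform(0, 2, size=(1000, 1, 3))
        od_arr = np.einsum("ij,hwj->hwi", basis.vectors, c)
        # the residual basis vector has negative components; zero the
        # residual concentration wherever it would push OD negative
        bad = od_arr.min(axis=-1) < 0
        c[bad, 2] = 0.0
        od_arr = np.einsum("ij,hwj->hwi", basis.vectors, c)
        od = ODImage(od=od_arr)
        ch = deconvolve(od, basis)
        np.testing.assert_allclose(ch.raw, c, atol=1e-9)
        recon = ch.reconstruct_od(basis)
        np.testing.assert_allclose(recon, od.od, atol=1e-9)

    def test_negative_concentrations_clipped_but_raw_kept(self, basis):
        # an OD vector opposite to hematoxylin yields a negative raw value
        od_arr = -0.2 * basis.vectors[:, 0] + 0.5 * basis.vectors[:, 1]
        od_arr = np.clip(od_arr, 0, None).reshape(1, 1, 3)
        ch = deconvolve(ODImage(od=od_arr), basis)
        assert ch.hematoxylin.min() >= 0
        assert ch.raw.min() < ch.hematoxylin.min() + 1e-12


class TestStainBasis:
    def test_default_columns_unit_norm_and_invertible(self, basis):
        norms = np.linalg.norm(basis.vectors, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert np.isfinite(np.linalg.cond(basis.vectors))

    def test_rejects_singular_matrix(self):
        v = np.ones((3, 3)) / np.sqrt(3)
        with pytest.raises(ValueError):
            StainBasis(vectors=v)

    def test_json_round_trip(self, basis):
        again = StainBasis.from_list(basis.to_list())
        np.testing.assert_allclose(again.vectors, basis.vectors)
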