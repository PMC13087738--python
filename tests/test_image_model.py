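"""Orthogonal reslicing, geometric transforms, contrast, LUTs and zoom."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from termstack import (
    AUTO,
    BoundsError,
    ConfigurationError,
    FixtureSpec,
    MultiDimImage,
    ViewState,
    apply_lut,
    auto_contrast_limits,
    available_colormaps,
    make_hyperstack,
    make_lut,
    normalize,
    orthoslice,
    render_pipeline,
    transform_slice,
    zoom,
)

from oracles import normalize_bruteforce


class TestOrthoslice:
    def test_xz_index_bookkeeping(self, coord_volume):
        """In a volume with value 100z + 10y + x, the XZ slice at y=1 must
        read 100r + 10 + c at character cell (r, c)."""
        view = ViewState(plane="XZ", plane_index=1)
        s = orthoslice(coord_volume, view)
        z, x = np.indices(s.shape)
        assert np.array_equal(s, (100 * z + 10 + x).astype(np.uint16))

    def test_yz_index_bookkeeping(self, coord_volume):
        view = ViewState(plane="YZ", plane_index=2)
        s = orthoslice(coord_volume, view)
        z, y = np.indices(s.shape)
        assert np.array_equal(s, (100 * z + 10 * y + 2).astype(np.uint16))

    def test_xy_identity_on_single_plane(self):
        img = make_hyperstack(FixtureSpec(shape=(1, 1, 1, 3, 4), pattern="random"))
        s = orthoslice(img, ViewState(plane="XY", plane_index=0))
        assert np.array_equal(s, img.data[0, 0, 0])

    def test_cross_plane_consistency(self, rng):
        """orthoslice(XZ, y)[z, x] == orthoslice(XY, z)[y, x] for all z, y, x."""
        data = rng.integers(0, 256, size=(1, 1, 5, 6, 7)).astype(np.uint8)
        img = MultiDimImage(data)
        for z in range(5):
            xy = orthoslice(img, ViewState(plane="XY", plane_index=z))
            for y in range(6):
                xz = orthoslice(img, ViewState(plane="XZ", plane_index=y))
                assert np.array_equal(xz[z, :], xy[y, :])
            for x in range(7):
                yz = orthoslice(img, ViewState(plane="YZ", plane_index=x))
                assert np.array_equal(yz[z, :], xy[:, x])

    @pytest.mark.parametrize(
        "view,axis",
        [
            (ViewState(plane="XY", plane_index=9), "Z"),
            (ViewState(plane="XZ", plane_index=9), "Y"),
            (ViewState(plane="YZ", plane_index=9), "X"),
            (ViewState(t_index=5), "T"),
            (ViewState(c_index=5), "C"),
        ],
    )
    def test_out_of_bounds_names_axis(self, small_volume, view, axis):
        with pytest.raises(BoundsError, match=axis):
            orthoslice(small_volume, view)


class TestTransformSlice:
    @pytest.fixture
    def raster(self):
        return np.arange(6, dtype=np.uint8).reshape(2, 3)

    def test_identity(self, raster):
        assert np.array_equal(transform_slice(raster), raster)

    def test_group_laws(self, raster):
        # flips are involutions
        twice = transform_slice(transform_slice(raster, flip_h=True), flip_h=True)
        assert np.array_equal(twice, raster)
        twice = transform_slice(transform_slice(raster, flip_v=True), flip_v=True)
        assert np.array_equal(twice, raster)
        # four quarter turns are the identity
        out = raster
        for _ in range(4):
            out = transform_slice(out, rotation_quarter_turns=1)
        assert np.array_equal(out, raster)

    def test_half_turn_equals_both_flips(self, raster):
        assert np.array_equal(
            transform_slice(raster, rotation_quarter_turns=2),
            transform_slice(raster, flip_h=True, flip_v=True),
        )

    def test_clockwise_quarter_turn(self):
        s = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        # clockwise: first column becomes last row reversed upward
        assert np.array_equal(
            transform_slice(s, rotation_quarter_turns=1),
            np.array([[3, 1], [4, 2]], dtype=np.uint8),
        )

    def test_rotation_then_flips_order(self):
        s = np.arange(6, dtype=np.uint8).reshape(2, 3)
        expect = np.rot90(s, -1)[:, ::-1]
        assert np.array_equal(
            transform_slice(s, rotation_quarter_turns=1, flip_h=True), expect
        )


class TestContrast:
    def test_minmax(self):
        assert auto_contrast_limits(np.array([3, 7, 5])) == (3.0, 7.0)

    def test_constant_slice_widens(self):
        assert auto_contrast_limits(np.full((2, 2), 9)) == (9.0, 10.0)

    def test_limits_match_independent_scan(self, rng):
        s = rng.integers(0, 65536, size=(16, 16)).astype(np.uint16)
        lo, hi = auto_contrast_limits(s)
        assert lo == min(v for v in s.ravel())
        assert hi == max(v for v in s.ravel())

    def test_normalize_endpoints_and_midpoint(self):
        s = np.array([10.0, 20.0, 15.0, 5.0, 25.0], dtype=np.float32)
        out = normalize(s, 10.0, 20.0)
        assert out[0] == 0 and out[1] == 255
        assert out[2] == 128  # midpoint rounds half up
        assert out[3] == 0 and out[4] == 255  # clamped outside limits

    def test_normalize_matches_bruteforce(self, rng):
        s = rng.integers(0, 65536, size=(8, 9)).astype(np.uint16)
        lo, hi = 1000.0, 60000.0
        assert np.array_equal(normalize(s, lo, hi), normalize_bruteforce(s, lo, hi))

    def test_bad_limits_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize(np.zeros((2, 2)), 5.0, 5.0)


class TestColorLUT:
    def test_gray_is_identity_ramp(self):
        lut = make_lut("gray")
        assert np.array_equal(lut.entries, np.repeat(np.arange(256), 3).reshape(256, 3))

    def test_inverted_gray_starts_white(self):
        lut = make_lut("gray", inverted=True)
        assert tuple(lut.entries[0]) == (255, 255, 255)
        assert tuple(lut.entries[255]) == (0, 0, 0)

    def test_inversion_reverses_every_registered_map(self):
        for name in available_colormaps():
            fwd = make_lut(name).entries
            inv = make_lut(name, inverted=True).entries
            assert np.array_equal(inv, fwd[::-1])

    def test_unknown_name_lists_alternatives(self):
        with pytest.raises(ConfigurationError, match="viridis"):
            make_lut("definitely-not-a-colormap")

    def test_apply_lut_is_table_lookup(self, rng):
        lut = make_lut("viridis")
        idx = rng.integers(0, 256, size=(6, 7)).astype(np.uint8)
        out = apply_lut(idx, lut)
        for r in range(6):
            for c in range(7):
                assert tuple(out[r, c]) == tuple(lut.entries[idx[r, c]])


class TestZoom:
    def test_factor_one_identity_both_modes(self, rng):
        a = rng.integers(0, 256, size=(5, 7, 3)).astype(np.uint8)
        assert np.array_equal(zoom(a, 1.0, interpolate=False), a)
        assert np.array_equal(zoom(a, 1.0, interpolate=True), a)

    def test_nearest_doubling_makes_blocks(self):
        a = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        out = zoom(a, 2.0)
        assert out.shape == (4, 4)
        assert np.array_equal(out, np.repeat(np.repeat(a, 2, axis=0), 2, axis=1))

    def test_halve_then_double_constant(self):
        a = np.full((6, 6), 42, dtype=np.uint8)
        out = zoom(zoom(a, 0.5), 2.0)
        assert np.array_equal(out, a)

    def test_bilinear_interpolates_between_neighbours(self):
        a = np.array([[0, 100]], dtype=np.uint8)
        out = zoom(a, 2.0, interpolate=True)
        # centre columns sample 1/4 and 3/4 of the way between the sources
        assert out.shape == (2, 4)
        assert list(out[0]) == [0, 25, 75, 100]

    def test_output_never_empty(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        assert zoom(a, 0.01).shape == (1, 1)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            zoom(np.zeros((2, 2), dtype=np.uint8), 0.0)


class TestRenderPipeline:
    def test_ramp_brightens_left_to_right(self):
        img = make_hyperstack(FixtureSpec(shape=(1, 1, 1, 4, 8), pattern="ramp-x"))
        rgb = render_pipeline(img, ViewState())
        lum = rgb.astype(int).sum(axis=2)
        assert np.all(np.diff(lum, axis=1) > 0)
        assert lum[0, 0] == 0 and lum[0, -1] == 3 * 255

    def test_inverted_colormap_darkens(self):
        img = make_hyperstack(FixtureSpec(shape=(1, 1, 1, 4, 8), pattern="ramp-x"))
        rgb = render_pipeline(img, ViewState(colormap_inverted=True))
        assert np.all(np.diff(rgb.astype(int).sum(axis=2), axis=1) < 0)

    @given(
        seed=st.integers(0, 50),
        k=st.integers(0, 3),
        fh=st.booleans(),
        fv=st.booleans(),
        plane=st.sampled_from(["XY", "XZ", "YZ"]),
        factor=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_pipeline_equals_stagewise_recomputation(self, seed, k, fh, fv, plane, factor):
        img = make_hyperstack(
            FixtureSpec(shape=(1, 1, 3, 5, 6), pattern="random", seed=seed)
        )
        view = ViewState(
            plane=plane,
            rotation_quarter_turns=k,
            flip_h=fh,
            flip_v=fv,
            colormap_name="magma",
            zoom_factor=factor,
        )
        s = transform_slice(orthoslice(img, view), k, fh, fv)
        lo, hi = auto_contrast_limits(s)
        expect = zoom(
            apply_lut(normalize(s, lo, hi), make_lut("magma")), factor, False
        )
        assert np.array_equal(render_pipeline(img, view), expect)

    def test_manual_contrast_used_verbatim(self):
        img = make_hyperstack(FixtureSpec(shape=(1, 1, 1, 2, 4), pattern="ramp-x"))
        rgb = render_pipeline(img, ViewState(contrast=(0.0, 255.0)))
        # with 0..255 limits the gray output equals the raw ramp values
        assert list(rgb[0, :, 0]) == [0, 1, 2, 3]

    def test_determinism(self):
        img = make_hyperstack(
            FixtureSpec(shape=(2, 2, 3, 6, 7), pattern="random", seed=3)
        )
        view = ViewState(plane="XZ", plane_index=2, zoom_factor=1.5, interpolate=True)
        a = render_pipeline(img, view)
        b = render_pipeline(img, view)
        assert a.tobytes() == b.tobytes()
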