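"""Unit and property tests for the image-analysis counting chain."""

import numpy as np
import pytest

from obseacensus.frame_pipeline import (
    FrameCensus,
    GeometryError,
    PipelineConfigError,
    PipelineParams,
    census_frame,
    census_sequence,
    combine_masks,
    expand_to_byte,
    fill_objects,
    filter_by_size,
    mask_to_byte,
    sobel_channel_edges,
    sobel_gradient_magnitude,
    subtract_reference,
)
from obseacensus.synthetic_data import SceneSpec, make_reference, render_scene

import oracles


def random_rgb(rng, shape=(24, 32)):
    return rng.integers(0, 256, size=shape + (3,), dtype=np.uint8)


class TestSubtractReference:
    def test_identical_frames_give_zero(self, rng):
        f = random_rgb(rng)
        assert not subtract_reference(f, f).any()

    def test_absolute_value_is_taken(self):
        f = np.full((2, 2, 3), 10, dtype=np.uint8)
        r = np.full((2, 2, 3), 250, dtype=np.uint8)
        assert (subtract_reference(f, r) == 240).all()
        assert (subtract_reference(r, f) == 240).all()

    def test_matches_pixel_loop_oracle(self, rng):
        f, r = random_rgb(rng, (9, 7)), random_rgb(rng, (9, 7))
        np.testing.assert_array_equal(subtract_reference(f, r), oracles.abs_diff_loop(f, r))

    def test_geometry_mismatch_names_both_shapes(self, rng):
        with pytest.raises(GeometryError, match=r"\(4, 4, 3\).*\(5, 4, 3\)"):
            subtract_reference(random_rgb(rng, (4, 4)), random_rgb(rng, (5, 4)))

    def test_global_offset_invariance(self, rng):
        f = rng.integers(40, 200, size=(16, 16, 3), dtype=np.uint8)
        r = rng.integers(40, 200, size=(16, 16, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            subtract_reference(f, r), subtract_reference(f + 30, r + 30)
        )


class TestExpandToByte:
    def test_constant_image_maps_to_zero(self):
        assert not expand_to_byte(np.full((5, 5, 3), 77, dtype=np.uint8)).any()

    def test_endpoints_map_to_range_ends(self):
        out = expand_to_byte(np.array([[40, 120]], dtype=np.uint8))
        np.testing.assert_array_equal(out, [[0, 255]])

    def test_matches_affine_rescale_oracle(self, rng):
        img = random_rgb(rng, (11, 13))
        np.testing.assert_array_equal(expand_to_byte(img), oracles.rescale_loop(img))

    def test_nonconstant_output_spans_full_range(self, rng):
        out = expand_to_byte(rng.integers(30, 90, size=(8, 8), dtype=np.uint8))
        assert out.min() == 0 and out.max() == 255


class TestSobelEdges:
    def test_constant_channels_give_empty_masks(self):
        img = np.full((10, 10, 3), 50, dtype=np.uint8)
        for mask in sobel_channel_edges(img):
            assert not mask.any()

    def test_magnitude_matches_convolution_oracle(self, rng):
        chan = rng.integers(0, 256, size=(10, 12)).astype(float)
        np.testing.assert_allclose(
            sobel_gradient_magnitude(chan), oracles.sobel_magnitude_loop(chan), rtol=1e-12
        )

    def test_vertical_step_edge_marks_band_only(self):
        img = np.zeros((12, 20, 3), dtype=np.uint8)
        img[:, 10:, :] = 200
        r, g, b = sobel_channel_edges(img)
        for mask in (r, g, b):
            assert mask[:, 9:11].all()  # band straddles the step
            assert not mask[:, :8].any() and not mask[:, 13:].any()

    def test_fixed_mode_requires_threshold(self):
        with pytest.raises(PipelineConfigError):
            PipelineParams(sobel_threshold_mode="fixed")

    def test_blob_contour_is_closed(self):
        """The edge mask around a high-contrast blob must enclose it, so that
        filling recovers a solid object."""
        img = np.full((40, 40, 3), 30, dtype=np.uint8)
        img[12:28, 10:30, :] = 220
        r, g, b = sobel_channel_edges(img)
        filled = fill_objects(combine_masks(r, g, b))
        assert filled[12:28, 10:30].all()


class TestCombineMasks:
    def test_all_zero_stays_zero(self):
        z = np.zeros((4, 4), dtype=bool)
        assert not combine_masks(z, z, z).any()

    def test_or_semantics_on_disjoint_pixels(self):
        r = np.zeros((3, 3), dtype=bool)
        g = np.zeros((3, 3), dtype=bool)
        b = np.zeros((3, 3), dtype=bool)
        r[0, 1] = True
        g[2, 2] = True
        out = combine_masks(r, g, b)
        assert out[0, 1] and out[2, 2] and out.sum() == 2

    def test_matches_or_loop_oracle(self, random_masks):
        masks = list(random_masks(n=30))
        for r, g, b in zip(masks[::3], masks[1::3], masks[2::3]):
            np.testing.assert_array_equal(combine_masks(r, g, b), oracles.or_loop(r, g, b))

    def test_geometry_mismatch_raises(self):
        with pytest.raises(GeometryError):
            combine_masks(np.zeros((3, 3), bool), np.zeros((4, 3), bool), np.zeros((3, 3), bool))


class TestFillObjects:
    def test_solid_disc_unchanged(self):
        yy, xx = np.mgrid[:21, :21]
        disc = (yy - 10) ** 2 + (xx - 10) ** 2 <= 49
        np.testing.assert_array_equal(fill_objects(disc), disc)

    def test_annulus_becomes_solid_disc(self):
        yy, xx = np.mgrid[:21, :21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        annulus = (r2 <= 64) & (r2 >= 25)
        disc = r2 <= 64
        np.testing.assert_array_equal(fill_objects(annulus), disc)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_border_flood_fill_oracle(self, random_masks, connectivity):
        for mask in random_masks(n=40):
            np.testing.assert_array_equal(
                fill_objects(mask, connectivity),
                oracles.fill_holes_bfs(mask, connectivity),
            )

    def test_monotone_and_idempotent(self, random_masks):
        for mask in random_masks(n=20):
            filled = fill_objects(mask)
            assert (filled | mask == filled).all()  # superset of input
            np.testing.assert_array_equal(fill_objects(filled), filled)


class TestFilterBySize:
    def test_bounds_are_inclusive(self):
        # components of areas 9, 10, 5000, 5001 on one canvas
        mask = np.zeros((80, 6000), dtype=bool)
        mask[0:3, 0:3] = True  # 9
        mask[10:12, 10:15] = True  # 10
        mask[20:70, 100:200] = True  # 5000
        mask[20:23, 300:1967] = True  # 5001
        objs = filter_by_size(mask)
        assert sorted(o.area for o in objs) == [10, 5000]

    def test_empty_mask_gives_empty_list(self):
        assert filter_by_size(np.zeros((5, 5), bool)) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_union_find_oracle(self, random_masks, connectivity):
        params = PipelineParams(min_area=1, max_area=10**6, connectivity=connectivity)
        for mask in random_masks(n=40):
            got = sorted(o.area for o in filter_by_size(mask, params))
            assert got == oracles.union_find_components(mask, connectivity)

    def test_tightening_bounds_never_increases_count(self, random_masks):
        for mask in random_masks(n=10, shape=(32, 32)):
            base = len(filter_by_size(mask, PipelineParams(min_area=1, max_area=100)))
            tighter = len(filter_by_size(mask, PipelineParams(min_area=3, max_area=50)))
            assert tighter <= base

    def test_objects_sorted_by_bbox(self, random_masks):
        for mask in random_masks(n=5, shape=(32, 32)):
            objs = filter_by_size(mask, PipelineParams(min_area=1, max_area=10**6))
            keys = [(o.bbox[0], o.bbox[1]) for o in objs]
            assert keys == sorted(keys)


class TestCensusFrame:
    def test_reference_frame_counts_zero(self, rng):
        ref = random_rgb(rng, (40, 40))
        c = census_frame(ref, ref)
        assert c.count == 0 and c.cumulative_area == 0

    def test_separated_blobs_counted_exactly(self):
        spec = SceneSpec(seed=5, n_fish=5)
        ref = make_reference(spec)
        frame, truth = render_scene(spec, ref)
        assert census_frame(frame, ref).count == truth.true_count == 5

    def test_oversized_object_is_eliminated(self):
        # single blob whose filled area exceeds max_area
        spec = SceneSpec(seed=6, n_fish=1, fish_area_range=(6000, 7000))
        ref = make_reference(spec)
        frame, _ = render_scene(spec, ref)
        assert census_frame(frame, ref).count == 0

    def test_census_internal_consistency(self):
        spec = SceneSpec(seed=7, n_fish=4)
        ref = make_reference(spec)
        frame, _ = render_scene(spec, ref)
        c = census_frame(frame, ref)
        assert c.count == len(c.objects)
        assert c.cumulative_area == sum(o.area for o in c.objects)


class TestCensusSequence:
    def test_reference_copies_give_zero_censuses(self, rng):
        ref = random_rgb(rng, (30, 30))
        out = census_sequence([(i, ref.copy()) for i in range(3)], ref)
        assert [c.count for c in out] == [0, 0, 0]
        assert [c.timestamp for c in out] == [0, 1, 2]

    def test_bad_frame_yields_flagged_entry_not_abort(self, rng):
        ref = random_rgb(rng, (30, 30))
        frames = [(0, ref.copy()), (1, random_rgb(rng, (10, 10))), (2, ref.copy())]
        out = census_sequence(frames, ref)
        assert len(out) == 3
        assert out[1].error is not None and out[0].error is None and out[2].error is None

    def test_empty_input_gives_empty_output(self, rng):
        assert census_sequence([], random_rgb(rng)) == []


def test_mask_serialises_as_0_255():
    m = np.array([[True, False]])
    np.testing.assert_array_equal(mask_to_byte(m), [[255, 0]])
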