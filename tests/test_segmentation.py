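"""Watershed segmentation: projection, preprocessing, partition, areas."""

import numpy as np
import pytest

from prothallus.evaluation import segmentation_score
from prothallus.images import LabelMap, PixelImage
from prothallus.render import RenderParams, render
from prothallus.segmentation import (
    AREA_COLORMAP,
    CellRecord,
    EmptySegmentationError,
    SegConfig,
    colorize_areas,
    max_project,
    preprocess,
    quantify_areas,
    segment,
)
from prothallus.simulate import SimCell


def img_of(arr, ps=1.0):
    return PixelImage(np.asarray(arr, dtype=float), pixel_size=ps)


class TestMaxProject:
    def test_single_slice_identity(self):
        a = img_of(np.arange(16 * 16).reshape(16, 16))
        out = max_project([a])
        np.testing.assert_array_equal(out.intensities, a.intensities)

    def test_zero_slice_is_neutral(self):
        a = img_of(np.random.default_rng(0).random((16, 16)))
        z = img_of(np.zeros((16, 16)))
        np.testing.assert_array_equal(
            max_project([a, z]).intensities, a.intensities
        )

    def test_result_dominates_every_slice(self):
        r = np.random.default_rng(1)
        slices = [img_of(r.random((16, 16))) for _ in range(4)]
        out = max_project(slices).intensities
        for s in slices:
            assert np.all(out >= s.intensities)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            max_project([img_of(np.zeros((16, 16))), img_of(np.zeros((8, 8)))])


class TestPreprocess:
    def test_constant_image_flagged_not_raised(self):
        out = preprocess(img_of(np.full((32, 32), 7.0)))
        assert out.flags.get("constant_input") is True
        assert np.all(out.intensities == 0)

    def test_output_in_unit_interval(self, rendered_snapshot):
        img, _, _, _ = rendered_snapshot
        out = preprocess(img)
        assert out.intensities.min() >= 0.0
        assert out.intensities.max() <= 1.0

    def test_walls_brighter_than_interiors(self, noiseless_snapshot):
        img, truth, _, _ = noiseless_snapshot
        out = preprocess(img)
        from prothallus.render import _wall_mask

        walls = _wall_mask(truth.labels)
        interiors = (truth.labels > 0) & ~walls
        assert out.intensities[walls].mean() > out.intensities[interiors].mean()


class TestSegment:
    def test_two_cell_noiseless_render_recovered(self):
        cells = [
            SimCell(id=1, polygon=np.array([(0, 0), (30, 0), (30, 30), (0, 30)], float),
                    role="ordinary", layer="marginal", birth_window=0),
            SimCell(id=2, polygon=np.array([(30, 0), (60, 0), (60, 30), (30, 30)], float),
                    role="ordinary", layer="marginal", birth_window=0),
        ]
        img, truth, _ = render(cells, RenderParams(pixel_size=0.5, blur_sigma=0, noise_sd=0))
        lm = segment(preprocess(img))
        score = segmentation_score(lm, truth, min_iou=0.95)
        assert score["n_seg"] == 2
        assert score["n_matched"] == 2

    def test_flat_blob_gives_single_cell(self):
        arr = np.zeros((64, 64))
        arr[16:48, 16:48] = 1000.0  # uniform tissue, no wall contrast
        lm = segment(preprocess(img_of(arr)))
        assert len(lm.label_ids()) == 1

    def test_no_tissue_raises(self):
        with pytest.raises(EmptySegmentationError):
            segment(PixelImage(np.zeros((32, 32)), pixel_size=1.0))

    def test_partition_and_dense_labels(self, rendered_snapshot):
        img, _, _, _ = rendered_snapshot
        lm = segment(preprocess(img))
        ids = lm.label_ids()
        assert ids.min() == 1 and set(ids) == set(range(1, ids.max() + 1))

    def test_deterministic(self, rendered_snapshot):
        img, _, _, _ = rendered_snapshot
        a = segment(preprocess(img))
        b = segment(preprocess(img))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rotation_robustness(self, rendered_snapshot):
        img, _, _, _ = rendered_snapshot
        n0 = len(segment(preprocess(img)).label_ids())
        rot = PixelImage(np.rot90(img.intensities).copy(), img.pixel_size)
        n90 = len(segment(preprocess(rot)).label_ids())
        assert n0 == n90

    def test_matches_truth_on_default_noise(self, rendered_snapshot):
        img, truth, _, _ = rendered_snapshot
        lm = segment(preprocess(img))
        score = segmentation_score(lm, truth, min_iou=0.7)
        assert score["match_rate"] >= 0.9


class TestQuantifyAreas:
    def make_map(self, ps):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        return LabelMap(labels, pixel_size=ps)

    def test_area_scales_with_pixel_size(self):
        recs = quantify_areas(self.make_map(1.0))
        assert recs[0].area == pytest.approx(100.0)
        recs = quantify_areas(self.make_map(0.5))
        assert recs[0].area == pytest.approx(25.0)

    def test_total_area_conserved(self, rendered_snapshot):
        img, truth, _, _ = rendered_snapshot
        recs = quantify_areas(truth)
        total = sum(r.area for r in recs)
        expected = (truth.labels > 0).sum() * truth.pixel_size**2
        assert total == pytest.approx(expected, rel=1e-9)

    def test_empty_map_gives_empty_list(self):
        lm = LabelMap(np.zeros((16, 16), dtype=np.int32), pixel_size=1.0)
        assert quantify_areas(lm) == []


class TestColorize:
    def record(self, area):
        return CellRecord(cell_id=1, area=area, centroid=(0, 0),
                          boundary=np.zeros((3, 2)))

    def lm(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:6, 2:6] = 1
        return LabelMap(labels, pixel_size=1.0)

    def test_zero_area_is_exact_blue(self):
        rgb, meta = colorize_areas([self.record(0.0)], self.lm(), cap=2000)
        assert tuple(rgb[3, 3]) == (0.0, 0.0, 1.0)
        assert meta["cap_um2"] == 2000

    def test_capped_area_is_exact_red(self):
        rgb, _ = colorize_areas([self.record(5000.0)], self.lm(), cap=2000)
        assert tuple(rgb[3, 3]) == (1.0, 0.0, 0.0)

    def test_half_cap_is_colormap_midpoint(self):
        rgb, _ = colorize_areas([self.record(1000.0)], self.lm(), cap=2000)
        np.testing.assert_allclose(rgb[3, 3], AREA_COLORMAP(0.5)[:3], atol=1e-8)

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError):
            colorize_areas([], self.lm(), cap=0.0)
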