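"""Preprocessing contracts: plane selection, normalization, segmentation,
erosion-dilation splitting (against a brute-force oracle), filtering, stats
and cropping."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.morphology import disk as disk_selem

from gadnet.preprocess import (
    MicrographStack,
    PreprocessConfig,
    Roi,
    SegmentationMask,
    compute_roi_stats,
    crop_cell_images,
    extract_planes,
    filter_rois_by_area,
    normalize_plane,
    segment_cells,
    split_rois_erosion_dilation,
)
from gadnet.synthetic import SynthConfig, generate_micrograph

STRUCT8 = np.ones((3, 3), dtype=bool)


def split_count_oracle(support, radius=1, max_iters=10):
    """Brute force: scan erosions; the answer is the component count at the
    first iteration with more than one component, else 1."""
    cur = support
    for _ in range(max_iters):
        cur = ndimage.binary_erosion(cur, structure=disk_selem(radius), border_value=0)
        if not cur.any():
            return 1
        _, n = ndimage.label(cur, structure=STRUCT8)
        if n > 1:
            return n
    return 1


def make_stack(n_planes=10, shape=(16, 16), n_channels=2, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0, 100, size=(n_channels, n_planes, *shape))
    return MicrographStack(vals, tuple(f"ch{i}" for i in range(n_channels))[:n_channels])


class TestExtractPlanes:
    def test_default_takes_first_and_last(self):
        stack = make_stack(n_planes=10)
        idx, planes = extract_planes(stack)
        assert idx == (0, 9)
        assert planes.shape[1] == 2
        assert np.array_equal(planes[:, 1], stack.intensities[:, 9])

    def test_single_plane_collapses_duplicates(self):
        stack = make_stack(n_planes=1)
        idx, planes = extract_planes(stack)
        assert idx == (0,)
        assert planes.shape[1] == 1

    def test_explicit_plane_selection(self):
        stack = make_stack(n_planes=10)
        idx, _ = extract_planes(stack, PreprocessConfig(planes_used=(2,)))
        assert idx == (2,)

    def test_out_of_range_plane_raises(self):
        stack = make_stack(n_planes=3)
        with pytest.raises(IndexError):
            extract_planes(stack, PreprocessConfig(planes_used=(5,)))


class TestNormalizePlane:
    def test_affine_map_by_definition(self):
        rng = np.random.default_rng(0)
        plane = rng.normal(100, 20, size=(50, 50))
        # force exact mean/SD interpretation via direct checks
        out = normalize_plane(plane)
        mean, sd = plane.mean(), plane.std()
        assert np.allclose(out, (plane - (mean - sd)) / (2 * sd))
        assert out.mean() == pytest.approx(0.5, abs=1e-12)

    def test_named_points(self):
        # this plane has mean 100 and SD 20 exactly:
        plane = np.array([[100.0, 120.0, 60.0], [120.0, 100.0, 100.0]])
        assert plane.mean() == 100.0 and plane.std() == 20.0
        out = normalize_plane(plane)
        assert out[0, 0] == pytest.approx(0.5)  # pixel at the mean
        assert out[0, 1] == pytest.approx(1.0)  # mean + SD
        assert out[0, 2] == pytest.approx(-0.5)  # mean - 2*SD -> below zero

    def test_values_outside_unit_interval_not_clipped(self):
        plane = np.array([[0.0, 0.0, 0.0, 100.0]])
        out = normalize_plane(plane)
        assert out.min() < 0.0 or out.max() > 1.0

    def test_affine_input_invariance(self):
        rng = np.random.default_rng(1)
        plane = rng.uniform(0, 1000, size=(30, 40))
        for a, b in [(2.0, 5.0), (0.3, -40.0), (17.0, 0.0)]:
            assert np.allclose(normalize_plane(a * plane + b), normalize_plane(plane))

    def test_constant_plane_returns_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant plane"):
            out = normalize_plane(np.full((8, 8), 3.0))
        assert np.all(out == 0.5)


class TestSegmentCells:
    def test_external_binary_mask_relabeled(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[2:5, 2:5] = 1
        mask[10:14, 10:14] = 1
        mask[20:24, 2:6] = 1
        plane = np.zeros((30, 30))
        seg = segment_cells(plane, external_mask=mask)
        assert seg.source == "external-mask"
        assert set(np.unique(seg.labels)) == {0, 1, 2, 3}

    def test_external_labeled_mask_relabeled_consecutively(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[1:4, 1:4] = 7
        mask[10:13, 10:13] = 99
        seg = segment_cells(np.zeros((20, 20)), external_mask=mask)
        assert set(np.unique(seg.labels)) == {0, 1, 2}

    def test_fallback_finds_bright_ellipses(self):
        rng = np.random.default_rng(2)
        plane = rng.normal(100.0, 5.0, size=(200, 200))
        centers = [(30, 30), (30, 160), (100, 100), (160, 40), (170, 170)]
        for r, c in centers:
            rr, cc = draw_disk((r, c), 12)
            plane[rr, cc] = 1000.0
        seg = segment_cells(plane)
        assert seg.source == "internal-fallback"
        assert seg.n_labels == 5

    def test_all_background_yields_zero_labels(self):
        seg = segment_cells(np.zeros((20, 20)))
        assert seg.n_labels == 0
        assert split_rois_erosion_dilation(seg) == []

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            segment_cells(np.zeros((10, 10)), external_mask=np.zeros((9, 9), dtype=int))


class TestErosionDilationSplit:
    def test_convex_disc_passes_through_unchanged(self):
        mask = np.zeros((50, 50), dtype=int)
        rr, cc = draw_disk((25, 25), 10)
        mask[rr, cc] = 1
        rois = split_rois_erosion_dilation(SegmentationMask(mask, "external-mask"))
        assert len(rois) == 1
        assert rois[0].split_lineage is None
        assert np.array_equal(rois[0].full_mask(mask.shape), mask > 0)

    def test_dumbbell_splits_into_two_within_parent(self):
        mask = np.zeros((60, 60), dtype=int)
        for center in [(30, 20), (30, 34)]:
            rr, cc = draw_disk(center, 10)
            mask[rr, cc] = 1
        support = mask > 0
        rois = split_rois_erosion_dilation(SegmentationMask(mask, "external-mask"))
        assert len(rois) == split_count_oracle(support) == 2
        union = np.zeros_like(support)
        for roi in rois:
            child = roi.full_mask(mask.shape)
            assert roi.split_lineage == 1
            assert not (union & child).any(), "children overlap"
            union |= child
        assert not (union & ~support).any(), "children escape the parent support"

    def test_mask_and_images_never_modified(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((40, 40), dtype=int)
        for center in [(20, 12), (20, 26)]:
            rr, cc = draw_disk(center, 8)
            mask[rr, cc] = 1
        image = rng.uniform(0, 1, size=mask.shape)
        mask_before, image_before = mask.copy(), image.copy()
        split_rois_erosion_dilation(SegmentationMask(mask, "external-mask"))
        assert np.array_equal(mask, mask_before)
        assert np.array_equal(image, image_before)

    def test_split_count_matches_oracle_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            mask = np.zeros((64, 64), dtype=int)
            n_blobs = int(rng.integers(1, 4))
            for _ in range(n_blobs):
                r = int(rng.integers(10, 54))
                c = int(rng.integers(10, 54))
                rad = int(rng.integers(4, 10))
                rr, cc = draw_disk((r, c), rad, shape=mask.shape)
                mask[rr, cc] = 1
            labeled, n = ndimage.label(mask > 0, structure=STRUCT8)
            rois = split_rois_erosion_dilation(SegmentationMask(labeled, "external-mask"))
            expected = sum(
                split_count_oracle(labeled == lab) for lab in range(1, n + 1)
            )
            assert len(rois) == expected

    def test_seeded_fused_pairs_split_into_two(self):
        """>= 95 of 100 generator-produced touching pairs separate cleanly."""
        n_pairs = split2 = 0
        seed = 0
        while n_pairs < 100:
            cfg = SynthConfig(
                n_cells=40, image_size=(460, 460), touching_pair_fraction=1.0,
                seed=seed, n_planes=1,
            )
            _, truth, _ = generate_micrograph(cfg)
            rois = split_rois_erosion_dilation(
                SegmentationMask(truth.labeled_mask, "external-mask")
            )
            children_by_parent = {}
            for roi in rois:
                if roi.split_lineage is not None:
                    children_by_parent.setdefault(roi.split_lineage, 0)
                    children_by_parent[roi.split_lineage] += 1
            fused_labels = {}
            for cell in truth.cells:
                fused_labels.setdefault(cell.mask_label, 0)
                fused_labels[cell.mask_label] += 1
            for lab, n_cells in fused_labels.items():
                if n_cells == 2 and n_pairs < 100:
                    n_pairs += 1
                    if children_by_parent.get(lab, 1) == 2:
                        split2 += 1
            seed += 1
        assert split2 >= 95, f"only {split2}/100 fused pairs split into two"


class TestFilterAndStats:
    def _roi_of_area(self, area):
        side = int(np.ceil(np.sqrt(area)))
        patch = np.zeros((side, side + 1), dtype=bool)
        patch.flat[:area] = True
        return Roi(patch=patch, offset=(0, 0), roi_id=area)

    def test_area_threshold_boundary(self):
        rois = [self._roi_of_area(a) for a in (100, 179, 180, 500)]
        kept = filter_rois_by_area(rois, PreprocessConfig(min_area=180))
        assert [r.area for r in kept] == [180, 500]

    def test_empty_and_identity_filters(self):
        assert filter_rois_by_area([], PreprocessConfig(min_area=180)) == []
        rois = [self._roi_of_area(a) for a in (5, 50)]
        assert filter_rois_by_area(rois, PreprocessConfig(min_area=1)) == rois

    def test_filter_monotone_in_min_area(self):
        rng = np.random.default_rng(4)
        rois = [self._roi_of_area(int(a)) for a in rng.integers(10, 400, size=30)]
        counts = [
            len(filter_rois_by_area(rois, PreprocessConfig(min_area=m)))
            for m in (1, 50, 100, 200, 400)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_stats_constant_region_and_square(self):
        patch = np.ones((10, 10), dtype=bool)
        roi = Roi(patch=patch, offset=(5, 5), roi_id=0)
        planes = {"a": np.full((30, 30), 50.0), "b": np.full((30, 30), 7.0)}
        stats = compute_roi_stats(roi, planes)
        assert stats["mean_a"] == 50.0
        assert stats["mean_b"] == 7.0
        assert stats["area_px2"] == 100

    def test_disc_circularity_near_one(self):
        shape = (60, 60)
        patch = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((30, 30), 20)
        patch[rr, cc] = True
        roi = Roi(patch=patch, offset=(0, 0), roi_id=0)
        assert 0.85 <= roi.circularity <= 1.05

    def test_empty_roi_rejected(self):
        roi = Roi(patch=np.zeros((4, 4), dtype=bool), offset=(0, 0), roi_id=0)
        with pytest.raises(ValueError):
            compute_roi_stats(roi, {"a": np.zeros((10, 10))})


class TestCrop:
    def test_crop_shape_and_values(self):
        patch = np.zeros((20, 30), dtype=bool)
        patch[:, :] = True
        roi = Roi(patch=patch, offset=(5, 8), roi_id=3)
        rng = np.random.default_rng(5)
        planes = {"x": rng.uniform(size=(60, 60)), "y": rng.uniform(size=(60, 60))}
        crops = crop_cell_images([roi], planes, ("x", "y"))
        assert crops[0].values.shape == (2, 20, 30)
        # full rectangle, not masked: values equal the plane everywhere
        assert np.allclose(crops[0].values[0], planes["x"][5:25, 8:38].astype(np.float32))

    def test_empty_channel_subset_rejected(self):
        roi = Roi(patch=np.ones((4, 4), dtype=bool), offset=(0, 0), roi_id=0)
        with pytest.raises(ValueError):
            crop_cell_images([roi], {}, ())
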