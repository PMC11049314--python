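"""Normalization, background masking, spherical k-means, the hierarchical
3->6->10 workflow, and volumetry."""

import numpy as np
import pytest

from iirbssfp import (
    LabelVolume,
    PhantomSpec,
    SegmentationModel,
    TiSeries,
    background_mask,
    brain_extract,
    build_phantom,
    dice,
    hierarchical_segment,
    lesion_volumes,
    normalize_voxels,
    spherical_kmeans,
)
from iirbssfp.segment import SegmentationError


def _true_brain(truth):
    skull = truth.labels.class_names.index("skull") + 1
    return (truth.labels.labels > 0) & (truth.labels.labels != skull)


class TestNormalization:
    def test_scale_invariance(self, phantom64):
        series, _ = phantom64
        n1 = normalize_voxels(series)
        scaled = TiSeries(series.volume * 7.3, series.voxel_size_mm, series.ti_ms)
        n2 = normalize_voxels(scaled)
        np.testing.assert_allclose(n2.volume, n1.volume, atol=1e-12)

    def test_zero_norm_voxel_is_flagged_not_nan(self):
        vol = np.zeros((2, 2, 2, 5))
        vol[0, 0, 0] = 1.0
        s = TiSeries(vol, (1, 1, 1), np.arange(5.0) + 1)
        out = normalize_voxels(s).volume
        assert np.all(np.isfinite(out))
        assert np.all(out[1, 1, 1] == 0.0)


class TestBackgroundMask:
    def test_noiseless_mask_equals_signal_support(self):
        spec = PhantomSpec(
            shape_voxels=(32,) * 3, voxel_size_mm=(4.0,) * 3, snr=np.inf,
            bias_field_order=0, seed=0,
        )
        series, truth = build_phantom(spec)
        m = background_mask(series, 0.02)
        np.testing.assert_array_equal(m, truth.labels.labels > 0)

    def test_zero_threshold_keeps_any_signal(self):
        vol = np.zeros((3, 3, 3, 4))
        vol[1, 1, 1] = 0.5
        s = TiSeries(vol, (1, 1, 1), np.arange(4.0) + 1)
        m = background_mask(s, 0.0)
        assert m.sum() == 1 and m[1, 1, 1]

    def test_automatic_threshold_separates_air_from_head_at_snr50(self):
        hits, fps = [], []
        for seed in range(3):
            series, truth = build_phantom(
                PhantomSpec(shape_voxels=(32,) * 3, voxel_size_mm=(4.0,) * 3, seed=seed)
            )
            m = background_mask(series, "otsu")
            head = truth.labels.labels > 0
            hits.append((m & head).sum() / head.sum())
            fps.append((m & ~head).sum() / (~head).sum())
        assert min(hits) >= 0.99
        assert max(fps) <= 0.01


class TestSphericalKMeans:
    def test_orthonormal_prototypes_recovered_exactly(self):
        rng = np.random.default_rng(0)
        protos = np.eye(6)[:3]
        curves = np.repeat(protos, 40, axis=0)
        cs = spherical_kmeans(curves[rng.permutation(len(curves))], 3, seed=0)
        # every center equals one prototype; partition perfect
        dots = cs.centers @ protos.T
        assert np.allclose(np.sort(dots.max(axis=1)), 1.0)
        sizes = np.bincount(cs.labels)
        assert np.all(sizes == 40)

    def test_objective_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(500, 20)) + 3.0
        curves = np.abs(raw)
        curves /= np.linalg.norm(curves, axis=1, keepdims=True)
        cs = spherical_kmeans(curves, 5, seed=0)
        hist = np.array(cs.objective_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_noiseless_three_tissue_partition_is_exact(
        self, phantom32_noiseless_lesion_free
    ):
        series, truth = phantom32_noiseless_lesion_free
        brain = _true_brain(truth)
        curves = normalize_voxels(series).volume[brain]
        cs = spherical_kmeans(curves, 3, seed=0)
        tl = truth.labels.labels[brain]
        names = truth.labels.class_names
        # sorted by min-time: WM first, then GM, then CSF (T1 order)
        for cluster, tissue in enumerate(("WM", "GM", "CSF")):
            want = tl == names.index(tissue) + 1
            assert dice(cs.labels == cluster, want) == 1.0

    def test_requires_enough_curves(self):
        with pytest.raises(SegmentationError):
            spherical_kmeans(np.eye(4)[:2], 3, seed=0)


class TestBrainExtract:
    def test_skull_shell_is_stripped(self, phantom64):
        series, truth = phantom64
        mask = brain_extract(series)
        skull = truth.labels.labels == truth.labels.class_names.index("skull") + 1
        assert dice(mask, _true_brain(truth)) >= 0.95
        assert (mask & skull).sum() / skull.sum() < 0.05

    def test_without_skull_mask_covers_head(self):
        geo = dict(PhantomSpec().geometry)
        geo["head"] = geo["brain_outer"]  # no skull shell
        series, truth = build_phantom(
            PhantomSpec(shape_voxels=(32,) * 3, voxel_size_mm=(4.0,) * 3,
                        geometry=geo, seed=0)
        )
        mask = brain_extract(series)
        head = truth.labels.labels > 0
        assert (mask & head).sum() / head.sum() >= 0.99


class TestHierarchical:
    def test_ten_segments_before_merging(self, phantom64):
        series, _ = phantom64
        res = SegmentationModel(series).fit(seed=0)
        assert res.n_segments == 10
        assert [s.k for s in res.stages] == [3, 6, 10]

    def test_deterministic_given_seed(self, phantom64):
        series, _ = phantom64
        a = SegmentationModel(series).fit(seed=0)
        b = SegmentationModel(series).fit(seed=0)
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)

    def test_pure_lesion_segments_exist(self, phantom64):
        """The refinement isolates the contrast-enhancing rim and the outer
        T2 shell as (near-)pure segments among the ten."""
        series, truth = phantom64
        res = SegmentationModel(series).fit(seed=0)
        s3 = res.stages[-1]
        tl = truth.labels.labels[res.brain_mask]
        names = truth.labels.class_names
        purity = {}
        for pos in range(s3.k):
            member = tl[s3.labels == pos]
            codes, counts = np.unique(member, return_counts=True)
            top = codes[np.argmax(counts)]
            name = names[top - 1] if top else "air"
            frac = counts.max() / len(member)
            purity.setdefault(name, 0.0)
            purity[name] = max(purity[name], frac)
        assert purity.get("CEL", 0.0) >= 0.9
        assert purity.get("T2L-1", 0.0) >= 0.9
        assert purity.get("WM", 0.0) >= 0.9

    def test_label_invariance_under_pervoxel_gains_fixed_mask(self, phantom64):
        series, _ = phantom64
        mask = brain_extract(series)
        gains = np.random.default_rng(3).uniform(0.5, 2.0, series.shape)
        gained = TiSeries(series.volume * gains[..., None], series.voxel_size_mm, series.ti_ms)
        l1 = hierarchical_segment(series, seed=0, brain_mask=mask)
        l2 = hierarchical_segment(gained, seed=0, brain_mask=mask)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_cluster_min_time_order_tracks_t1_on_noiseless_tissues(
        self, phantom32_noiseless_lesion_free
    ):
        series, truth = phantom32_noiseless_lesion_free
        brain = _true_brain(truth)
        curves = normalize_voxels(series).volume[brain]
        cs = spherical_kmeans(curves, 3, seed=0)
        # min-time sorted cluster order equals T1 order (WM 848 < GM 912 < CSF 2990)
        assert np.all(np.diff(cs.min_time_index) >= 0)


class TestVolumes:
    def test_unit_conversion(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels.ravel()[:1000] = 1
        lv = LabelVolume(labels, ("WM",), (1.0, 1.0, 1.0))
        vols = lesion_volumes(lv)
        assert vols["WM"] == pytest.approx(1.0)

    def test_empty_class_is_zero(self):
        lv = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), ("WM", "GM"), (2.0, 2.0, 2.0))
        vols = lesion_volumes(lv)
        assert vols == {"WM": 0.0, "GM": 0.0}

    def test_sphere_volume_within_voxelization_error(self, phantom64):
        _, truth = phantom64
        names = truth.labels.class_names
        core = truth.labels.labels == names.index("NEC") + 1
        vol = core.sum() * truth.labels.voxel_volume_mm3 / 1000.0
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 6.0**3 / 1000.0, rel=0.25)
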