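import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from hsiderm import mlprep
from hsiderm.mlprep import (
    FeatureCube,
    WindowSample,
    augment_flips,
    balance_oversample,
    build_masks,
    make_validation_split,
    normalize,
    rolling_windows,
    sample_windows,
    select_channels,
    split_vertical,
)
from hsiderm.photometric import ProcessedCube


def disk_mask(shape, center, radius):
    rr = np.hypot(
        np.arange(shape[0])[:, None] - center[0], np.arange(shape[1])[None, :] - center[1]
    )
    return rr <= radius


def dummy_sample(label, value=0.0, side="train", shape=(2, 2, 1)):
    return WindowSample(patch=np.full(shape, value, dtype=np.float32), label=label,
                        center=(0, 0), side=side)


class TestBuildMasks:
    def test_core_is_erosion_by_30(self):
        ann = disk_mask((280, 280), (140, 140), 100)
        fov = np.ones((280, 280), dtype=bool)
        masks = build_masks(ann, fov, erosion_px=30, margin_px=60, annulus_outer_px=110)
        expect = disk_mask((280, 280), (140, 140), 70)
        # rasterized erosion of a rasterized disk: allow a 1-px rim
        assert (masks.lesion_core ^ expect).sum() < 0.02 * expect.sum()

    def test_no_healthy_pixel_within_60px_of_boundary(self):
        ann = disk_mask((280, 280), (140, 140), 60)
        fov = np.ones((280, 280), dtype=bool)
        masks = build_masks(ann, fov, erosion_px=30, margin_px=60, annulus_outer_px=130)
        dist_to_lesion = distance_transform_edt(~ann)
        assert dist_to_lesion[masks.healthy_region].min() > 60 - 1.5

    def test_clipped_annulus_stays_disjoint(self):
        # annotation close to the fov edge: the annulus is clipped but the
        # sampling regions stay pairwise disjoint
        fov = disk_mask((200, 200), (100, 100), 95)
        ann = disk_mask((200, 200), (70, 70), 40)
        masks = build_masks(ann, fov, erosion_px=10, margin_px=20, annulus_outer_px=80)
        assert not (masks.healthy_region & masks.exclusion_band).any()
        assert not (masks.healthy_region & masks.lesion_core).any()

    def test_empty_core_rejected(self):
        ann = disk_mask((100, 100), (50, 50), 10)
        with pytest.raises(ValueError, match="smaller erosion"):
            build_masks(ann, np.ones((100, 100), dtype=bool), erosion_px=30)

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_masks(np.zeros((50, 50), dtype=bool), np.ones((50, 50), dtype=bool))


class TestSelectChannels:
    def test_34_channels_and_surface_selection(self, processed):
        feat = select_channels(processed)
        assert feat.values.shape[-1] == 34
        idx = int(np.argmin(np.abs(processed.band_centers_nm - 575.0)))
        assert feat.surface_band_nm == processed.band_centers_nm[idx]
        assert np.array_equal(feat.values[:, :, 33], processed.depth[:, :, idx])

    def test_surface_band_891_selects_last(self, processed):
        feat = select_channels(processed, surface_band_nm=891.0)
        assert np.array_equal(feat.values[:, :, 33], processed.depth[:, :, 32])

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            ProcessedCube(values=np.zeros((4, 4, 34)), band_centers_nm=np.linspace(477, 891, 33))


class TestNormalize:
    def test_minmax(self):
        values = np.zeros((1, 3, 34))
        values[0, :, 0] = [2.0, 3.0, 4.0]
        out = normalize(values)
        assert np.allclose(out.values[0, :, 0], [0.0, 0.5, 1.0])

    def test_nonfinite_to_zero_before_scaling(self):
        values = np.zeros((1, 4, 34))
        values[0, :, 0] = [np.nan, np.inf, -np.inf, 4.0]
        out = normalize(values)
        assert np.all(np.isfinite(out.values))
        assert np.allclose(out.values[0, :, 0], [0.0, 0.0, 0.0, 1.0])

    def test_constant_channel_zeroed(self):
        values = np.full((2, 2, 34), 7.0)
        assert np.all(normalize(values).values == 0.0)

    def test_scaling_restricted_to_fov(self):
        values = np.zeros((2, 2, 34))
        values[..., 0] = [[1.0, 2.0], [3.0, 100.0]]
        fov = np.array([[True, True], [True, False]])
        out = normalize(values, fov)
        assert np.allclose(out.values[0, :, 0], [0.0, 0.5])
        assert out.values[1, 1, 0] == 1.0  # out-of-fov clipped to the range


def feature_disk(shape=(120, 100), radius=25):
    h, w = shape
    ann = disk_mask(shape, (h // 2, w // 2), radius)
    fov = np.ones(shape, dtype=bool)
    rng = np.random.default_rng(0)
    cube = FeatureCube(values=rng.random((h, w, 34), dtype=np.float32),
                       band_centers_nm=np.linspace(477, 891, 33), surface_band_nm=575.0)
    masks = build_masks(ann, fov, erosion_px=8, margin_px=12, annulus_outer_px=40)
    return cube, masks


class TestSplitVertical:
    def test_centered_disk_symmetric(self):
        cube, masks = feature_disk()
        train, test = split_vertical(cube, masks, label="MM")
        assert abs(int(train.masks.lesion_core.sum()) - int(test.masks.lesion_core.sum())) <= \
            masks.lesion_core.shape[0]
        assert train.cube.values.shape[1] + test.cube.values.shape[1] == cube.values.shape[1]

    def test_reassembly(self):
        cube, masks = feature_disk()
        train, test = split_vertical(cube, masks, label="MM")
        assert np.array_equal(
            np.concatenate([train.cube.values, test.cube.values], axis=1), cube.values
        )

    def test_losing_core_rejected(self):
        # two blobs: only the left one survives erosion, but the second blob
        # drags the centroid column right of it, emptying one half's core
        cube, masks = feature_disk(shape=(120, 180))
        ann = disk_mask((120, 180), (60, 30), 12) | disk_mask((120, 180), (60, 150), 7)
        bad = build_masks(ann, np.ones((120, 180), dtype=bool),
                          erosion_px=8, margin_px=12, annulus_outer_px=40)
        with pytest.raises(ValueError, match="lesion_core"):
            split_vertical(cube, bad, label="MM")


class TestSampleWindows:
    @staticmethod
    def _half(label="MM"):
        cube, masks = feature_disk(shape=(160, 160), radius=35)
        return split_vertical(cube, masks, label=label)

    def test_quota_and_labels(self):
        train, _ = self._half()
        samples = sample_windows(train, n_lesion=40, n_healthy=20, seed=1)
        assert len(samples) == 60
        assert sum(s.label == "MM" for s in samples) == 40
        assert sum(s.label == "healthy" for s in samples) == 20
        for s in samples:
            assert s.patch.shape == (30, 30, 34)

    def test_deterministic(self):
        train, _ = self._half()
        a = sample_windows(train, 30, 10, seed=9)
        b = sample_windows(train, 30, 10, seed=9)
        assert [s.center for s in a] == [s.center for s in b]

    def test_centers_respect_regions(self):
        train, _ = self._half()
        samples = sample_windows(train, 40, 20, seed=2)
        for s in samples:
            region = train.masks.lesion_core if s.label == "MM" else train.masks.healthy_region
            assert region[s.center]

    def test_patch_matches_cube(self):
        train, _ = self._half()
        s = sample_windows(train, 5, 5, seed=3)[0]
        r, c = s.center
        assert np.array_equal(s.patch, train.cube.values[r - 15 : r + 15, c - 15 : c + 15])

    def test_shortfall_reported(self):
        train, _ = self._half()
        with pytest.raises(ValueError, match="lesion: need 100000"):
            sample_windows(train, n_lesion=100000, n_healthy=1, seed=0)


class TestBalanceOversample:
    def test_counts_equalized(self):
        samples = (
            [dummy_sample("A", i) for i in range(100)]
            + [dummy_sample("B", i) for i in range(60)]
            + [dummy_sample("C", i) for i in range(40)]
        )
        out = balance_oversample(samples, seed=1)
        labels = [s.label for s in out]
        assert labels.count("A") == labels.count("B") == labels.count("C") == 100

    def test_balanced_input_unchanged(self):
        samples = [dummy_sample("A", 1), dummy_sample("B", 2)]
        assert balance_oversample(samples, seed=0) == samples

    def test_added_samples_are_duplicates(self):
        samples = [dummy_sample("A", i) for i in range(5)] + [dummy_sample("B", 99)]
        out = balance_oversample(samples, seed=0)
        originals = {id(s) for s in samples}
        for s in out:
            if id(s) not in originals:
                assert s in samples  # dataclass equality: exact duplicate

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            balance_oversample([dummy_sample("A")], seed=0)


class TestAugmentFlips:
    def test_triples_count_and_keeps_labels(self):
        rng = np.random.default_rng(0)
        samples = [
            WindowSample(patch=rng.random((6, 6, 34)), label="MM", center=(3, 3), side="train")
            for _ in range(4)
        ]
        out = augment_flips(samples)
        assert len(out) == 12
        assert all(s.label == "MM" for s in out)

    def test_flip_involution(self):
        rng = np.random.default_rng(1)
        s = WindowSample(patch=rng.random((6, 6, 34)), label="PN", center=(3, 3), side="train")
        twice = augment_flips(augment_flips([s]))
        # horizontal flip of the horizontal flip reproduces the original
        assert np.array_equal(twice[0].patch[:, ::-1][:, ::-1], s.patch)
        flipped_h = augment_flips([s])[2]
        assert np.array_equal(flipped_h.patch[:, ::-1], s.patch)

    def test_channels_untouched(self):
        patch = np.arange(6 * 6 * 34, dtype=np.float32).reshape(6, 6, 34)
        s = WindowSample(patch=patch, label="MM", center=(3, 3), side="train")
        _, flipped_v, flipped_h = augment_flips([s])
        assert np.array_equal(flipped_v.patch, patch[::-1, :])
        assert np.array_equal(flipped_h.patch, patch[:, ::-1])


class TestRollingWindows:
    @staticmethod
    def _cube(h, w):
        rng = np.random.default_rng(0)
        return FeatureCube(values=rng.random((h, w, 34), dtype=np.float32),
                           band_centers_nm=np.linspace(477, 891, 33), surface_band_nm=575.0)

    def test_center_count_100x100(self):
        # [DERIVED]: brute-force center count under the (15, 15) inset convention
        cube = self._cube(100, 100)
        centers = [c for c, _ in rolling_windows(cube, np.ones((100, 100), dtype=bool))]
        assert len(centers) == 71 * 71
        rows = sorted({r for r, _ in centers})
        assert rows[0] == 15 and rows[-1] == 85

    def test_fov_respected(self):
        cube = self._cube(60, 60)
        fov = np.zeros((60, 60), dtype=bool)
        fov[20:30, 20:30] = True
        centers = [c for c, _ in rolling_windows(cube, fov)]
        assert centers and all(fov[c] for c in centers)

    def test_repeatable_patches(self):
        cube = self._cube(40, 40)
        fov = np.ones((40, 40), dtype=bool)
        a = dict(rolling_windows(cube, fov))
        b = dict(rolling_windows(cube, fov))
        for c in a:
            assert np.array_equal(a[c], b[c])

    def test_window_larger_than_frame(self):
        cube = self._cube(20, 20)
        with pytest.raises(ValueError, match="larger than frame"):
            next(rolling_windows(cube, np.ones((20, 20), dtype=bool)))


class TestValidationSplit:
    @staticmethod
    def _samples():
        counts = {"MM": 1750, "PN": 3250, "healthy": 2000}  # 20 x (250 + 100)
        return [dummy_sample(label, i) for label, n in counts.items() for i in range(n)]

    def test_7000_to_1400(self):
        train, val = make_validation_split(self._samples(), fraction=0.2, seed=0)
        assert len(val) == 1400 and len(train) == 5600

    def test_strata_preserved(self):
        train, val = make_validation_split(self._samples(), fraction=0.2, seed=0)
        val_labels = [s.label for s in val]
        assert val_labels.count("MM") == 350
        assert val_labels.count("PN") == 650
        assert val_labels.count("healthy") == 400

    def test_disjoint(self):
        samples = self._samples()
        train, val = make_validation_split(samples, fraction=0.2, seed=1)
        train_ids = {id(s) for s in train}
        assert not any(id(s) in train_ids for s in val)
        assert len(train) + len(val) == len(samples)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            make_validation_split(self._samples(), fraction=0.0, seed=0)
        with pytest.raises(ValueError, match="stratum"):
            make_validation_split([dummy_sample("A", i) for i in range(2)], 0.1, seed=0)


class TestWindowPersistence:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        samples = [
            WindowSample(patch=rng.random((30, 30, 34)).astype(np.float32),
                         label="MM", center=(20, 21), side="test")
            for _ in range(3)
        ]
        mlprep.save_windows(samples, tmp_path, seed=7, quotas={"lesion": 3})
        loaded = mlprep.load_windows(tmp_path)
        assert len(loaded) == 3
        for a, b in zip(samples, loaded):
            assert np.array_equal(a.patch, b.patch)
            assert a.label == b.label and a.center == b.center and a.side == b.side
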