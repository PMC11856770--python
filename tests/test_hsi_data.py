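"""Cube loading, band removal, normalization, splitting, patching."""

import numpy as np
import pytest
import scipy.io

from benchmark_tables import TABLES
from sgtn.hsi_data import (GroundTruthMap, HSICube, default_band_drops,
                           extract_patch, load_cube, make_patch_set,
                           normalize_cube, patch_arrays, read_split_manifest,
                           remove_bands, split_counts, stratified_split,
                           write_split_manifest)


def _save_pair(tmp_path, cube, labels):
    cube_path = tmp_path / "cube.mat"
    gt_path = tmp_path / "gt.mat"
    scipy.io.savemat(cube_path, {"data": cube})
    scipy.io.savemat(gt_path, {"labels": labels})
    return cube_path, gt_path


class TestLoadCube:
    def test_mat_round_trip(self, tmp_path, rng):
        cube = rng.uniform(size=(10, 12, 5))
        labels = rng.integers(0, 4, size=(10, 12))
        hsi, gt = load_cube(*_save_pair(tmp_path, cube, labels))
        np.testing.assert_allclose(hsi.values, cube)
        np.testing.assert_array_equal(gt.labels, labels)
        assert hsi.band_count == 5
        assert np.issubdtype(gt.labels.dtype, np.integer)

    def test_mat_v73_hdf5_container(self, tmp_path, rng):
        """MAT v7.3 files are HDF5 with a 512-byte MATLAB user block and
        column-major arrays; the loader must transpose them back."""
        import h5py
        cube = rng.uniform(size=(6, 7, 3))
        labels = rng.integers(0, 3, size=(6, 7))
        paths = []
        for name, arr in (("cube", cube.T), ("labels", labels.T)):
            path = tmp_path / f"{name}.mat"
            with h5py.File(path, "w", userblock_size=512) as f:
                f[name] = arr
            header = (b"MATLAB 7.3 MAT-file" + b" " * 97 + b"\x00" * 8
                      + bytes([0x00, 0x02]) + b"IM")
            with open(path, "r+b") as fh:
                fh.write(header)
            paths.append(path)
        hsi, gt = load_cube(*paths)
        np.testing.assert_allclose(hsi.values, cube)
        np.testing.assert_array_equal(gt.labels, labels)

    def test_envi_cube_and_labels(self, tmp_path, rng):
        from sgtn import envi
        cube = rng.uniform(size=(5, 6, 4)).astype(np.float32)
        labels = rng.integers(0, 3, size=(5, 6)).astype(np.int32)
        envi.write_envi(cube, tmp_path / "cube.hdr")
        envi.write_envi(labels, tmp_path / "gt.hdr")
        hsi, gt = load_cube(tmp_path / "cube.hdr", tmp_path / "gt.hdr")
        np.testing.assert_allclose(hsi.values, cube)
        np.testing.assert_array_equal(gt.labels, labels)

    def test_degenerate_single_pixel(self, tmp_path):
        hsi, gt = load_cube(*_save_pair(tmp_path, np.ones((1, 1, 1)),
                                        np.zeros((1, 1), dtype=int)))
        assert hsi.shape == (1, 1, 1)
        assert gt.class_count == 0

    def test_dimension_mismatch_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError, match="mismatch"):
            load_cube(*_save_pair(tmp_path, rng.uniform(size=(10, 10, 5)),
                                  np.zeros((9, 10), dtype=int)))

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_cube(tmp_path / "nope.mat", tmp_path / "nope_gt.mat")

    def test_nan_cube_rejected(self):
        bad = np.ones((2, 2, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            HSICube(bad)


class TestRemoveBands:
    @pytest.mark.parametrize("n_bands,dataset,expected", [
        (220, "indian_pines", 200),
        (224, "salinas", 204),
    ])
    def test_default_water_band_lists(self, rng, n_bands, dataset, expected):
        cube = HSICube(rng.uniform(size=(4, 4, n_bands)))
        out = remove_bands(cube, default_band_drops(dataset))
        assert out.band_count == expected
        assert len(out.dropped_bands) == n_bands - expected

    def test_empty_drop_is_identity(self, tiny_cube):
        out = remove_bands(tiny_cube, [])
        np.testing.assert_array_equal(out.values, tiny_cube.values)

    def test_remaining_bands_keep_order(self, tiny_cube):
        out = remove_bands(tiny_cube, [1, 3])
        np.testing.assert_array_equal(out.values,
                                      tiny_cube.values[:, :, [0, 2, 4]])

    @pytest.mark.parametrize("bad", [[0, 0], [99], [-1]])
    def test_invalid_indices_rejected(self, tiny_cube, bad):
        with pytest.raises(ValueError):
            remove_bands(tiny_cube, bad)


class TestNormalize:
    def test_linear_rescale(self):
        band = np.array([[[100.0], [300.0]], [[200.0], [150.0]]])
        out = normalize_cube(HSICube(band))
        assert out.values[1, 0, 0] == pytest.approx(0.5)

    def test_constant_band_maps_to_zero(self, rng):
        v = rng.uniform(size=(3, 3, 2))
        v[:, :, 1] = 7.0
        out = normalize_cube(HSICube(v))
        np.testing.assert_array_equal(out.values[:, :, 1], 0.0)

    def test_per_band_extrema(self, rng):
        out = normalize_cube(HSICube(rng.normal(size=(4, 4, 3)) * 10))
        for b in range(3):
            # independent direct scan of each band
            assert out.values[:, :, b].min() == pytest.approx(0.0)
            assert out.values[:, :, b].max() == pytest.approx(1.0)


class TestStratifiedSplit:
    @pytest.mark.parametrize("dataset", list(TABLES))
    def test_floor_rule_reproduces_published_tables(self, dataset):
        rows, (tf, vf) = TABLES[dataset]
        for name, tr, va, te, total in rows:
            assert split_counts(total, tf, vf) == (tr, va, te), name

    def test_floor_rule_small_n(self):
        assert split_counts(10, 0.10, 0.10) == (1, 0, 9)

    def test_partition_is_disjoint_and_complete(self, tiny_gt):
        split = stratified_split(tiny_gt, 0.2, 0.2, seed=5)
        for c in tiny_gt.classes:
            parts = [set(map(tuple, split.train[c])),
                     set(map(tuple, split.val[c])),
                     set(map(tuple, split.test[c]))]
            assert sum(len(p) for p in parts) == len(set.union(*parts))
            all_coords = set(map(tuple, np.argwhere(tiny_gt.labels == c)))
            assert set.union(*parts) == all_coords

    def test_counts_seed_independent_membership_seed_dependent(self, tiny_gt):
        a = stratified_split(tiny_gt, 0.3, 0.2, seed=1)
        b = stratified_split(tiny_gt, 0.3, 0.2, seed=2)
        assert a.counts().equals(b.counts())
        differs = any(
            set(map(tuple, a.train[c])) != set(map(tuple, b.train[c]))
            for c in tiny_gt.classes
            if 0 < len(a.train[c]) < (tiny_gt.labels == c).sum())
        assert differs

    def test_zero_train_class_warns(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, :2] = 1   # n=2 -> floor(0.1*2)=0
        labels[1, :] = 2
        with pytest.warns(UserWarning, match="0 samples"):
            stratified_split(GroundTruthMap(labels), 0.1, 0.1, seed=0)

    def test_published_train_totals_from_synthetic_label_maps(self):
        # lay out a label map with the published class totals and check the
        # subset totals the rule produces
        expected_totals = {"indian_pines": 1018, "salinas": 533,
                           "pavia_university": 423}
        for dataset, (rows, (tf, vf)) in TABLES.items():
            totals = [r[4] for r in rows]
            flat = np.concatenate([np.full(n, c + 1)
                                   for c, n in enumerate(totals)])
            side = int(np.ceil(np.sqrt(len(flat))))
            labels = np.zeros(side * side, dtype=int)
            labels[:len(flat)] = flat
            split = stratified_split(GroundTruthMap(labels.reshape(side, side)),
                                     tf, vf, seed=0)
            assert split.counts()["train"].sum() == expected_totals[dataset]

    def test_manifest_round_trip(self, tiny_gt, tmp_path):
        split = stratified_split(tiny_gt, 0.2, 0.2, seed=5)
        path = tmp_path / "manifest.csv"
        write_split_manifest(split, path)
        df = read_split_manifest(path)
        assert len(df) == (tiny_gt.labels > 0).sum()
        assert set(df["subset"]) <= {"train", "val", "test"}


class TestPatches:
    def test_interior_window_is_literal_neighborhood(self, tiny_cube):
        p = extract_patch(tiny_cube, (5, 6), 5)
        np.testing.assert_array_equal(p.window,
                                      tiny_cube.values[3:8, 4:9])

    @pytest.mark.parametrize("center", [(0, 0), (0, 11), (9, 0), (9, 11), (1, 1)])
    def test_border_matches_pad_then_crop_oracle(self, tiny_cube, center):
        s = 5
        half = (s - 1) // 2
        padded = np.pad(tiny_cube.values, ((half, half), (half, half), (0, 0)),
                        mode="reflect")
        r, c = center
        expected = padded[r:r + s, c:c + s]
        np.testing.assert_array_equal(
            extract_patch(tiny_cube, center, s).window, expected)

    def test_s1_is_single_spectrum(self, tiny_cube):
        p = extract_patch(tiny_cube, (2, 3), 1)
        np.testing.assert_array_equal(p.window[0, 0], tiny_cube.values[2, 3])

    def test_even_s_and_outside_center_rejected(self, tiny_cube):
        with pytest.raises(ValueError):
            extract_patch(tiny_cube, (2, 3), 4)
        with pytest.raises(ValueError):
            extract_patch(tiny_cube, (99, 0), 3)

    def test_patch_set_labels_and_order(self, tiny_cube, tiny_gt):
        coords = np.argwhere(tiny_gt.labels > 0)[:7]
        patches = make_patch_set(tiny_cube, tiny_gt, coords, 3)
        assert len(patches) == 7
        for patch, (r, c) in zip(patches, coords):
            assert patch.label == tiny_gt.labels[r, c]
            assert patch.center == (r, c)
        assert make_patch_set(tiny_cube, tiny_gt, np.empty((0, 2)), 3) == []

    def test_unlabeled_index_rejected(self, tiny_cube, tiny_gt):
        bg = np.argwhere(tiny_gt.labels == 0)[:1]
        with pytest.raises(ValueError, match="unlabeled"):
            make_patch_set(tiny_cube, tiny_gt, bg, 3)

    def test_patch_arrays_agrees_with_single_extraction(self, tiny_cube, tiny_gt):
        coords = np.argwhere(tiny_gt.labels > 0)[:9]
        X, y = patch_arrays(tiny_cube, tiny_gt, coords, 5)
        for k, (r, c) in enumerate(coords):
            np.testing.assert_allclose(
                X[k], extract_patch(tiny_cube, (r, c), 5).window, atol=1e-6)
            assert y[k] == tiny_gt.labels[r, c]
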