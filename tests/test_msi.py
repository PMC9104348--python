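"""MSI data model, normalization, ion images and segmentation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from metatrack.cohort_sim import generate_msi_phantom
from metatrack.msi import (
    MSIDataset,
    MsiError,
    bisecting_kmeans_segment,
    build_pixel_matrix,
    ion_image,
    load_imzml,
    region_log2fc,
    tic_normalize,
    write_imzml,
)


def _tiny_dataset():
    coords = [(0, 0), (1, 0), (0, 1), (1, 1)]
    mz = np.array([700.0, 750.0, 800.0])
    intensities = [
        np.array([10.0, 0.0, 5.0]),
        np.array([2.0, 8.0, 0.0]),
        np.array([1.0, 1.0, 1.0]),
        np.array([0.0, 4.0, 12.0]),
    ]
    return MSIDataset(coordinates=coords, mz_arrays=[mz.copy() for _ in coords], intensity_arrays=intensities)


class TestDataModel:
    def test_empty_pixel_list_rejected(self):
        with pytest.raises(MsiError):
            MSIDataset(coordinates=[], mz_arrays=[], intensity_arrays=[])

    def test_non_ascending_mz_rejected(self):
        with pytest.raises(MsiError):
            MSIDataset(
                coordinates=[(0, 0)],
                mz_arrays=[np.array([700.0, 600.0])],
                intensity_arrays=[np.array([1.0, 1.0])],
            )

    def test_duplicate_coordinates_rejected(self):
        mz = np.array([700.0])
        with pytest.raises(MsiError):
            MSIDataset(
                coordinates=[(0, 0), (0, 0)],
                mz_arrays=[mz, mz],
                intensity_arrays=[np.array([1.0]), np.array([1.0])],
            )


class TestTicNormalize:
    def test_pixel_sums_are_one(self, phantom):
        ds, _ = phantom
        norm = tic_normalize(ds)
        for it in norm.intensity_arrays:
            assert it.sum() == pytest.approx(1.0, abs=1e-12)

    def test_relative_intensities_within_pixel_unchanged(self):
        ds = _tiny_dataset()
        norm = tic_normalize(ds)
        ratio_before = ds.intensity_arrays[0][0] / ds.intensity_arrays[0][2]
        ratio_after = norm.intensity_arrays[0][0] / norm.intensity_arrays[0][2]
        assert ratio_after == pytest.approx(ratio_before)

    def test_rescaling_a_pixel_is_invisible_after_normalization(self):
        ds = _tiny_dataset()
        ds2 = _tiny_dataset()
        ds2.intensity_arrays[0] = ds2.intensity_arrays[0] * 7.0
        n1, n2 = tic_normalize(ds), tic_normalize(ds2)
        np.testing.assert_allclose(n1.intensity_arrays[0], n2.intensity_arrays[0])

    def test_zero_tic_pixel_excluded(self):
        ds = _tiny_dataset()
        ds.intensity_arrays[2] = np.zeros(3)
        norm = tic_normalize(ds)
        assert norm.excluded_pixels == [2]


class TestIonImage:
    def test_region_specific_peak(self):
        ds = _tiny_dataset()
        img = ion_image(ds, 750.0, window_da=0.5)
        np.testing.assert_allclose(img, [[0.0, 8.0], [1.0, 4.0]])

    def test_offset_peak_outside_window(self):
        ds = _tiny_dataset()
        img = ion_image(ds, 700.002, window_da=0.001)
        assert not img.any()

    def test_partition_additivity_equals_tic(self, phantom):
        ds, _ = phantom
        edges = np.linspace(ds.mz_range[0] - 1, ds.mz_range[1] + 1, 7)
        total = sum(
            ion_image(ds, (lo + hi) / 2, window_da=(hi - lo) / 2)
            for lo, hi in zip(edges, edges[1:])
        )
        tic = np.zeros(ds.shape())
        for (x, y), it in zip(ds.coordinates, ds.intensity_arrays):
            tic[y, x] = it.sum()
        np.testing.assert_allclose(total, tic, rtol=1e-9)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(MsiError):
            ion_image(_tiny_dataset(), 700.0, window_da=0.0)


class TestBuildPixelMatrix:
    def test_single_reference_equals_ion_image(self):
        ds = _tiny_dataset()
        M, zero = build_pixel_matrix(ds, [750.0], tol_da=0.5)
        img = ion_image(ds, 750.0, window_da=0.5)
        flat = [img[y, x] for (x, y) in ds.coordinates]
        np.testing.assert_allclose(M[:, 0], flat)
        assert zero == []

    def test_out_of_range_reference_flagged(self):
        M, zero = build_pixel_matrix(_tiny_dataset(), [999.0], tol_da=0.001)
        assert zero == [0] and not M.any()

    def test_empty_reference_list_rejected(self):
        with pytest.raises(MsiError):
            build_pixel_matrix(_tiny_dataset(), [])


class TestBisectingKmeans:
    def test_k1_single_cluster(self, phantom):
        ds, _ = phantom
        M, _ = build_pixel_matrix(tic_normalize(ds), ds.mz_arrays[0])
        seg = bisecting_kmeans_segment(M, k=1, seed=0)
        assert set(seg.labels) == {0} and seg.split_tree == []

    def test_two_separable_populations_exact(self, rng):
        A = np.tile([10.0, 0.0, 0.0], (30, 1)) + rng.normal(0, 0.01, (30, 3))
        B = np.tile([0.0, 10.0, 0.0], (30, 1)) + rng.normal(0, 0.01, (30, 3))
        M = np.vstack([A, B])
        truth = np.r_[np.zeros(30), np.ones(30)]
        seg = bisecting_kmeans_segment(M, k=2, seed=1)
        assert adjusted_rand_score(truth, seg.labels) == 1.0

    def test_three_region_phantom_recovery(self):
        ds, truth = generate_msi_phantom(width=30, height=30, n_features=50, seed=11)
        M, _ = build_pixel_matrix(tic_normalize(ds), ds.mz_arrays[0])
        seg = bisecting_kmeans_segment(M, k=3, seed=11)
        assert adjusted_rand_score(truth.region_labels.ravel(), seg.labels) >= 0.9

    def test_deterministic_and_sse_decreasing(self):
        ds, _ = generate_msi_phantom(width=15, height=15, n_features=20, seed=2)
        M, _ = build_pixel_matrix(tic_normalize(ds), ds.mz_arrays[0])
        s1 = bisecting_kmeans_segment(M, k=4, seed=5)
        s2 = bisecting_kmeans_segment(M, k=4, seed=5)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        for split in s1.split_tree:
            assert split["sse_after"] < split["sse_before"]

    def test_k_exceeding_pixels_rejected(self):
        with pytest.raises(MsiError):
            bisecting_kmeans_segment(np.ones((4, 2)), k=5)

    def test_contrast_increases_recovery(self):
        """Higher between-region contrast must not worsen recovery."""
        aris = []
        for contrast in (0.2, 0.8, 2.0):
            ds, truth = generate_msi_phantom(
                width=20, height=20, n_features=30,
                region_contrast_log2sd=contrast, seed=3,
            )
            M, _ = build_pixel_matrix(tic_normalize(ds), ds.mz_arrays[0])
            seg = bisecting_kmeans_segment(M, k=3, seed=3)
            aris.append(adjusted_rand_score(truth.region_labels.ravel(), seg.labels))
        assert aris[2] >= aris[0]
        assert aris[2] >= 0.9


class TestRegionFoldChange:
    def test_same_region_all_zeros(self, phantom):
        ds, truth = phantom
        M, _ = build_pixel_matrix(ds, ds.mz_arrays[0])
        fc, _ = region_log2fc(M, truth.region_labels.ravel(), 0, 0)
        np.testing.assert_allclose(fc, 0.0)

    def test_empty_region_rejected(self, phantom):
        ds, truth = phantom
        M, _ = build_pixel_matrix(ds, ds.mz_arrays[0])
        with pytest.raises(MsiError):
            region_log2fc(M, truth.region_labels.ravel(), 0, 99)

    def test_tissue_vs_serum_amplification_envelope(self):
        """Tissue effects planted at 3x the serum log2FC land in the
        reported 2-7x amplification envelope."""
        rng = np.random.default_rng(8)
        serum_log2fc = rng.uniform(-0.5, 0.5, 20)
        effects = {
            "HGSC": np.power(2.0, 3.0 * serum_log2fc),
            "necrotic": np.ones(20),
            "healthy": np.ones(20),
        }
        ds, truth = generate_msi_phantom(
            width=20, height=20, n_features=20, region_effects=effects,
            noise_rsd=0.05, tic_variation=0.0, seed=8,
        )
        M, _ = build_pixel_matrix(ds, ds.mz_arrays[0])
        labels = truth.region_labels.ravel()
        fc, _ = region_log2fc(M, labels, 0, 2)  # HGSC vs healthy
        ratio = np.mean(np.abs(fc)) / np.mean(np.abs(serum_log2fc))
        assert 2.0 <= ratio <= 7.0


class TestImzmlRoundTrip:
    def test_round_trip_within_float32(self, tmp_path):
        ds, _ = generate_msi_phantom(width=6, height=5, n_features=8, seed=2)
        path = tmp_path / "phantom.imzML"
        write_imzml(ds, path)
        back = load_imzml(path)
        assert back.n_pixels == ds.n_pixels
        assert back.coordinates == ds.coordinates
        for a, b in zip(back.intensity_arrays, ds.intensity_arrays):
            np.testing.assert_allclose(a, b, rtol=1e-6)
        for a, b in zip(back.mz_arrays, ds.mz_arrays):
            np.testing.assert_allclose(a, b, rtol=1e-9)
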