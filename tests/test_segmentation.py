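from collections import deque

import numpy as np
import pytest

from mitometry.segmentation import (
    count_nuclei,
    detect_spots,
    positive_fraction,
    segment_objects,
)
from mitometry.synthetic import SpindleSimParams, make_spindle_stack

from conftest import make_grid_2d, make_grid_3d


def flood_fill_components(binary):
    """Exhaustive BFS connected components (full connectivity) oracle."""
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, int)
    offsets = [
        tuple(o - 1 for o in off)
        for off in np.ndindex(*(3,) * binary.ndim)
        if any(o != 1 for o in off)
    ]
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            pos = queue.popleft()
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if all(0 <= n < s for n, s in zip(nb, binary.shape)):
                    if binary[nb] and not labels[nb]:
                        labels[nb] = current
                        queue.append(nb)
    return labels, current


class TestSegmentObjects:
    def test_size_filter_15um2_retains_one_object(self):
        """Of a 10 µm² and a 20 µm² particle, only the larger survives
        the 15 µm² particle-size threshold."""
        img = np.zeros((40, 40))
        img[2:4, 2:7] = 100      # 10 px = 10 µm² at 1 µm² pixels
        img[20:24, 20:25] = 100  # 20 px = 20 µm²
        grid = make_grid_2d({"nuclei": img})
        objects = segment_objects(grid, "nuclei", "otsu", min_size_um2=15.0)
        assert objects.n_objects == 1
        assert objects.table["area_um2"].iloc[0] == pytest.approx(20.0)

    def test_all_zero_image_gives_zero_objects(self):
        grid = make_grid_2d({"c": np.zeros((16, 16))})
        objects = segment_objects(grid, "c", "otsu")
        assert objects.n_objects == 0

    def test_unknown_threshold_method(self):
        grid = make_grid_2d({"c": np.zeros((8, 8))})
        with pytest.raises(ValueError):
            segment_objects(grid, "c", "magic")

    def test_fixed_threshold_string(self):
        img = np.zeros((8, 8))
        img[2, 2] = 10
        grid = make_grid_2d({"c": img})
        objects = segment_objects(grid, "c", "fixed:5")
        assert objects.n_objects == 1
        assert objects.threshold_used == 5.0

    def test_touching_at_corner_counts_as_one_under_full_connectivity(self):
        img = np.zeros((8, 8))
        img[1:3, 1:3] = 1
        img[3:5, 3:5] = 1  # touches only at the corner (2,2)-(3,3)
        grid = make_grid_2d({"c": img})
        objects = segment_objects(grid, "c", "fixed:0.5")
        _, n_oracle = flood_fill_components(img > 0.5)
        assert objects.n_objects == n_oracle == 1

    def test_labeling_matches_flood_fill_oracle(self, rng):
        """Connected-component labeling equals an exhaustive flood fill on
        random binary images up to 32²."""
        for _ in range(100):
            shape = tuple(rng.integers(8, 33, size=2))
            img = (rng.random(shape) < 0.35).astype(float)
            grid = make_grid_2d({"c": img})
            objects = segment_objects(grid, "c", "fixed:0.5")
            oracle_labels, n_oracle = flood_fill_components(img > 0.5)
            assert objects.n_objects == n_oracle
            # identical partition: each oracle component maps to one label
            for k in range(1, n_oracle + 1):
                got = np.unique(objects.labels[oracle_labels == k])
                assert len(got) == 1 and got[0] > 0

    def test_volumes_equal_count_times_voxel_volume(self, rng):
        img = (rng.random((4, 16, 16)) < 0.2).astype(float)
        grid = make_grid_3d({"c": img}, voxel_um=(0.3, 0.1, 0.1))
        objects = segment_objects(grid, "c", "fixed:0.5")
        np.testing.assert_allclose(
            objects.table["volume_um3"],
            objects.table["n_voxels"] * 0.3 * 0.1 * 0.1,
        )


class TestDetectSpots:
    def test_two_planted_gaussians_recovered(self):
        params = SpindleSimParams(
            n_cells=1, icd_um=5.0, alpha_deg=25.0, snr=None, seed=1
        )
        grid, manifest = make_spindle_stack(params)
        spots = detect_spots(grid, "centrosome", expected_sigma_um=0.3)
        assert len(spots) == 2
        truth = np.array(
            [manifest.entities[0]["p1_zyx_um"], manifest.entities[0]["p2_zyx_um"]]
        )
        found = spots.centroids()
        for t in truth:
            err = np.abs(found - t).min(axis=0)
            assert np.all(err <= np.array(grid.voxel_um) * 0.5)

    def test_empty_stack_gives_empty_set(self):
        grid = make_grid_3d({"c": np.zeros((6, 24, 24))})
        assert len(detect_spots(grid, "c", expected_sigma_um=0.3)) == 0

    def test_invalid_sigma(self):
        grid = make_grid_3d({"c": np.zeros((4, 8, 8))})
        with pytest.raises(ValueError):
            detect_spots(grid, "c", expected_sigma_um=0.0)

    def test_recovery_rate_at_snr8(self):
        """At SNR 8, at least 95% of planted pole spots are recovered
        within one voxel of their true position (15-cell stack)."""
        params = SpindleSimParams(
            n_cells=15,
            icd_range_um=(3, 8),
            alpha_range_deg=(0, 60),
            snr=8.0,
            seed=21,
        )
        grid, manifest = make_spindle_stack(params)
        spots = detect_spots(grid, "centrosome", expected_sigma_um=0.3)
        found = spots.centroids()
        voxel = np.array(grid.voxel_um)
        truth = [
            np.array(e[key])
            for e in manifest.entities
            for key in ("p1_zyx_um", "p2_zyx_um")
        ]
        hits = sum(
            bool(np.any(np.all(np.abs(found - t) <= voxel, axis=1))) for t in truth
        )
        assert hits / len(truth) >= 0.95


class TestCountNuclei:
    def test_planted_disjoint_nuclei_counted(self):
        img = np.zeros((60, 60))
        for i in range(4):
            for j in range(5):
                img[3 + 11 * i : 9 + 11 * i, 3 + 11 * j : 9 + 11 * j] = 50
        grid = make_grid_2d({"dapi": img})
        count, objects = count_nuclei(grid, "dapi", min_size_um2=15.0)
        assert count == 20 and objects.n_objects == 20

    def test_empty_image_gives_zero(self):
        grid = make_grid_2d({"dapi": np.zeros((32, 32))})
        count, _ = count_nuclei(grid, "dapi")
        assert count == 0

    def test_subthreshold_nucleus_dropped(self):
        img = np.zeros((80, 80))
        for k in range(10):
            img[5 + 7 * k : 10 + 7 * k, 5:10] = 50  # 25 µm² each
        img[5:8, 40:43] = 50  # 9 µm² — below the 15 µm² cut
        grid = make_grid_2d({"dapi": img})
        count, _ = count_nuclei(grid, "dapi", min_size_um2=15.0)
        assert count == 10


class TestPositiveFraction:
    @staticmethod
    def grid_with_objects(means):
        nuc = np.zeros((30, 30))
        marker = np.zeros((30, 30))
        for i, m in enumerate(means):
            nuc[2 + 6 * i : 6 + 6 * i, 2:6] = 10
            marker[2 + 6 * i : 6 + 6 * i, 2:6] = m
        return make_grid_2d({"nuclei": nuc, "edu": marker})

    def test_all_equal_means_fraction_one(self):
        grid = self.grid_with_objects([40, 40, 40])
        objects = segment_objects(grid, "nuclei", "fixed:5")
        assert positive_fraction(objects, grid, "edu") == pytest.approx(1.0)

    def test_half_above_cutoff(self):
        """Means {100, 10}: the 50%-of-max cutoff is 50, so half qualify."""
        grid = self.grid_with_objects([100, 10])
        objects = segment_objects(grid, "nuclei", "fixed:5")
        assert positive_fraction(objects, grid, "edu") == pytest.approx(0.5)

    def test_absolute_rule(self):
        grid = self.grid_with_objects([100, 10, 30])
        objects = segment_objects(grid, "nuclei", "fixed:5")
        frac = positive_fraction(objects, grid, "edu", rule=("absolute", 20.0))
        assert frac == pytest.approx(2 / 3)

    def test_missing_marker_channel(self):
        grid = self.grid_with_objects([10])
        objects = segment_objects(grid, "nuclei", "fixed:5")
        with pytest.raises(KeyError):
            positive_fraction(objects, grid, "nope")

    def test_zero_objects_undefined(self):
        grid = make_grid_2d({"nuclei": np.zeros((8, 8)), "edu": np.zeros((8, 8))})
        objects = segment_objects(grid, "nuclei", "otsu")
        with pytest.raises(ValueError):
            positive_fraction(objects, grid, "edu")
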