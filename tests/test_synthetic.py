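import json

import numpy as np
import pytest

from mitometry.synthetic import (
    ColocSimParams,
    GroundTruthManifest,
    RosetteSimParams,
    SizingError,
    SpindleSimParams,
    make_cilium_stack,
    make_coloc_stack,
    make_neurite_field,
    make_rosette_section,
    make_spindle_stack,
)


class TestManifest:
    def test_json_round_trip_lossless(self, tmp_path):
        manifest = GroundTruthManifest(
            kind="spindle",
            seed=3,
            params={"icd_um": 5.123456789012345, "voxel_um": [0.3, 0.1, 0.1]},
            entities=[{"cell_id": 0, "alpha_deg": 29.999999999999996}],
        )
        path = tmp_path / "m.json"
        manifest.to_json(path)
        back = GroundTruthManifest.from_json(path)
        assert back == manifest

    def test_from_json_string(self):
        manifest = GroundTruthManifest(kind="x", seed=0, params={})
        assert GroundTruthManifest.from_json(manifest.to_json()) == manifest


class TestSpindlePhantom:
    def test_zero_tilt_shares_z(self):
        grid, manifest = make_spindle_stack(
            SpindleSimParams(n_cells=3, alpha_deg=0.0, icd_um=4.0, snr=None, seed=0)
        )
        for e in manifest.entities:
            assert e["p1_zyx_um"][0] == pytest.approx(e["p2_zyx_um"][0], abs=1e-12)

    def test_fixed_seed_byte_identical(self):
        p = SpindleSimParams(n_cells=2, snr=8.0, seed=7)
        g1, m1 = make_spindle_stack(p)
        g2, m2 = make_spindle_stack(p)
        assert g1.intensities.tobytes() == g2.intensities.tobytes()
        assert m1.to_json() == m2.to_json()

    def test_planted_trigonometry(self):
        """alpha=30, ICD=6: pole distance 6 µm, z-difference 3 µm."""
        grid, manifest = make_spindle_stack(
            SpindleSimParams(n_cells=4, alpha_deg=30.0, icd_um=6.0, snr=None, seed=1)
        )
        for e in manifest.entities:
            p1 = np.array(e["p1_zyx_um"])
            p2 = np.array(e["p2_zyx_um"])
            assert np.linalg.norm(p2 - p1) == pytest.approx(6.0, abs=1e-9)
            assert abs(p2[0] - p1[0]) == pytest.approx(3.0, abs=1e-9)

    def test_oversized_separation_rejected(self):
        with pytest.raises(SizingError):
            make_spindle_stack(
                SpindleSimParams(n_cells=1, icd_um=30.0, cell_box_xy_um=18.0)
            )

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SpindleSimParams(alpha_deg=95.0)
        with pytest.raises(ValueError):
            SpindleSimParams(icd_um=-1.0)
        with pytest.raises(ValueError):
            SpindleSimParams(snr=0.0)


class TestColocPhantom:
    def test_target_one_all_inside(self):
        grid, manifest = make_coloc_stack(
            ColocSimParams(target_m1=1.0, snr=None, seed=0)
        )
        a = grid.channel("A") > 0.5
        b = grid.channel("B") > 0.5
        assert np.all(b[a])
        for e in manifest.entities:
            if e.get("object") == "A":
                assert e["n_inside_b"] == e["n_voxels"]

    def test_target_zero_disjoint(self):
        grid, _ = make_coloc_stack(ColocSimParams(target_m1=0.0, snr=None, seed=0))
        a = grid.channel("A") > 0.5
        b = grid.channel("B") > 0.5
        assert not np.any(a & b)

    def test_planted_count_exact_for_half(self):
        """target 0.5 with uniform intensity: planted inside-count is
        exactly half the A voxels, and the manifest records it."""
        grid, manifest = make_coloc_stack(
            ColocSimParams(target_m1=0.5, snr=None, seed=2)
        )
        a = grid.channel("A") > 0.5
        b = grid.channel("B") > 0.5
        n_a = int(a.sum())
        n_in = int((a & b).sum())
        assert n_in * 2 == n_a
        assert manifest.params["planted_inside_voxels"] == n_in
        assert manifest.params["planted_m1"] == pytest.approx(0.5)

    def test_partial_object_hits_exact_count(self):
        params = ColocSimParams(
            n_objects_a=3, n_objects_b=3, target_m1=0.4, snr=None, seed=5
        )
        grid, manifest = make_coloc_stack(params)
        a = grid.channel("A") > 0.5
        b = grid.channel("B") > 0.5
        expected = int(round(0.4 * a.sum()))
        assert int((a & b).sum()) == expected
        # planted M1 within one voxel's intensity share of the target
        assert abs(manifest.params["planted_m1"] - 0.4) <= 0.5 / a.sum() + 1e-12

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            make_coloc_stack(ColocSimParams(n_objects_b=0, target_m1=0.5))

    def test_determinism(self):
        p = ColocSimParams(target_m1=0.3, snr=8.0, seed=11)
        g1, m1 = make_coloc_stack(p)
        g2, m2 = make_coloc_stack(p)
        assert g1.intensities.tobytes() == g2.intensities.tobytes()
        assert m1.to_json() == m2.to_json()


class TestRosettePhantom:
    def test_theta_ninety_pair_parallel_to_tangent(self):
        grid, manifest = make_rosette_section(
            RosetteSimParams(n_mitoses=1, theta_list_deg=[90.0], seed=0)
        )
        e = manifest.entities[0]
        center = np.array(manifest.params["center_xy_um"])
        mid = np.array(e["midpoint_xy_um"])
        axis = np.array(e["p2_xy_um"]) - np.array(e["p1_xy_um"])
        radial = (mid - center) / np.linalg.norm(mid - center)
        assert abs(float(np.dot(axis, radial))) < 1e-9

    def test_theta_zero_pair_along_radius(self):
        grid, manifest = make_rosette_section(
            RosetteSimParams(n_mitoses=1, theta_list_deg=[0.0], seed=0)
        )
        e = manifest.entities[0]
        center = np.array(manifest.params["center_xy_um"])
        mid = np.array(e["midpoint_xy_um"])
        axis = np.array(e["p2_xy_um"]) - np.array(e["p1_xy_um"])
        radial = (mid - center) / np.linalg.norm(mid - center)
        cosang = abs(np.dot(axis, radial) / np.linalg.norm(axis))
        assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_asym_fraction_exact_allocation(self):
        grid, manifest = make_rosette_section(
            RosetteSimParams(
                lumen_radius_um=95.0, n_mitoses=100, asym_fraction=0.6, seed=3
            )
        )
        classes = [e["division_class"] for e in manifest.entities]
        assert classes.count("asymmetric") == 60
        assert classes.count("symmetric") == 40

    def test_packing_limit(self):
        with pytest.raises(ValueError):
            make_rosette_section(
                RosetteSimParams(lumen_radius_um=5.0, n_mitoses=100,
                                 asym_fraction=0.5)
            )

    def test_requires_theta_or_fraction(self):
        with pytest.raises(ValueError):
            RosetteSimParams(n_mitoses=3)


class TestCiliumPhantom:
    def test_straight_arc_length_exact(self):
        _, manifest = make_cilium_stack(5.0, tortuosity=0.0, seed=1)
        poly = np.array(manifest.entities[0]["polyline_zyx_um"])
        arc = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)).sum()
        assert arc == pytest.approx(5.0, abs=1e-9)
        chord = np.linalg.norm(poly[-1] - poly[0])
        assert chord == pytest.approx(5.0, abs=1e-9)

    def test_curved_arc_length_exact(self):
        _, manifest = make_cilium_stack(5.0, tortuosity=0.5, seed=2)
        poly = np.array(manifest.entities[0]["polyline_zyx_um"])
        arc = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)).sum()
        assert arc == pytest.approx(5.0, abs=1e-9)
        assert np.linalg.norm(poly[-1] - poly[0]) < 5.0  # genuinely curved

    def test_seed_reproducible(self):
        g1, m1 = make_cilium_stack(4.0, 0.3, seed=5)
        g2, m2 = make_cilium_stack(4.0, 0.3, seed=5)
        assert g1.intensities.tobytes() == g2.intensities.tobytes()
        assert m1.to_json() == m2.to_json()

    def test_length_exceeding_stack_rejected(self):
        with pytest.raises(SizingError):
            make_cilium_stack(50.0, 0.0, shape_um=(5.0, 5.0, 5.0))

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            make_cilium_stack(0.0)


class TestNeuriteField:
    def test_exact_pixel_count(self):
        grid, manifest = make_neurite_field(
            100.0, 4, 10, pixel_um=(1.0, 1.0), seed=0
        )
        assert int((grid.channel("tubb3") > 0).sum()) == 100
        assert manifest.params["n_foreground_px"] == 100

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            make_neurite_field(100.0, 0, 0, seed=0)
        with pytest.raises(ValueError):
            make_neurite_field(100.0, 5, 3, seed=0)

    def test_manifest_density_arithmetic(self):
        _, manifest = make_neurite_field(120.0, 3, 8, pixel_um=(0.5, 0.5), seed=1)
        p = manifest.params
        assert p["tubb3_density_um2_per_cell"] == pytest.approx(
            p["area_um2_planted"] / 8
        )
        # voxel-quantised area within one pixel of the request
        assert abs(p["area_um2_planted"] - 120.0) <= 0.25


class TestSerialization:
    def test_manifest_entities_json_serialisable(self):
        for maker, args in [
            (make_cilium_stack, (3.0, 0.2)),
            (make_neurite_field, (50.0, 2, 5)),
        ]:
            _, manifest = maker(*args, seed=1)
            json.loads(manifest.to_json())
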