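"""Displacement estimation and mesh propagation on phantoms with known motion."""

import numpy as np
import pytest

from aortastrain import (
    MeshSequence,
    PhantomConfig,
    TrackingParams,
    cycle_closure_error,
    estimate_displacement,
    make_phantom,
    propagate_mesh,
)
from aortastrain.tracking import DisplacementField


class TestEstimateDisplacement:
    def test_identity_pair_gives_zero_displacement_full_confidence(self, cyl48):
        cfg, series, gt, _ = cyl48
        pts = gt.surface_points(6, 8)
        f = estimate_displacement(series.volumes[0], series.volumes[0], pts, series.affine)
        assert np.abs(f.displacements).max() < 0.01 * cfg.voxel_spacing_mm
        assert f.confidence.min() > 0.99

    def test_constructed_integer_shift_recovered(self):
        """A volume index-shifted by exactly 2 voxels along x is the oracle.
        Noise textures the volume so every patch is unique and the full 3D
        shift is observable (a noise-free tube constrains only the normal
        component)."""
        cfg = PhantomConfig(grid_shape=(48, 48, 48), radius_mm=5.0, n_phases=4,
                            distension_fraction=0.05, noise_sd=40.0, seed=2)
        series, gt = make_phantom(cfg)
        vol = series.volumes[0]
        shifted = np.roll(vol, 2, axis=0)
        pts = gt.surface_points(6, 8)
        f = estimate_displacement(vol, shifted, pts, series.affine)
        expected = np.array([2 * cfg.voxel_spacing_mm, 0.0, 0.0])
        err = np.linalg.norm(f.displacements - expected, axis=1)
        assert err.max() < 0.25 * cfg.voxel_spacing_mm

    def test_distension_radial_displacement_within_quarter_voxel(self, cyl48):
        """Analytic wall motion of the distending phantom is the oracle."""
        cfg, series, gt, _ = cyl48
        pts = gt.surface_points(6, 10)
        k = cfg.peak_phase - 1
        moved = gt.deform(pts, k)
        truth = gt.deform(pts, k + 1) - moved
        f = estimate_displacement(series.volumes[k], series.volumes[k + 1],
                                  moved, series.affine)
        err = np.linalg.norm(f.displacements - truth, axis=1)
        assert np.mean(err) < 0.25 * cfg.voxel_spacing_mm
        assert f.confidence.mean() > 0.5

    def test_flat_patch_gets_zero_confidence(self, cyl48):
        cfg, series, _, _ = cyl48
        center = cfg.extent_mm / 2  # deep inside the uniform lumen
        f = estimate_displacement(series.volumes[0], series.volumes[1],
                                  center, series.affine)
        assert f.confidence[0] == 0.0
        np.testing.assert_array_equal(f.displacements[0], 0.0)

    def test_point_outside_volume_rejected(self, cyl48):
        _, series, _, _ = cyl48
        with pytest.raises(ValueError, match="outside the volume"):
            estimate_displacement(series.volumes[0], series.volumes[1],
                                  np.array([[1000.0, 0, 0]]), series.affine)

    def test_translation_equivariance_to_joint_integer_shifts(self, cyl48):
        """Shifting both volumes and the query points by the same integer
        voxel offset must leave the estimated displacements unchanged."""
        cfg, series, gt, _ = cyl48
        shift_vox = np.array([3, 0, 0])
        va = np.roll(series.volumes[2], shift_vox[0], axis=0)
        vb = np.roll(series.volumes[3], shift_vox[0], axis=0)
        pts = gt.surface_points(5, 8)
        base = estimate_displacement(series.volumes[2], series.volumes[3], pts, series.affine)
        moved = estimate_displacement(va, vb, pts + shift_vox * cfg.voxel_spacing_mm,
                                      series.affine)
        np.testing.assert_allclose(moved.displacements, base.displacements,
                                   atol=0.05 * cfg.voxel_spacing_mm)

    def test_noise_never_raises_confidence(self):
        base = dict(grid_shape=(48, 48, 48), radius_mm=5.0, n_phases=4,
                    distension_fraction=0.05, seed=11)
        confs = []
        for sd in (0.0, 20.0, 60.0):
            series, gt = make_phantom(PhantomConfig(noise_sd=sd, **base))
            pts = gt.surface_points(5, 8)
            f = estimate_displacement(series.volumes[0], series.volumes[1],
                                      pts, series.affine)
            confs.append(f.confidence.mean())
        assert confs[0] >= confs[1] >= confs[2]

    def test_nonfinite_displacement_rejected_by_field(self):
        with pytest.raises(ValueError, match="non-finite"):
            DisplacementField(np.zeros((1, 3)), np.array([[np.nan, 0, 0]]), np.ones(1))


class TestPropagation:
    @staticmethod
    def _mesh(series, target=1000):
        from conftest import build_reference_mesh
        return build_reference_mesh(series, target)

    def test_motionless_series_keeps_mesh_fixed(self):
        cfg = PhantomConfig(grid_shape=(48, 48, 48), radius_mm=5.0, n_phases=4,
                            distension_fraction=0.0)
        series, _ = make_phantom(cfg)
        mesh = self._mesh(series)
        seq = propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)
        dev = np.abs(seq.node_positions - seq.node_positions[0]).max()
        assert dev < 0.02 * cfg.voxel_spacing_mm

    def test_rigid_translation_recovered_per_phase(self):
        cfg = PhantomConfig(grid_shape=(64, 64, 64), radius_mm=6.0, n_phases=6,
                            distension_fraction=0.0, rigid_translation_mm=(3.0, 0, 0))
        series, _ = make_phantom(cfg)
        mesh = self._mesh(series, 1500)
        seq = propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)
        for k in range(1, cfg.n_phases):
            offset = np.array([3.0, 0, 0]) * cfg.amplitude(k)
            err = np.linalg.norm(seq.node_positions[k] - (seq.node_positions[0] + offset),
                                 axis=1)
            assert err.max() < 0.25 * cfg.voxel_spacing_mm

    def test_distension_peak_radius_within_quarter_voxel(self, cyl48, cyl48_seq):
        cfg, _, _, _ = cyl48
        c = cfg.extent_mm / 2
        nodes0 = cyl48_seq.node_positions[0]
        peak = cyl48_seq.node_positions[cfg.peak_phase]
        interior = np.abs(nodes0[:, 2] - c[2]) < 8.0
        r0 = np.hypot(*(nodes0[interior, :2] - c[:2]).T)
        rp = np.hypot(*(peak[interior, :2] - c[:2]).T)
        assert np.mean(rp) == pytest.approx(1.05 * np.mean(r0),
                                            abs=0.25 * cfg.voxel_spacing_mm)

    def test_connectivity_and_node_count_preserved(self, cyl48, cyl48_seq):
        _, _, _, mesh = cyl48
        assert cyl48_seq.n_nodes == len(mesh.vertices)
        np.testing.assert_array_equal(cyl48_seq.triangles, np.asarray(mesh.faces))
        assert np.all(np.isfinite(cyl48_seq.node_positions))


class TestCycleClosure:
    def test_motionless_closure_is_zero(self):
        cfg = PhantomConfig(grid_shape=(48, 48, 48), radius_mm=5.0, n_phases=4,
                            distension_fraction=0.0)
        series, _ = make_phantom(cfg)
        from conftest import build_reference_mesh

        mesh = build_reference_mesh(series, 1000)
        seq = propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)
        closure = cycle_closure_error(seq, cfg.voxel_spacing_mm)
        assert closure["mean_voxel"] < 0.02

    def test_periodic_phantom_closes_below_half_voxel(self, cyl48, cyl48_seq):
        cfg, _, _, _ = cyl48
        closure = cycle_closure_error(cyl48_seq, cfg.voxel_spacing_mm)
        assert closure["mean_voxel"] < 0.5

    def test_drift_correction_never_increases_closure(self, cyl48):
        cfg, series, _, mesh = cyl48
        params = TrackingParams(drift_correction=True)
        seq_dc = propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces),
                                series, params)
        seq = propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)
        c_dc = cycle_closure_error(seq_dc, cfg.voxel_spacing_mm)
        c = cycle_closure_error(seq, cfg.voxel_spacing_mm)
        assert c_dc["mean_voxel"] <= c["mean_voxel"]
        # linear redistribution leaves the reference phase untouched
        np.testing.assert_array_equal(seq_dc.node_positions[0], seq.node_positions[0])

    def test_sequence_without_residual_rejected(self):
        seq = MeshSequence(np.array([[0, 1, 2]]), np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="closure residual"):
            cycle_closure_error(seq)
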