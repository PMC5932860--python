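"""Shared fixtures: phantoms and meshes reused across the suite.

Heavy artefacts (image series, propagated mesh sequences, the demonstration
pipeline run) are session-scoped so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortastrain import (
    PhantomConfig,
    TrackingParams,
    decimate,
    extract_surface,
    make_phantom,
    propagate_mesh,
    segment_lumen,
    smooth_volume_preserving,
)


def build_reference_mesh(series, target_faces: int, smooth_iters: int = 10):
    mask = segment_lumen(series.volumes[0], series.affine)
    mesh = extract_surface(mask)
    mesh = decimate(mesh, target_faces)
    return smooth_volume_preserving(mesh, smooth_iters)


@pytest.fixture(scope="session")
def mesh_builder():
    return build_reference_mesh


@pytest.fixture(scope="session")
def cyl48():
    """Small distending cylinder: 48^3 grid, 5 mm radius, 6 phases, 5%."""
    cfg = PhantomConfig(grid_shape=(48, 48, 48), radius_mm=5.0, n_phases=6,
                        distension_fraction=0.05)
    series, gt = make_phantom(cfg)
    mesh = build_reference_mesh(series, 1200)
    return cfg, series, gt, mesh


@pytest.fixture(scope="session")
def cyl48_seq(cyl48):
    cfg, series, gt, mesh = cyl48
    return propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)


@pytest.fixture(scope="session")
def cyl96():
    """Reference-resolution distending cylinder: 96^3, 0.625 mm, 10 phases."""
    cfg = PhantomConfig(grid_shape=(96, 96, 96), radius_mm=8.0, n_phases=10,
                        distension_fraction=0.05)
    series, gt = make_phantom(cfg)
    return cfg, series, gt


@pytest.fixture(scope="session")
def cyl96_mesh_raw(cyl96):
    _, series, _ = cyl96
    return extract_surface(segment_lumen(series.volumes[0], series.affine))


@pytest.fixture(scope="session")
def cyl96_mesh(cyl96_mesh_raw):
    return smooth_volume_preserving(decimate(cyl96_mesh_raw, 3000), 10)


@pytest.fixture(scope="session")
def cyl96_seq(cyl96, cyl96_mesh):
    _, series, _ = cyl96
    mesh = cyl96_mesh
    return propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)


@pytest.fixture(scope="session")
def rigid_tracked():
    """Rigid translation+rotation phantom tracked through the images."""
    cfg = PhantomConfig(grid_shape=(64, 64, 64), radius_mm=6.0, n_phases=6,
                        distension_fraction=0.0, rigid_translation_mm=(2.0, 1.0, 0.0),
                        rigid_rotation_deg=3.0)
    series, gt = make_phantom(cfg)
    mesh = build_reference_mesh(series, 1500)
    seq = propagate_mesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), series)
    return cfg, gt, mesh, seq


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full curved-aorta pipeline at reference conditions (8/5/3% regional
    distension, noise at 5% of lumen-background contrast)."""
    from aortastrain import demo_config, run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    cfg = demo_config(str(out), seed=1)
    manifest = run_pipeline(cfg)
    return cfg, manifest, out


@pytest.fixture(scope="session")
def sphere_mask():
    """Digitised 10 mm sphere at 0.625 mm voxels (analytic area/volume known)."""
    from aortastrain.meshing import BinaryMask

    n, sp = 64, 0.625
    aff = np.diag([sp] * 3 + [1.0])
    aff[:3, 3] = sp / 2
    idx = np.indices((n, n, n)).reshape(3, -1).T * sp + sp / 2
    d = np.linalg.norm(idx - n * sp / 2, axis=1) - 10.0
    vol = (np.clip(0.5 - d / sp, 0, 1) * 400).reshape(n, n, n)
    return segment_lumen(vol, aff, 200.0)
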