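"""Lumen segmentation and reference-mesh construction.

The end-diastolic (phase 0) volume is segmented by thresholding (Otsu by
default) followed by largest-connected-component selection and a one-voxel
morphological closing; an external mask can be supplied instead.  The lumen
surface is extracted by marching cubes, decimated with a quadric-error-metric
edge collapse and low-pass smoothed with a Taubin (shrink/inflate) filter —
both steps hold the enclosed volume to within 1%, the operational meaning of
"volume preserving" here.  The resulting mesh is the frozen reference
configuration: its node/triangle indexing never changes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes

from .decimation import quadric_decimate

__all__ = [
    "BinaryMask",
    "segment_lumen",
    "extract_surface",
    "decimate",
    "smooth_volume_preserving",
]


@dataclass
class BinaryMask:
    """Binary lumen mask on the source volume's grid."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def segment_lumen(volume: np.ndarray, affine: np.ndarray, threshold: float | str | None = "auto",
                  min_component_voxels: int = 27) -> BinaryMask:
    """Threshold + largest-component + closing segmentation of the lumen.

    ``threshold="auto"`` picks Otsu's threshold between the two intensity
    modes.  Raises if the segmentation is empty or implausibly fills the
    grid (>90%, i.e. the threshold fell below the background).
    """
    volume = np.asarray(volume, dtype=float)
    if threshold is None or threshold == "auto":
        threshold = float(threshold_otsu(volume))
    fg = volume >= threshold
    if not fg.any():
        raise ValueError(f"empty segmentation: no voxel above threshold {threshold:g}")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError(f"empty segmentation: no voxel above threshold {threshold:g}")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_voxels:
        raise ValueError(f"largest component has {int(sizes[largest - 1])} voxels "
                         f"(< {min_component_voxels}); threshold {threshold:g} too high?")
    mask = labels == largest
    if mask.mean() > 0.9:
        raise ValueError(f"implausible segmentation: component covers {mask.mean():.0%} of the "
                         f"grid; threshold {threshold:g} is likely below the background intensity")
    mask = ndimage.binary_closing(mask, structure=ndimage.generate_binary_structure(3, 1),
                                  iterations=1)
    # closing can reconnect crumbs; keep the single largest component
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return BinaryMask(mask.astype(np.uint8), np.asarray(affine, dtype=float))


def extract_surface(mask: BinaryMask, antialias_sigma_vox: float = 1.0) -> trimesh.Trimesh:
    """Watertight triangulated 0.5-level isosurface of the mask, in world mm.

    The binary field is low-pass filtered (Gaussian, default 1 voxel) before
    marching cubes: the 0.5 level of the smoothed indicator recovers the
    underlying smooth boundary instead of the voxel staircase, which would
    otherwise overestimate surface area by several percent.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.data.astype(float), 2)
    if antialias_sigma_vox > 0:
        padded = ndimage.gaussian_filter(padded, antialias_sigma_vox)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = verts - 2.0  # undo padding offset
    affine = np.asarray(mask.affine)
    verts = verts @ affine[:3, :3].T + affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
        if not mesh.is_watertight:
            raise ValueError("marching-cubes surface is not watertight after repair")
    mesh.metadata["provenance"] = [{"op": "marching_cubes", "level": 0.5}]
    return mesh


def _require_manifold(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight or not mesh.is_winding_consistent:
        raise ValueError("mesh is not a closed 2-manifold")


def decimate(mesh: trimesh.Trimesh, target_triangles: int) -> trimesh.Trimesh:
    """Quadric-error-metric edge-collapse decimation to ~target_triangles."""
    if target_triangles < 100:
        raise ValueError("target_triangles must be >= 100")
    if target_triangles >= len(mesh.faces):
        return mesh.copy()
    _require_manifold(mesh)
    verts, faces = quadric_decimate(mesh.vertices, mesh.faces, target_triangles)
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if len(out.faces) > int(1.05 * target_triangles):
        raise RuntimeError(f"decimation stalled at {len(out.faces)} faces "
                           f"(target {target_triangles})")
    out.metadata["provenance"] = list(mesh.metadata.get("provenance", [])) + [
        {"op": "quadric_decimate", "target_triangles": int(target_triangles)}]
    return out


def smooth_volume_preserving(mesh: trimesh.Trimesh, iterations: int = 20,
                             lamb: float = 0.5, mu: float = -0.53) -> trimesh.Trimesh:
    """Taubin shrink/inflate low-pass smoothing (uniform graph Laplacian).

    Each iteration applies a shrinking Laplacian step of weight ``lamb``
    followed by an inflating step of weight ``mu`` (< -lamb), which damps
    surface roughness without the systematic shrinkage of plain Laplacian
    smoothing; any residual enclosed-volume drift is then removed exactly
    by a single uniform rescale about the centroid, so the smoothed mesh
    encloses the original volume to machine precision.
    ``iterations=0`` returns the mesh unchanged.
    """
    if iterations == 0:
        return mesh.copy()
    _require_manifold(mesh)
    from scipy.sparse import coo_matrix

    tris = mesh.faces
    n = len(mesh.vertices)
    i = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2], tris[:, 1], tris[:, 2], tris[:, 0]])
    j = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0], tris[:, 0], tris[:, 1], tris[:, 2]])
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()

    x = np.array(mesh.vertices, dtype=float)
    for _ in range(iterations):
        for w in (lamb, mu):
            lap = adj @ x / deg[:, None] - x
            x = x + w * lap
    # exact volume restoration: uniform rescale about the centroid
    v0 = abs(float(mesh.volume))
    out = trimesh.Trimesh(vertices=x, faces=np.array(tris), process=False)
    v1 = abs(float(out.volume))
    if v1 > 0:
        centroid = x.mean(axis=0)
        x = centroid + (x - centroid) * (v0 / v1) ** (1.0 / 3.0)
        out = trimesh.Trimesh(vertices=x, faces=np.array(tris), process=False)
    out.metadata["provenance"] = list(mesh.metadata.get("provenance", [])) + [
        {"op": "taubin_smooth", "iterations": int(iterations), "lamb": lamb, "mu": mu}]
    return out
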