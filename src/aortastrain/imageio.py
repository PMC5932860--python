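"""Multi-phase image containers and file I/O.

Volumes are scalar 3D arrays indexed ``[i, j, k]`` with a shared 4x4
voxel-to-world affine (world coordinates in mm).  NIfTI is handled by
nibabel, MetaImage (.mha/.mhd) by SimpleITK.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["ImageSeries", "read_volume", "write_volume"]


@dataclass
class ImageSeries:
    """Ordered multi-phase 3D volumes sharing one voxel-to-world affine.

    Parameters
    ----------
    volumes : list of ndarray
        One scalar volume per cardiac phase; phase 0 is the reference
        (end-diastole analogue).  All volumes share a grid shape.
    affine : (4, 4) ndarray
        Voxel index -> world mm map.
    phase_times : ndarray, optional
        Normalised phase times in [0, 1); defaults to uniform spacing.
    """

    volumes: list[np.ndarray]
    affine: np.ndarray
    phase_times: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.volumes) < 2:
            raise ValueError("an ImageSeries needs at least 2 phases")
        shape = self.volumes[0].shape
        for i, v in enumerate(self.volumes):
            if v.ndim != 3 or v.shape != shape:
                raise ValueError(f"phase {i} shape {v.shape} != phase 0 shape {shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.phase_times is None:
            self.phase_times = np.arange(len(self.volumes)) / len(self.volumes)

    @property
    def n_phases(self) -> int:
        return len(self.volumes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def write(self, out_dir: str | Path, fmt: str = "nii.gz", extra_manifest: dict | None = None) -> Path:
        """Write one file per phase plus a JSON manifest; returns manifest path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        for i, vol in enumerate(self.volumes):
            name = f"phase_{i:02d}.{fmt}"
            write_volume(vol, self.affine, out / name)
            files.append(name)
        manifest = {
            "n_phases": self.n_phases,
            "files": files,
            "affine": self.affine.tolist(),
            "spacing_mm": self.spacing.tolist(),
            "phase_times": np.asarray(self.phase_times).tolist(),
        }
        if extra_manifest:
            manifest.update(extra_manifest)
        mpath = out / "series.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        return mpath

    @classmethod
    def read(cls, manifest_path: str | Path) -> "ImageSeries":
        mpath = Path(manifest_path)
        if mpath.is_dir():
            mpath = mpath / "series.json"
        meta = json.loads(mpath.read_text())
        vols = []
        affine = np.asarray(meta["affine"])
        for name in meta["files"]:
            vol, aff = read_volume(mpath.parent / name)
            vols.append(vol)
        return cls(vols, affine, np.asarray(meta["phase_times"]))


def _is_metaimage(path: Path) -> bool:
    return path.suffix.lower() in {".mha", ".mhd"}


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D volume; returns ``(data, affine)`` with world units in mm."""
    path = Path(path)
    if _is_metaimage(path):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # sitk is zyx
        affine = _sitk_affine(img)
        return np.asarray(data, dtype=float), affine
    img = nib.load(str(path))
    # nibabel affines are RAS mm
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_metaimage(path):
        img = sitk.GetImageFromArray(np.asarray(data, dtype=np.float32).transpose(2, 1, 0))
        direction = affine[:3, :3] / np.linalg.norm(affine[:3, :3], axis=0)
        img.SetSpacing(tuple(np.linalg.norm(affine[:3, :3], axis=0)))
        img.SetOrigin(tuple(affine[:3, 3]))
        img.SetDirection(tuple(direction.ravel()))
        sitk.WriteImage(img, str(path), useCompression=True)
        return
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def _sitk_affine(img: sitk.Image) -> np.ndarray:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing())
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing
    affine[:3, 3] = np.asarray(img.GetOrigin())
    return affine
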