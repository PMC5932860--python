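"""Regional partition of the aortic mesh and PPSA summaries.

The thoracic aorta is split by four landmark cut planes ordered along the
flow direction — sinotubular junction (STJ), brachiocephalic artery origin,
left subclavian artery origin, and the diaphragm level — into ascending
aorta, aortic arch and descending thoracic aorta.  Elements proximal to the
STJ or distal to the diaphragm are excluded; "global" covers the three
included segments.  Classification is by element centroid against the
planes' signed distances (normals oriented downstream), which is
deterministic and unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .strain import PPSAMap, StrainField

__all__ = ["RegionLandmarks", "partition", "regional_summary", "peak_of_mean_summary"]

PLANE_ORDER = ("stj", "bca", "lsa", "diaphragm")
REGION_ORDER = ("ascending", "arch", "descending")
EXCLUDED = ("pre_stj", "post_diaphragm")


@dataclass
class RegionLandmarks:
    """Cut planes (point + downstream unit normal, mm) bounding the segments."""

    planes: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        missing = set(PLANE_ORDER) - set(self.planes)
        if missing:
            raise ValueError(f"missing landmark planes: {sorted(missing)}")
        norm = {}
        for name, (p, n) in self.planes.items():
            n = np.asarray(n, dtype=float)
            ln = np.linalg.norm(n)
            if ln == 0:
                raise ValueError(f"zero normal for plane {name!r}")
            norm[name] = (np.asarray(p, dtype=float), n / ln)
        self.planes = norm

    @classmethod
    def from_dict(cls, d: dict) -> "RegionLandmarks":
        return cls({k: (np.asarray(v["point"]), np.asarray(v["normal"])) for k, v in d.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionLandmarks":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {k: {"point": p.tolist(), "normal": n.tolist()} for k, (p, n) in self.planes.items()}

    def signed_distance(self, name: str, points: np.ndarray) -> np.ndarray:
        p, n = self.planes[name]
        return (np.atleast_2d(points) - p) @ n


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    return np.linalg.norm(points - (a + t[:, None] * ab), axis=1)


def partition(nodes: np.ndarray, triangles: np.ndarray, landmarks: RegionLandmarks) -> np.ndarray:
    """Per-element region labels from centroid positions vs the cut planes.

    An element belongs to a segment when its centroid lies downstream of the
    segment's upstream plane and upstream of its downstream plane.  On a
    folded vessel (the arch brings ascending and descending limbs close
    together) a plane's half-space can also cut the opposite limb, so a
    centroid may satisfy more than one segment's condition; such claims are
    resolved by proximity to the chord between the claiming segment's two
    plane anchor points.  Labels are total-exhaustive over {pre_stj,
    ascending, arch, descending, post_diaphragm}; a plane set leaving a
    segment empty yields a zero-element region (downstream summaries report
    it as absent).
    """
    centroids = np.asarray(nodes)[np.asarray(triangles)].mean(axis=1)
    d = {name: landmarks.signed_distance(name, centroids) for name in PLANE_ORDER}
    anchor = {name: landmarks.planes[name][0] for name in PLANE_ORDER}

    # (label, claim condition, chord endpoints for the proximity tie-break)
    segments = [
        ("pre_stj", d["stj"] < 0, (anchor["stj"], anchor["stj"])),
        ("ascending", (d["stj"] >= 0) & (d["bca"] < 0), (anchor["stj"], anchor["bca"])),
        ("arch", (d["bca"] >= 0) & (d["lsa"] < 0), (anchor["bca"], anchor["lsa"])),
        ("descending", (d["lsa"] >= 0) & (d["diaphragm"] < 0), (anchor["lsa"], anchor["diaphragm"])),
        ("post_diaphragm", d["diaphragm"] >= 0, (anchor["diaphragm"], anchor["diaphragm"])),
    ]
    labels = np.full(len(centroids), "post_diaphragm", dtype=object)
    best = np.full(len(centroids), np.inf)
    for name, claim, (a, b) in segments:
        dist = np.where(claim, _dist_to_segment(centroids, a, b), np.inf)
        take = dist < best
        labels[take] = name
        best = np.minimum(best, dist)
    return labels


def regional_summary(ppsa_map: PPSAMap, labels: np.ndarray,
                     area_weighted: bool = True) -> pd.DataFrame:
    """Per-region (and global) mean/SD/min/max of element PPSA.

    The mean is area-weighted by reference-configuration element area unless
    ``area_weighted=False``; "global" covers all included (ascending, arch,
    descending) valid elements.  Empty regions are absent from the table.
    """
    labels = np.asarray(labels, dtype=object)
    rows = []
    included = np.isin(labels, REGION_ORDER) & ppsa_map.valid
    groups = [(r, (labels == r) & ppsa_map.valid) for r in REGION_ORDER]
    groups.append(("global", included))
    for name, sel in groups:
        if not sel.any():
            continue
        vals = ppsa_map.ppsa[sel]
        w = ppsa_map.areas_ref[sel] if area_weighted else np.ones(sel.sum())
        mean = float(np.average(vals, weights=w))
        sd = float(np.sqrt(np.average((vals - mean) ** 2, weights=w)))
        rows.append({"region": name, "mean_ppsa_pct": mean, "sd_ppsa_pct": sd,
                     "min_ppsa_pct": float(vals.min()), "max_ppsa_pct": float(vals.max()),
                     "n_elements": int(sel.sum()), "area_mm2": float(ppsa_map.areas_ref[sel].sum())})
    return pd.DataFrame(rows)


def peak_of_mean_summary(field: StrainField, labels: np.ndarray,
                         area_weighted: bool = True) -> pd.DataFrame:
    """Alternative aggregation: regional mean principal strain per phase,
    then the temporal peak of that mean, in percent."""
    labels = np.asarray(labels, dtype=object)
    rows = []
    included = np.isin(labels, REGION_ORDER) & field.valid
    groups = [(r, (labels == r) & field.valid) for r in REGION_ORDER]
    groups.append(("global", included))
    for name, sel in groups:
        if not sel.any():
            continue
        w = field.areas_ref[sel] if area_weighted else np.ones(sel.sum())
        per_phase = np.array([np.average(field.principal_max[k, sel], weights=w)
                              for k in range(field.principal_max.shape[0])])
        rows.append({"region": name, "peak_of_mean_ppsa_pct": 100.0 * per_phase.max(),
                     "peak_phase": int(per_phase.argmax()), "n_elements": int(sel.sum())})
    return pd.DataFrame(rows)
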