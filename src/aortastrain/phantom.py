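"""Synthetic multi-phase deforming-vessel phantom with analytic ground truth.

The phantom emulates a contrast-filled thoracic-aorta lumen on ECG-gated CT:
a bright tube on a darker background at ~0.6 mm isotropic resolution,
reconstructed at 10 phases over the cardiac cycle.  Two geometries are
provided: a straight cylinder (pure distension / axial stretch, closed-form
strain) and a "candy-cane" curved aorta (ascending limb, semicircular arch,
descending limb) with optionally region-specific distension.

Motion model
------------
Every phase ``k`` scales the motion by a half-sine amplitude
``a_k = sin(pi * k / n_phases)``: zero at the reference phase 0, peaking at
mid-cycle (the systole analogue), and returning to zero at phase
``n_phases`` — the motion is periodic, so a full cycle closes on itself.
Wall points move radially away from the (static) centerline by a factor
``1 + rho(s) * a_k`` where ``rho`` is the distension fraction (optionally a
per-region value blended smoothly along the centerline), plus an optional
axial stretch for the straight cylinder and an optional superimposed rigid
translation/rotation.

Because the deformation is an analytic map, displacement and in-plane
Green-Lagrange principal strain are available in closed form at any surface
point: for a radial scale ``s_r = 1 + rho * a`` the circumferential strain
is ``(s_r^2 - 1)/2``, and on the arch the axial stretch of a point at tube
angle ``phi`` is ``(c + r*s_r*cos(phi)) / (c + r*cos(phi))`` for centerline
radius ``c`` (smaller than the circumferential stretch whenever ``r < c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .imageio import ImageSeries

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "make_phantom",
    "analytic_strain_at",
    "finite_difference_principal_strain",
]

REGIONS = ("ascending", "arch", "descending")


@dataclass
class PhantomConfig:
    """Parameters of the synthetic deforming-vessel image series.

    Defaults mirror a routine pre-TAVR gated CT reconstruction: 0.625 mm
    isotropic voxels and 10 cardiac phases.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing_mm: float = 0.625
    n_phases: int = 10
    geometry: str = "straight_cylinder"  # or "curved_aorta"
    radius_mm: float = 8.0
    distension_fraction: float = 0.05
    regional_distension: dict[str, float] | None = None  # curved_aorta only
    longitudinal_stretch_fraction: float = 0.0
    lumen_intensity: float = 400.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    rigid_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rigid_rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.distension_fraction < 0:
            raise ValueError("distension_fraction must be >= 0")
        if self.radius_mm <= 2 * self.voxel_spacing_mm:
            raise ValueError("radius_mm must exceed 2 voxels for the lumen to be resolvable")
        if self.geometry not in ("straight_cylinder", "curved_aorta"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "curved_aorta" and self.longitudinal_stretch_fraction != 0:
            raise ValueError("longitudinal stretch is only supported for the straight cylinder")
        if self.regional_distension is not None:
            unknown = set(self.regional_distension) - set(REGIONS)
            if unknown:
                raise ValueError(f"unknown regions {sorted(unknown)}; expected {REGIONS}")
            if self.geometry != "curved_aorta":
                raise ValueError("regional_distension requires the curved_aorta geometry")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_spacing_mm

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_spacing_mm] * 3 + [1.0])
        # voxel centers: index 0 sits half a voxel inside the volume
        aff[:3, 3] = self.voxel_spacing_mm / 2.0
        return aff

    def amplitude(self, phase: int | np.ndarray) -> np.ndarray:
        """Half-sine temporal motion profile; 0 at phase 0 and phase n_phases."""
        return np.sin(np.pi * np.asarray(phase, dtype=float) / self.n_phases)

    @property
    def peak_amplitude(self) -> float:
        return float(self.amplitude(np.arange(self.n_phases)).max())

    @property
    def peak_phase(self) -> int:
        return int(np.argmax(self.amplitude(np.arange(self.n_phases))))


# ---------------------------------------------------------------------------
# geometry helpers


class _Centerline:
    """Densely sampled vessel centerline with per-sample region labels."""

    def __init__(self, points: np.ndarray, tangents: np.ndarray, arclen: np.ndarray,
                 region_breaks: tuple[float, float], arch_center: np.ndarray | None,
                 arch_radius: float | None):
        self.points = points
        self.tangents = tangents
        self.arclen = arclen
        self.region_breaks = region_breaks  # (end of ascending, end of arch)
        self.arch_center = arch_center
        self.arch_radius = arch_radius
        self.tree = cKDTree(points)
        self.total_length = float(arclen[-1])

    def foot(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest centerline sample for each point: (arclength s, index)."""
        _, idx = self.tree.query(np.atleast_2d(pts))
        return self.arclen[idx], idx

    def region_of_s(self, s: np.ndarray) -> np.ndarray:
        l1, l2 = self.region_breaks
        out = np.full(np.shape(s), "descending", dtype=object)
        out[np.asarray(s) < l2] = "arch"
        out[np.asarray(s) < l1] = "ascending"
        return out


def _build_curved_centerline(cfg: PhantomConfig, step: float = 0.25) -> _Centerline:
    ext = cfg.extent_mm
    r = cfg.radius_mm
    c_arch = 2.5 * r
    center_x, center_y = ext[0] / 2.0, ext[1] / 2.0
    z_bottom = 0.12 * ext[2]
    z_arch = ext[2] - c_arch - r - 0.06 * ext[2]
    if z_arch <= z_bottom:
        raise ValueError("grid too small to contain the curved vessel; enlarge grid_shape or shrink radius_mm")
    x_asc, x_desc = center_x + c_arch, center_x - c_arch
    l_asc = z_arch - z_bottom
    l_arch = np.pi * c_arch

    s_asc = np.arange(0.0, l_asc, step)
    p_asc = np.stack([np.full_like(s_asc, x_asc), np.full_like(s_asc, center_y), z_bottom + s_asc], axis=1)
    t_asc = np.tile([0.0, 0.0, 1.0], (len(s_asc), 1))

    theta = np.arange(0.0, np.pi, step / c_arch)
    p_arch = np.stack([center_x + c_arch * np.cos(theta),
                       np.full_like(theta, center_y),
                       z_arch + c_arch * np.sin(theta)], axis=1)
    t_arch = np.stack([-np.sin(theta), np.zeros_like(theta), np.cos(theta)], axis=1)

    s_desc = np.arange(0.0, l_asc + step, step)
    p_desc = np.stack([np.full_like(s_desc, x_desc), np.full_like(s_desc, center_y), z_arch - s_desc], axis=1)
    t_desc = np.tile([0.0, 0.0, -1.0], (len(s_desc), 1))

    points = np.concatenate([p_asc, p_arch, p_desc])
    tangents = np.concatenate([t_asc, t_arch, t_desc])
    arclen = np.concatenate([s_asc, l_asc + theta * c_arch, l_asc + l_arch + s_desc])
    return _Centerline(points, tangents, arclen, (l_asc, l_asc + l_arch),
                       np.array([center_x, center_y, z_arch]), c_arch)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """C1 ramp from 0 to 1 over u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Analytic displacement and strain of the phantom's motion.

    ``displacement(points, phase)`` returns world-mm displacement vectors of
    reference (phase 0) material points at the given phase;
    ``principal_strain(points, phase)`` the in-plane maximum principal
    Green-Lagrange strain at reference lumen-surface points.
    """

    config: PhantomConfig
    centerline: _Centerline | None = field(default=None, repr=False)
    _blend_width_mm: float = 4.0

    # -- temporal ------------------------------------------------------
    def amplitude(self, phase: int | np.ndarray) -> np.ndarray:
        return self.config.amplitude(phase)

    # -- geometry ------------------------------------------------------
    @property
    def _cyl_axis_center(self) -> np.ndarray:
        return self.config.extent_mm / 2.0

    @property
    def cylinder_length_mm(self) -> float:
        return 0.75 * self.config.extent_mm[2]

    def rho_at_s(self, s: np.ndarray) -> np.ndarray:
        """Distension fraction along the centerline (blended at region joints)."""
        cfg = self.config
        if cfg.regional_distension is None or self.centerline is None:
            return np.full(np.shape(s), cfg.distension_fraction)
        rho = {r: cfg.regional_distension.get(r, cfg.distension_fraction) for r in REGIONS}
        l1, l2 = self.centerline.region_breaks
        w = self._blend_width_mm
        s = np.asarray(s, dtype=float)
        out = np.full(s.shape, rho["ascending"])
        out = out + (rho["arch"] - rho["ascending"]) * _smoothstep((s - (l1 - w / 2)) / w)
        out = out + (rho["descending"] - rho["arch"]) * _smoothstep((s - (l2 - w / 2)) / w)
        return out

    def _decompose(self, points: np.ndarray):
        """Split reference points into centerline foot, radial offset, arclength."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.config.geometry == "straight_cylinder":
            c = self._cyl_axis_center
            foot = np.column_stack([np.full(len(pts), c[0]), np.full(len(pts), c[1]), pts[:, 2]])
            s = pts[:, 2] - (c[2] - self.cylinder_length_mm / 2.0)
            return foot, pts - foot, s
        s, idx = self.centerline.foot(pts)
        foot = self.centerline.points[idx]
        return foot, pts - foot, s

    def _rigid(self, pts: np.ndarray, phase: int) -> np.ndarray:
        cfg = self.config
        a = float(self.amplitude(phase))
        t = a * np.asarray(cfg.rigid_translation_mm, dtype=float)
        ang = np.deg2rad(a * cfg.rigid_rotation_deg)
        g = cfg.extent_mm / 2.0
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        return (pts - g) @ rot.T + g + t

    def _rigid_inverse(self, pts: np.ndarray, phase: int) -> np.ndarray:
        cfg = self.config
        a = float(self.amplitude(phase))
        t = a * np.asarray(cfg.rigid_translation_mm, dtype=float)
        ang = np.deg2rad(a * cfg.rigid_rotation_deg)
        g = cfg.extent_mm / 2.0
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
        return (pts - g - t) @ rot.T + g

    def deform(self, points: np.ndarray, phase: int) -> np.ndarray:
        """Map reference material points to their phase-``phase`` positions."""
        cfg = self.config
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a = float(self.amplitude(phase))
        foot, v, s = self._decompose(pts)
        scale = 1.0 + self.rho_at_s(s) * a
        out = foot + v * scale[:, None]
        if cfg.geometry == "straight_cylinder" and cfg.longitudinal_stretch_fraction:
            z0 = self._cyl_axis_center[2]
            sz = 1.0 + cfg.longitudinal_stretch_fraction * a
            out[:, 2] = z0 + (out[:, 2] - z0) * sz
        return self._rigid(out, phase)

    def displacement(self, points: np.ndarray, phase: int) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.deform(pts, phase) - pts

    # -- strain --------------------------------------------------------
    def principal_strain(self, points: np.ndarray, phase: int, tol_mm: float = 1.0) -> np.ndarray:
        """Closed-form maximum principal Green-Lagrange strain at surface points."""
        cfg = self.config
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        foot, v, s = self._decompose(pts)
        r = np.linalg.norm(v, axis=1)
        if np.any(np.abs(r - cfg.radius_mm) > tol_mm):
            off = float(np.abs(r - cfg.radius_mm).max())
            raise ValueError(f"point off the reference lumen surface by {off:.2f} mm (> {tol_mm} mm)")
        a = float(self.amplitude(phase))
        s_circ = 1.0 + self.rho_at_s(s) * a
        e_circ = (s_circ**2 - 1.0) / 2.0
        s_ax = np.ones_like(e_circ)
        if cfg.geometry == "straight_cylinder":
            s_ax[:] = 1.0 + cfg.longitudinal_stretch_fraction * a
        else:
            cl = self.centerline
            on_arch = (s > cl.region_breaks[0]) & (s < cl.region_breaks[1])
            if np.any(on_arch):
                u = foot[on_arch] - cl.arch_center
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                cosphi = np.einsum("ij,ij->i", v[on_arch], u) / r[on_arch]
                c = cl.arch_radius
                s_ax[on_arch] = (c + r[on_arch] * s_circ[on_arch] * cosphi) / (c + r[on_arch] * cosphi)
        e_ax = (s_ax**2 - 1.0) / 2.0
        return np.maximum(e_circ, e_ax)

    @property
    def ppsa_expected_by_region(self) -> dict[str, float]:
        """Analytic PPSA (%) per region at the peak-amplitude phase."""
        cfg = self.config
        a = cfg.peak_amplitude
        out = {}
        for region in REGIONS:
            rho = cfg.distension_fraction
            if cfg.regional_distension is not None:
                rho = cfg.regional_distension.get(region, rho)
            out[region] = 100.0 * (((1.0 + rho * a) ** 2) - 1.0) / 2.0
        return out

    @property
    def ppsa_expected(self) -> float:
        """Analytic peak principal strain amplitude (%) of the motion."""
        return max(self.ppsa_expected_by_region.values())

    # -- sampling / frames ---------------------------------------------
    def surface_points(self, n_axial: int = 40, n_circ: int = 24,
                       margin_mm: float = 4.0) -> np.ndarray:
        """Regular sample of reference lumen-surface points (ends excluded)."""
        cfg = self.config
        if cfg.geometry == "straight_cylinder":
            c = self._cyl_axis_center
            half = self.cylinder_length_mm / 2.0 - margin_mm
            z = np.linspace(c[2] - half, c[2] + half, n_axial)
            th = np.arange(n_circ) * 2 * np.pi / n_circ
            zz, tt = np.meshgrid(z, th, indexing="ij")
            return np.column_stack([
                c[0] + cfg.radius_mm * np.cos(tt).ravel(),
                c[1] + cfg.radius_mm * np.sin(tt).ravel(),
                zz.ravel(),
            ])
        cl = self.centerline
        s = np.linspace(margin_mm, cl.total_length - margin_mm, n_axial)
        idx = np.searchsorted(cl.arclen, s).clip(0, len(cl.points) - 1)
        pts = []
        th = np.arange(n_circ) * 2 * np.pi / n_circ
        for i in idx:
            p, t = cl.points[i], cl.tangents[i]
            n1 = np.cross(t, [0.0, 1.0, 0.0])
            n1 /= np.linalg.norm(n1)
            n2 = np.cross(t, n1)
            ring = p + cfg.radius_mm * (np.outer(np.cos(th), n1) + np.outer(np.sin(th), n2))
            pts.append(ring)
        return np.concatenate(pts)

    def surface_frame(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-surface tangents (circumferential, axial) at points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        foot, v, s = self._decompose(pts)
        radial = v / np.linalg.norm(v, axis=1, keepdims=True)
        if self.config.geometry == "straight_cylinder":
            axial = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        else:
            _, idx = self.centerline.foot(pts)
            axial = self.centerline.tangents[idx]
        circ = np.cross(axial, radial)
        circ /= np.linalg.norm(circ, axis=1, keepdims=True)
        # re-orthogonalise the axial direction on the arch
        axial = np.cross(radial, circ)
        return circ, axial

    def region_of(self, points: np.ndarray) -> np.ndarray:
        """Region label ('ascending'/'arch'/'descending') of reference points."""
        if self.config.geometry == "straight_cylinder":
            raise ValueError("regions are defined for the curved_aorta geometry only")
        _, _, s = self._decompose(points)
        return self.centerline.region_of_s(s)

    def landmark_planes(self, margin_mm: float = 3.0) -> dict:
        """Region cut planes (point + downstream normal) for the regions module.

        For the curved geometry the four planes sit at: just inside the
        ascending end (sinotubular-junction analogue), the two construction
        joints (brachiocephalic / left-subclavian analogues) and just inside
        the descending end (diaphragm analogue).
        """
        cfg = self.config
        if cfg.geometry == "straight_cylinder":
            c = self._cyl_axis_center
            half = self.cylinder_length_mm / 2.0
            zs = {"stj": c[2] - half + margin_mm, "bca": c[2] - half / 3, "lsa": c[2] + half / 3,
                  "diaphragm": c[2] + half - margin_mm}
            return {k: {"point": [c[0], c[1], z], "normal": [0.0, 0.0, 1.0]} for k, z in zs.items()}
        cl = self.centerline
        l1, l2 = cl.region_breaks
        out = {}
        for name, s in [("stj", margin_mm), ("bca", l1), ("lsa", l2),
                        ("diaphragm", cl.total_length - margin_mm)]:
            i = int(np.searchsorted(cl.arclen, s).clip(0, len(cl.points) - 1))
            out[name] = {"point": cl.points[i].tolist(), "normal": cl.tangents[i].tolist()}
        return out

    def manifest(self) -> dict:
        cfg = self.config
        return {
            "phantom_config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in vars(cfg).items()},
            "ppsa_expected_pct": self.ppsa_expected if cfg.distension_fraction or cfg.regional_distension else 0.0,
            "ppsa_expected_by_region_pct": self.ppsa_expected_by_region,
            "landmarks": self.landmark_planes(),
        }


def analytic_strain_at(gt: GroundTruth, point: np.ndarray, phase: int) -> float | np.ndarray:
    """Maximum principal Green-Lagrange strain of the analytic motion."""
    out = gt.principal_strain(point, phase)
    return float(out[0]) if np.ndim(point) == 1 else out


def finite_difference_principal_strain(gt: GroundTruth, points: np.ndarray,
                                       phase: int, h: float = 1e-3) -> np.ndarray:
    """Numerical principal strain from central differences of the motion map.

    Independent of the closed form: builds the in-plane deformation gradient
    from finite differences of ``gt.deform`` along the surface tangents and
    eigen-decomposes E = (F^T F - I)/2.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t1, t2 = gt.surface_frame(pts)
    cols = []
    for t in (t1, t2):
        dp = (gt.deform(pts + h * t, phase) - gt.deform(pts - h * t, phase)) / (2 * h)
        cols.append(dp)
    # metric of the deformed tangent vectors: C = F^T F in the (t1, t2) frame
    g11 = np.einsum("ij,ij->i", cols[0], cols[0])
    g22 = np.einsum("ij,ij->i", cols[1], cols[1])
    g12 = np.einsum("ij,ij->i", cols[0], cols[1])
    e11, e22, e12 = (g11 - 1) / 2, (g22 - 1) / 2, g12 / 2
    mu = (e11 + e22) / 2
    rad = np.sqrt(((e11 - e22) / 2) ** 2 + e12**2)
    return mu + rad


# ---------------------------------------------------------------------------
# rasterization


def _capped_cylinder_sdf(pts: np.ndarray, center: np.ndarray, radius: float,
                         half_len: float) -> np.ndarray:
    rd = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) - radius
    az = np.abs(pts[:, 2] - center[2]) - half_len
    outside = np.hypot(np.maximum(rd, 0.0), np.maximum(az, 0.0))
    inside = np.minimum(np.maximum(rd, az), 0.0)
    return outside + inside


def make_phantom(config: PhantomConfig) -> tuple[ImageSeries, GroundTruth]:
    """Render the multi-phase image series and its analytic ground truth."""
    cfg = config
    gt = GroundTruth(cfg, _build_curved_centerline(cfg) if cfg.geometry == "curved_aorta" else None)

    # grid fit check at peak deformation
    rho_max = cfg.distension_fraction
    if cfg.regional_distension:
        rho_max = max(cfg.regional_distension.values())
    peak_r = cfg.radius_mm * (1 + rho_max * cfg.peak_amplitude)
    shift = np.linalg.norm(cfg.rigid_translation_mm)
    margin = cfg.voxel_spacing_mm
    if cfg.geometry == "straight_cylinder":
        c = gt._cyl_axis_center
        fits = (peak_r + shift + margin < min(c[0], c[1], cfg.extent_mm[0] - c[0], cfg.extent_mm[1] - c[1]))
    else:
        cl = gt.centerline
        lo = cl.points.min(axis=0) - peak_r - shift - margin
        hi = cl.points.max(axis=0) + peak_r + shift + margin
        fits = np.all(lo > 0) and np.all(hi < cfg.extent_mm)
    if not fits:
        raise ValueError("grid too small to contain the vessel at peak distension; "
                         "enlarge grid_shape or reduce radius/distension/translation")

    idx = np.indices(cfg.grid_shape).reshape(3, -1).T.astype(float)
    aff = cfg.affine
    world = idx @ aff[:3, :3].T + aff[:3, 3]

    rng = np.random.default_rng(cfg.seed)
    has_rigid = np.any(np.asarray(cfg.rigid_translation_mm) != 0) or cfg.rigid_rotation_deg != 0

    # static foot-point cache when there is no rigid motion (centerline is static)
    cache = None
    if cfg.geometry == "curved_aorta" and not has_rigid:
        s, i = gt.centerline.foot(world)
        cache = (np.linalg.norm(world - gt.centerline.points[i], axis=1), s)

    vols = []
    w = cfg.voxel_spacing_mm
    for k in range(cfg.n_phases):
        a = float(cfg.amplitude(k))
        q = gt._rigid_inverse(world, k) if has_rigid else world
        if cfg.geometry == "straight_cylinder":
            sz = 1.0 + cfg.longitudinal_stretch_fraction * a
            d = _capped_cylinder_sdf(q, gt._cyl_axis_center,
                                     cfg.radius_mm * (1 + cfg.distension_fraction * a),
                                     gt.cylinder_length_mm / 2.0 * sz)
        else:
            if cache is not None:
                dist, s = cache
            else:
                s, i = gt.centerline.foot(q)
                dist = np.linalg.norm(q - gt.centerline.points[i], axis=1)
            d = dist - cfg.radius_mm * (1.0 + gt.rho_at_s(s) * a)
        vol = cfg.background_intensity + (cfg.lumen_intensity - cfg.background_intensity) * \
            np.clip(0.5 - d / w, 0.0, 1.0)
        vol = vol.reshape(cfg.grid_shape)
        if cfg.noise_sd > 0:
            vol = vol + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
        vols.append(vol)

    series = ImageSeries(vols, aff)
    return series, gt
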