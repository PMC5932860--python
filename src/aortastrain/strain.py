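"""Per-triangle Green-Lagrange strain and peak principal strain amplitude.

Strain is computed element-wise on the triangulated lumen surface in a total
Lagrangian frame: every phase is compared against the phase-0 (end-diastole)
reference configuration.  For each triangle the in-plane deformation
gradient ``F`` maps the two reference edge vectors, expressed in an
orthonormal in-plane frame of the reference triangle, to the deformed edge
vectors in the deformed triangle's frame; the Green-Lagrange tensor
``E = (F^T F - I)/2`` is by construction invariant to any rigid motion of
the mesh, which is precisely why strain rather than displacement is the
deformation measure of choice for a vessel that translates and rotates with
the heartbeat.

PPSA (peak principal strain amplitude) is the temporal maximum, over the
cycle, of the largest eigenvalue of ``E``, reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tracking import MeshSequence

__all__ = [
    "StrainField",
    "PPSAMap",
    "deformation_gradient",
    "green_lagrange",
    "principal_strain",
    "compute_strain_field",
    "ppsa",
]

DEGENERATE_AREA_MM2 = 1e-9


def _tri_frame(nodes: np.ndarray, tris: np.ndarray):
    """Edge vectors of each triangle expressed in an orthonormal in-plane frame.

    Returns the (M, 2, 2) upper-triangular edge matrix ``[[e1.u1, e2.u1],
    [0, e2.u2]]`` and the (M,) triangle areas.
    """
    a, b, c = nodes[tris[:, 0]], nodes[tris[:, 1]], nodes[tris[:, 2]]
    e1, e2 = b - a, c - a
    n = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(n, axis=1)
    l1 = np.linalg.norm(e1, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u1 = e1 / l1[:, None]
        u2 = np.cross(n, e1)
        u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
    mat = np.empty((len(tris), 2, 2))
    mat[:, 0, 0] = l1
    mat[:, 0, 1] = np.einsum("ij,ij->i", e2, u1)
    mat[:, 1, 0] = 0.0
    mat[:, 1, 1] = np.einsum("ij,ij->i", e2, u2)
    return mat, area


def deformation_gradient(tri_ref: np.ndarray, tri_def: np.ndarray) -> np.ndarray:
    """In-plane 2x2 deformation gradient between two corresponding triangles.

    Exact for the two independent edges: ``F = D R^{-1}`` where ``R`` and
    ``D`` are the reference and deformed edge matrices in their respective
    in-plane orthonormal frames.

    Raises ``ValueError`` on a degenerate (zero-area) triangle.
    """
    ref = np.asarray(tri_ref, dtype=float).reshape(1, 3, 3)
    dfm = np.asarray(tri_def, dtype=float).reshape(1, 3, 3)
    tris = np.array([[0, 1, 2]])
    r, area_r = _tri_frame(ref.reshape(3, 3), tris)
    d, area_d = _tri_frame(dfm.reshape(3, 3), tris)
    if area_r[0] <= DEGENERATE_AREA_MM2 or area_d[0] <= DEGENERATE_AREA_MM2:
        raise ValueError("degenerate (zero-area) triangle")
    return (d[0] @ np.linalg.inv(r[0]))


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain tensor E = (F^T F - I)/2 (symmetrised exactly)."""
    F = np.asarray(F, dtype=float)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(F.shape[-1]))
    return 0.5 * (E + np.swapaxes(E, -1, -2))


def principal_strain(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Largest eigenvalue and unit eigenvector of symmetric 2x2 tensor(s).

    Closed form: ``e_max = mu + sqrt(delta^2 + tau^2)`` with
    ``mu = (E11+E22)/2``, ``delta = (E11-E22)/2``, ``tau = E12``.  The
    eigenvector sign convention is a nonnegative first component (ties:
    nonnegative second component).
    """
    E = np.asarray(E, dtype=float)
    single = E.ndim == 2
    Eb = E.reshape(-1, 2, 2)
    mu = (Eb[:, 0, 0] + Eb[:, 1, 1]) / 2.0
    delta = (Eb[:, 0, 0] - Eb[:, 1, 1]) / 2.0
    tau = Eb[:, 0, 1]
    rad = np.sqrt(delta**2 + tau**2)
    emax = mu + rad
    # eigenvector of the larger eigenvalue
    vec = np.stack([tau, emax - Eb[:, 0, 0]], axis=1)
    small = np.linalg.norm(vec, axis=1) < 1e-15
    vec[small] = [1.0, 0.0]  # isotropic tensor: any direction
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    flip = (vec[:, 0] < 0) | ((vec[:, 0] == 0) & (vec[:, 1] < 0))
    vec[flip] *= -1.0
    if single:
        return float(emax[0]), vec[0]
    return emax, vec


@dataclass
class StrainField:
    """Per-phase, per-triangle in-plane Green-Lagrange strain.

    Attributes
    ----------
    E : (n_phases, M, 2, 2) ndarray
        Strain tensor of each triangle at each phase (phase 0 all zero).
    principal_max : (n_phases, M) ndarray
        Largest eigenvalue per triangle and phase.
    principal_dir : (n_phases, M, 2) ndarray
        Corresponding in-plane unit direction.
    valid : (M,) bool ndarray
        False for triangles degenerate in any phase (excluded downstream).
    """

    E: np.ndarray
    principal_max: np.ndarray
    principal_dir: np.ndarray
    valid: np.ndarray
    triangles: np.ndarray
    areas_ref: np.ndarray

    @property
    def n_excluded(self) -> int:
        return int((~self.valid).sum())


@dataclass
class PPSAMap:
    """Per-element peak principal strain amplitude, in percent."""

    ppsa: np.ndarray          # (M,) %; NaN for excluded elements
    valid: np.ndarray
    triangles: np.ndarray
    areas_ref: np.ndarray
    peak_phase: np.ndarray    # (M,) phase index attaining the element peak

    def nodal(self, n_nodes: int) -> np.ndarray:
        """Area-weighted one-ring average at nodes (visualisation only)."""
        num = np.zeros(n_nodes)
        den = np.zeros(n_nodes)
        w = np.where(self.valid, self.areas_ref, 0.0)
        val = np.where(self.valid, self.ppsa, 0.0)
        for k in range(3):
            np.add.at(num, self.triangles[:, k], w * val)
            np.add.at(den, self.triangles[:, k], w)
        with np.errstate(invalid="ignore"):
            return num / den


def compute_strain_field(seq: MeshSequence) -> StrainField:
    """Green-Lagrange strain of every triangle at every phase vs phase 0."""
    tris = seq.triangles
    n_phases = seq.n_phases
    ref_mat, ref_area = _tri_frame(seq.node_positions[0], tris)
    valid = ref_area > DEGENERATE_AREA_MM2
    M = len(tris)
    E = np.zeros((n_phases, M, 2, 2))
    emax = np.zeros((n_phases, M))
    edir = np.zeros((n_phases, M, 2))
    edir[..., 0] = 1.0
    inv_ref = np.zeros((M, 2, 2))
    inv_ref[valid] = np.linalg.inv(ref_mat[valid])
    for k in range(1, n_phases):
        def_mat, def_area = _tri_frame(seq.node_positions[k], tris)
        valid &= def_area > DEGENERATE_AREA_MM2
        F = def_mat @ inv_ref
        Ek = green_lagrange(F)
        E[k] = Ek
        emax[k], edir[k] = principal_strain(Ek)
    E[:, ~valid] = 0.0
    emax[:, ~valid] = 0.0
    return StrainField(E, emax, edir, valid, tris, ref_area)


def ppsa(field: StrainField, aggregation: str = "element-peak") -> PPSAMap:
    """Peak principal strain amplitude per element, in percent.

    ``aggregation`` is recorded for the regional reduction stage:
    ``"element-peak"`` (default) takes each element's own temporal maximum
    before any regional mean; ``"peak-of-mean"`` leaves the regional stage
    to average per phase and then take the temporal peak.
    """
    if aggregation not in ("element-peak", "peak-of-mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    # the reference phase is identically zero and would mask an all-negative
    # (pure contraction) history, so the temporal peak runs over phases >= 1
    peak_phase = 1 + np.argmax(field.principal_max[1:], axis=0)
    vals = 100.0 * field.principal_max[1:].max(axis=0)
    if np.any(vals[field.valid] < 0):
        warnings.warn("PPSA is negative on some elements (pure contraction); "
                      "values are reported signed", stacklevel=2)
    out = np.where(field.valid, vals, np.nan)
    return PPSAMap(out, field.valid, field.triangles, field.areas_ref, peak_phase)
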