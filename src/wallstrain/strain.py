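"""Green–Lagrange strain analysis on the tracked wall mesh.

Per-element deformation gradients come from constant-strain-triangle (CST)
kinematics on the reference (end-diastolic) mesh; the Green–Lagrange tensor
E = ½(FᵀF − I) is exactly invariant to rigid motion, so rigid probe or
phantom motion produces zero strain by construction.  The per-frame summary
statistic is the reference-area-weighted mean of the first (largest)
principal strain over all valid elements, ε̄ρ(t); its maximum over one
cardiac cycle, ε̄ρ+, divided by the circuit's pulse pressure gives the
primary outcome ε̄ρ+/PP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hemodynamics import CycleWindow
from .mesh import WallMesh
from .tracking import DisplacementField

__all__ = [
    "StrainFrame",
    "StrainSeries",
    "deformation_gradient",
    "green_lagrange",
    "principal_strains",
    "mean_principal_strain",
    "compute_strain_series",
    "max_over_cycle",
    "normalize_strain",
    "percent_change",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrainFrame:
    """Per-element strain state at one frame.

    ``F`` (K, 2, 2) deformation gradients, ``E`` (K, 2, 2) Green–Lagrange
    tensors, ``eps1 >= eps2`` (K,) principal strains, ``areas`` (K,)
    reference element areas in mm², ``valid`` (K,) marks elements whose
    reference triangle was non-degenerate.
    """

    F: np.ndarray
    E: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    areas: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class StrainSeries:
    """Mean principal strain over a cine: ε̄ρ(t), ε̄ρ+, PP, and ε̄ρ+/PP."""

    mean_strain: np.ndarray  # ε̄ρ per frame
    eps_max: float  # ε̄ρ+
    eps_max_frame: int
    pp: float | None  # mm Hg
    eps_norm: float | None  # ε̄ρ+/PP, per mm Hg

    def summary(self) -> dict[str, float]:
        out = {"eps_max": self.eps_max, "eps_max_frame": self.eps_max_frame}
        if self.pp is not None:
            out["pp_mmhg"] = self.pp
            out["eps_norm_per_mmhg"] = self.eps_norm
        return out


def deformation_gradient(
    mesh: WallMesh, nodal_displacements: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element deformation gradients F = I + ∂u/∂X from CST kinematics.

    ``nodal_displacements`` is (N, 2) in the same units as the mesh
    coordinates.  Returns ``(F (K, 2, 2), valid (K,))``; elements with a
    degenerate reference triangle are flagged invalid (F set to identity)
    and logged.
    """
    u = np.asarray(nodal_displacements, dtype=float)
    if u.shape != (len(mesh.nodes), 2):
        raise ValueError("need one 2-D displacement per mesh node")
    tri = mesh.elements
    x_ref = mesh.nodes[tri]  # (K, 3, 2)
    x_def = x_ref + u[tri]
    d_ref = np.stack([x_ref[:, 1] - x_ref[:, 0], x_ref[:, 2] - x_ref[:, 0]], axis=2)
    d_def = np.stack([x_def[:, 1] - x_def[:, 0], x_def[:, 2] - x_def[:, 0]], axis=2)
    det = np.linalg.det(d_ref)
    scale = np.max(np.abs(d_ref), axis=(1, 2)) ** 2
    valid = np.abs(det) > 1e-12 * np.maximum(scale, 1e-30)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("deformation_gradient: skipped %d degenerate elements", n_bad)
    f = np.tile(np.eye(2), (len(tri), 1, 1))
    if valid.any():
        f[valid] = d_def[valid] @ np.linalg.inv(d_ref[valid])
    return f, valid


def green_lagrange(f: np.ndarray) -> np.ndarray:
    """Green–Lagrange strain E = ½(FᵀF − I), symmetrized.

    Works on a single 2×2 matrix or a stack (..., 2, 2).
    """
    f = np.asarray(f, dtype=float)
    c = np.swapaxes(f, -1, -2) @ f
    e = 0.5 * (c - np.eye(2))
    return 0.5 * (e + np.swapaxes(e, -1, -2))


def principal_strains(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal strains (eigenvalues of E) sorted descending.

    Accepts a single symmetric 2×2 tensor or a stack; returns (ε1, ε2)
    with ε1 >= ε2.
    """
    w = np.linalg.eigvalsh(np.asarray(e, dtype=float))
    eps2 = w[..., 0]
    eps1 = w[..., 1]
    return eps1, eps2


def strain_frame(mesh: WallMesh, nodal_displacements: np.ndarray) -> StrainFrame:
    """Full per-element strain state at one frame."""
    f, valid = deformation_gradient(mesh, nodal_displacements)
    e = green_lagrange(f)
    eps1, eps2 = principal_strains(e)
    return StrainFrame(F=f, E=e, eps1=eps1, eps2=eps2,
                       areas=mesh.element_areas(), valid=valid)


def mean_principal_strain(frame: StrainFrame) -> float:
    """Reference-area-weighted mean of ε1 over valid elements."""
    if not frame.valid.any():
        raise ValueError("no valid elements")
    w = frame.areas[frame.valid]
    return float(np.sum(frame.eps1[frame.valid] * w) / np.sum(w))


def compute_strain_series(
    mesh: WallMesh,
    field: DisplacementField,
    pp: float | None = None,
    window: CycleWindow | None = None,
) -> StrainSeries:
    """ε̄ρ(t) over a tracked cine, its cycle maximum, and ε̄ρ+/PP.

    ``pp`` is the circuit (lumen) pulse pressure in mm Hg; when omitted the
    series carries unnormalized strain only.  ``window`` restricts the
    maximum to one cardiac cycle (defaults to all frames).
    """
    means = np.empty(field.n_frames)
    for t in range(field.n_frames):
        means[t] = mean_principal_strain(strain_frame(mesh, field.displacements[t]))
    eps_max, idx = max_over_cycle(means, window)
    eps_norm = normalize_strain(eps_max, pp) if pp is not None else None
    return StrainSeries(mean_strain=means, eps_max=eps_max, eps_max_frame=idx,
                        pp=pp, eps_norm=eps_norm)


def max_over_cycle(
    values: np.ndarray, window: CycleWindow | None = None
) -> tuple[float, int]:
    """Maximum of ε̄ρ(t) within a cycle window and the frame attaining it."""
    values = np.asarray(values, dtype=float)
    if window is None:
        lo, hi = 0, len(values) - 1
    else:
        lo, hi = window.start_index, window.end_index
        if hi >= len(values):
            raise ValueError("window exceeds series length")
    seg = values[lo : hi + 1]
    if seg.size == 0:
        raise ValueError("empty window")
    idx = int(np.argmax(seg))
    return float(seg[idx]), lo + idx


def normalize_strain(eps_max: float, pp: float) -> float:
    """Pulse-pressure-normalized strain ε̄ρ+/PP (per mm Hg)."""
    if pp <= 0:
        raise ValueError("pulse pressure must be positive")
    return eps_max / pp


def percent_change(x: float, baseline: float) -> float:
    """Percent change of ``x`` relative to ``baseline``."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return (x - baseline) / baseline * 100.0
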