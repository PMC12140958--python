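"""Annular finite-element meshing of the vessel wall between two contours.

The region of interest — the wall between manually (or synthetically) drawn
inner and outer contours — is triangulated with a structured annular layout:
nodes on radial layers interpolated between the contours at uniformly spaced
polar angles, each quad split into two triangles.  This is deterministic,
quality-bounded, and trivially annular, which unstructured Delaunay meshing
of the same region is not.

Contours are assumed star-shaped about their common centroid (true for the
near-circular aneurysm cross-sections this pipeline targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point, Polygon

__all__ = [
    "Contour",
    "WallMesh",
    "circle_contour",
    "build_mesh",
    "mesh_quality",
    "read_contours_csv",
    "write_contours_csv",
    "export_mesh_text",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contour:
    """Closed simple polyline in image mm coordinates (origin top-left, y down).

    Points are (N, 2) as (x, y); the closing edge from the last point back to
    the first is implicit.  Orientation is normalized to counter-clockwise
    (positive shoelace area in the stored coordinates).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValueError("contour needs >= 8 (x, y) points")
        # drop an explicit duplicate closing point
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        poly = Polygon(pts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("contour must be a simple (non-self-intersecting) polygon")
        if _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        object.__setattr__(self, "points", pts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def circle_contour(radius: float, center: tuple[float, float], n_points: int = 128) -> Contour:
    """Regular polygon approximation of a circle, for synthetic phantoms."""
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    pts = np.column_stack(
        (center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta))
    )
    return Contour(points=pts)


@dataclass(frozen=True)
class WallMesh:
    """Triangulated annular wall region.

    ``nodes`` (M, 2) mm in the reference (frame-0) configuration, indexed as
    layer-major rings: node ``i * n_circ + j`` sits on radial layer ``i`` at
    circumferential station ``j``.  ``elements`` (K, 3) node indices with
    positive signed area.
    """

    nodes: np.ndarray
    elements: np.ndarray
    n_layers: int
    n_circ: int

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        elements = np.asarray(self.elements, dtype=np.intp)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "elements", elements)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ValueError("nodes must be (M, 2)")
        if elements.ndim != 2 or elements.shape[1] != 3:
            raise ValueError("elements must be (K, 3)")
        areas = self.element_areas()
        if np.any(areas <= 0):
            raise ValueError("all elements must have positive signed area")
        used = np.zeros(len(nodes), dtype=bool)
        used[elements.ravel()] = True
        if not used.all():
            raise ValueError("every node must belong to at least one element")
        if self._n_components() != 1:
            raise ValueError("mesh must be edge-connected (single component)")

    def element_areas(self) -> np.ndarray:
        """Signed reference areas, mm²."""
        p = self.nodes[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (n_edges, 2) sorted node pairs."""
        e = np.vstack(
            [self.elements[:, [0, 1]], self.elements[:, [1, 2]], self.elements[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self):
        """Sparse symmetric node-adjacency matrix (CSR)."""
        e = self.edges()
        m = len(self.nodes)
        data = np.ones(len(e) * 2)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(m, m)).tocsr()

    def _n_components(self) -> int:
        n, _ = connected_components(self.adjacency(), directed=False)
        return int(n)

    @property
    def total_area(self) -> float:
        return float(np.sum(self.element_areas()))


def _polar_radius_interp(contour: Contour, center: np.ndarray) -> callable:
    """Radius-vs-angle interpolant for a star-shaped contour."""
    rel = contour.points - center
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
    r = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # wrap for periodic interpolation
    theta_ext = np.concatenate([theta[-1:] - 2 * np.pi, theta, theta[:1] + 2 * np.pi])
    r_ext = np.concatenate([r[-1:], r, r[:1]])

    def interp(angles: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(angles, 2.0 * np.pi), theta_ext, r_ext)

    return interp


def build_mesh(inner: Contour, outer: Contour, target_edge: float = 1.25) -> WallMesh:
    """Structured annular triangulation of the wall between two contours.

    Node counts are chosen so that radial and circumferential edge lengths
    are approximately ``target_edge`` (mm).  Raises a "contour order" error
    if the inner contour is not strictly inside the outer, and a
    "resolution" error if ``target_edge`` is no smaller than the mean gap.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    if not outer.polygon.contains(inner.polygon):
        raise ValueError("contour order error: inner contour must lie strictly inside outer")
    center = inner.centroid
    r_in = _polar_radius_interp(inner, center)
    r_out = _polar_radius_interp(outer, center)

    theta_dense = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    gap = r_out(theta_dense) - r_in(theta_dense)
    mean_gap = float(np.mean(gap))
    if np.any(gap <= 0):
        raise ValueError("contour order error: contours cross")
    if target_edge >= mean_gap:
        raise ValueError(
            f"resolution error: target_edge {target_edge} mm >= mean wall gap "
            f"{mean_gap:.3f} mm"
        )
    mean_circ = float(np.mean(np.pi * (r_in(theta_dense) + r_out(theta_dense))))
    n_layers = max(1, int(round(mean_gap / target_edge)))
    n_circ = max(8, int(round(mean_circ / target_edge)))

    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    ri, ro = r_in(theta), r_out(theta)
    nodes = np.empty(((n_layers + 1) * n_circ, 2))
    for layer in range(n_layers + 1):
        frac = layer / n_layers
        r = ri + frac * (ro - ri)
        nodes[layer * n_circ : (layer + 1) * n_circ, 0] = center[0] + r * np.cos(theta)
        nodes[layer * n_circ : (layer + 1) * n_circ, 1] = center[1] + r * np.sin(theta)

    elements = []
    for layer in range(n_layers):
        base0 = layer * n_circ
        base1 = (layer + 1) * n_circ
        for j in range(n_circ):
            jn = (j + 1) % n_circ
            quad = (base0 + j, base0 + jn, base1 + jn, base1 + j)
            elements.append((quad[0], quad[1], quad[2]))
            elements.append((quad[0], quad[2], quad[3]))
    elements = np.asarray(elements, dtype=np.intp)

    # enforce positive orientation
    p = nodes[elements]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    flip = (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]) < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    mesh = WallMesh(nodes=nodes, elements=elements, n_layers=n_layers, n_circ=n_circ)

    annulus = outer.polygon.difference(inner.polygon).buffer(0.05 * mean_gap)
    centroids = nodes[elements].mean(axis=1)
    for c in centroids[:: max(1, len(centroids) // 64)]:  # spot-check
        if not annulus.contains(Point(c)):
            raise ValueError("mesh element centroid escaped the wall region")
    return mesh


def mesh_quality(mesh: WallMesh) -> dict[str, float]:
    """Quality metrics: minimum interior angle (deg) and max edge-length ratio."""
    p = mesh.nodes[mesh.elements]
    d0 = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    d1 = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    d2 = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    lengths = np.stack([d0, d1, d2], axis=1)
    min_angle = np.inf
    for i in range(3):
        opp = lengths[:, i]
        e1 = lengths[:, (i + 1) % 3]
        e2 = lengths[:, (i + 2) % 3]
        cos_a = np.clip((e1**2 + e2**2 - opp**2) / (2 * e1 * e2), -1.0, 1.0)
        min_angle = min(min_angle, float(np.min(np.degrees(np.arccos(cos_a)))))
    max_aspect = float(np.max(lengths.max(axis=1) / lengths.min(axis=1)))
    return {"min_angle": min_angle, "max_aspect": max_aspect}


def read_contours_csv(path: str | Path) -> tuple[Contour, Contour]:
    """Read inner/outer contours from CSV.

    Columns: ``contour`` (inner|outer), ``point_index``, ``x_mm``, ``y_mm``.
    Returns (inner, outer).
    """
    df = pd.read_csv(path)
    for col in ("contour", "point_index", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"contour CSV missing column {col!r}")
    out = {}
    for name, grp in df.groupby("contour"):
        grp = grp.sort_values("point_index")
        out[name] = Contour(points=grp[["x_mm", "y_mm"]].to_numpy(float))
    if set(out) != {"inner", "outer"}:
        raise ValueError("contour CSV must contain exactly 'inner' and 'outer' contours")
    return out["inner"], out["outer"]


def write_contours_csv(path: str | Path, inner: Contour, outer: Contour) -> None:
    rows = []
    for name, contour in (("inner", inner), ("outer", outer)):
        for i, (x, y) in enumerate(contour.points):
            rows.append({"contour": name, "point_index": i, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def export_mesh_text(mesh: WallMesh, path: str | Path) -> None:
    """Write the mesh in a simple indexed-triangle text format."""
    with open(path, "w") as fh:
        fh.write(f"nodes {len(mesh.nodes)}\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.6f} {y:.6f}\n")
        fh.write(f"elements {len(mesh.elements)}\n")
        for a, b, c in mesh.elements:
            fh.write(f"{a} {b} {c}\n")
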