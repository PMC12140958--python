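"""Speckle tracking: NCC block matching with subpixel refinement.

Nodal displacements are estimated frame-to-frame by normalized
cross-correlation (NCC) block matching with separable parabolic subpixel
refinement, regularized on the mesh graph, and accumulated into cumulative
displacement fields relative to the end-diastolic reference frame.  Blocks
are re-centered at the node's current (cumulatively displaced) position so
large cyclic excursions stay inside the search window.

Everything here is deterministic: identical inputs give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from scipy.ndimage import map_coordinates

from .cine import CineLoop
from .mesh import WallMesh

__all__ = ["TrackingParams", "DisplacementField", "track_pair", "regularize",
           "accumulate", "track_cine"]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class TrackingParams:
    """Block-matching and regularization parameters (pixel units)."""

    block_halfwidth: int = 8
    search_radius: int = 10
    subpixel: str = "parabolic"
    min_correlation: float = 0.5
    smoothing_weight: float = 0.5
    smoothing_iters: int = 60
    symmetric: bool = True
    refine_iters: int = 3
    mode: str = "reference"

    def __post_init__(self) -> None:
        if self.block_halfwidth < 2:
            raise ValueError("block_halfwidth must be >= 2")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.subpixel not in ("none", "parabolic"):
            raise ValueError("subpixel must be 'none' or 'parabolic'")
        if not -1.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation must lie in [-1, 1]")
        if not 0.0 <= self.smoothing_weight <= 1.0:
            raise ValueError("smoothing_weight must lie in [0, 1]")
        if self.smoothing_iters < 0:
            raise ValueError("smoothing_iters must be >= 0")
        if self.refine_iters < 0:
            raise ValueError("refine_iters must be >= 0")
        if self.mode not in ("reference", "incremental"):
            raise ValueError("mode must be 'reference' or 'incremental'")


@dataclass(frozen=True)
class DisplacementField:
    """Cumulative per-node displacements for each frame, relative to frame 0.

    ``displacements`` (n_frames, n_nodes, 2) in mm as (dx, dy);
    ``scores`` (n_frames, n_nodes) holds the NCC peak of the increment that
    led into each frame (frame 0 scores are 1 by convention).
    """

    displacements: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "displacements", d)
        object.__setattr__(self, "scores", s)
        if d.ndim != 3 or d.shape[2] != 2 or s.shape != d.shape[:2]:
            raise ValueError("displacements must be (T, N, 2) with matching scores")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacements must be finite")
        if np.any(d[0] != 0):
            raise ValueError("frame-0 displacement must be identically zero")

    @property
    def n_frames(self) -> int:
        return int(self.displacements.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.displacements.shape[1])


def _window_sums(search: np.ndarray, block: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset window sums and sums of squares via integral images.

    ``search`` is (N, S, S); returns two (N, O, O) arrays with
    O = S − block + 1.
    """
    n, s, _ = search.shape
    sat = np.zeros((n, s + 1, s + 1))
    sat[:, 1:, 1:] = search.cumsum(axis=1).cumsum(axis=2)
    sat2 = np.zeros((n, s + 1, s + 1))
    sat2[:, 1:, 1:] = (search**2).cumsum(axis=1).cumsum(axis=2)

    def win(table):
        return (
            table[:, block:, block:]
            - table[:, :-block, block:]
            - table[:, block:, :-block]
            + table[:, :-block, :-block]
        )

    return win(sat), win(sat2)


def _refine_subpixel(
    frame_b: np.ndarray,
    templates: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    hw: int,
    iters: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative image-domain subpixel refinement.

    The moving block is re-sampled from ``frame_b`` by cubic spline
    interpolation at the current displacement estimate and the residual
    offset is re-estimated from a 3×3 NCC neighborhood; at convergence the
    residual vanishes, which removes the peak-locking bias of a single
    correlation-surface fit (the fit's gain error only slows convergence,
    it no longer biases the fixed point).
    """
    n = len(cx)
    blk = 2 * hw + 1
    t_mean = templates.mean(axis=(1, 2), keepdims=True)
    tm = templates - t_mean
    tn = np.sqrt((tm**2).sum(axis=(1, 2)))
    ext = np.arange(-hw - 1, hw + 2)
    dx = dx.copy()
    dy = dy.copy()
    for _ in range(iters):
        base_y = (cy + dy)[:, None, None]
        base_x = (cx + dx)[:, None, None]
        yy = np.broadcast_to(base_y + ext[None, :, None], (n, blk + 2, blk + 2))
        xx = np.broadcast_to(base_x + ext[None, None, :], (n, blk + 2, blk + 2))
        win = map_coordinates(
            frame_b, [yy.ravel(), xx.ravel()], order=3, mode="nearest"
        ).reshape(n, blk + 2, blk + 2)
        corr = np.empty((n, 3, 3))
        for oy in range(3):
            for ox in range(3):
                w = win[:, oy : oy + blk, ox : ox + blk]
                wm = w - w.mean(axis=(1, 2), keepdims=True)
                wn = np.sqrt((wm**2).sum(axis=(1, 2)))
                corr[:, oy, ox] = (tm * wm).sum(axis=(1, 2)) / np.maximum(tn * wn, _EPS)
        c0 = corr[:, 1, 1]
        cl, cr = corr[:, 1, 0], corr[:, 1, 2]
        cu, cd = corr[:, 0, 1], corr[:, 2, 1]
        den_x = cl - 2 * c0 + cr
        den_y = cu - 2 * c0 + cd
        with np.errstate(invalid="ignore", divide="ignore"):
            rx = np.where(np.abs(den_x) > _EPS, 0.5 * (cl - cr) / den_x, 0.0)
            ry = np.where(np.abs(den_y) > _EPS, 0.5 * (cu - cd) / den_y, 0.0)
        best = corr.reshape(n, -1).argmax(axis=1)
        by, bx = np.divmod(best, 3)
        step_x = np.where(best == 4, np.clip(np.nan_to_num(rx), -1, 1), bx - 1.0)
        step_y = np.where(best == 4, np.clip(np.nan_to_num(ry), -1, 1), by - 1.0)
        dx = dx + step_x
        dy = dy + step_y
    return dx, dy


def track_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    points_px: np.ndarray,
    params: TrackingParams,
    pixel_spacing: float = 1.0,
    search_center: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Displacement of each point from ``frame_a`` to ``frame_b``.

    For every point a (2·hw+1)² block around its (rounded, clamped) position
    in ``frame_a`` is matched against all integer offsets within
    ``search_radius`` of ``search_center`` (defaults to the point itself) in
    ``frame_b``; the NCC-maximizing offset is refined to subpixel by a
    separable parabolic fit of the correlation surface around the peak,
    optionally followed by ``refine_iters`` rounds of image-domain
    re-sampling refinement.  Passing a ``search_center`` offset from the
    points lets a caller track against a fixed reference frame while keeping
    large cyclic motions inside the search window; the returned displacement
    includes that offset.  Returns ``(displacements_mm (N, 2), scores (N,),
    valid (N,))``.  Flat (zero-variance) blocks and points with no block
    support are flagged invalid with zero displacement and score 0.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape or frame_a.ndim != 2:
        raise ValueError("frames must be equal-shaped 2-D images")
    pts = np.asarray(points_px, dtype=float)
    n = len(pts)
    hw, sr = params.block_halfwidth, params.search_radius
    blk = 2 * hw + 1
    h, w = frame_a.shape
    if blk > min(h, w):
        raise ValueError("block larger than image")

    cx = np.rint(pts[:, 0]).astype(int)
    cy = np.rint(pts[:, 1]).astype(int)
    # no overlap with the image at all -> invalid
    out_of_image = (cx < -hw) | (cx > w - 1 + hw) | (cy < -hw) | (cy > h - 1 + hw)
    cx = np.clip(cx, hw, w - 1 - hw)
    cy = np.clip(cy, hw, h - 1 - hw)
    if search_center is None:
        scx, scy = cx, cy
    else:
        sc = np.asarray(search_center, dtype=float)
        scx = np.clip(np.rint(sc[:, 0]).astype(int), hw, w - 1 - hw)
        scy = np.clip(np.rint(sc[:, 1]).astype(int), hw, h - 1 - hw)

    d_blk = np.arange(-hw, hw + 1)
    blocks = frame_a[
        (cy[:, None, None] + d_blk[None, :, None]),
        (cx[:, None, None] + d_blk[None, None, :]),
    ]  # (N, blk, blk)

    padded = np.pad(frame_b, sr, mode="edge")
    d_sea = np.arange(-hw - sr, hw + sr + 1)
    search = padded[
        (scy[:, None, None] + sr + d_sea[None, :, None]),
        (scx[:, None, None] + sr + d_sea[None, None, :]),
    ]  # (N, S, S)

    npix = blk * blk
    t_sum = blocks.sum(axis=(1, 2))
    t_var = (blocks**2).sum(axis=(1, 2)) - t_sum**2 / npix
    flat = t_var <= _EPS * npix

    num_raw = fftconvolve(search, blocks[:, ::-1, ::-1], mode="valid", axes=(1, 2))
    w_sum, w_sum2 = _window_sums(search, blk)
    w_var = np.maximum(w_sum2 - w_sum**2 / npix, 0.0)
    denom = np.sqrt(np.maximum(t_var[:, None, None] * w_var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = (num_raw - t_sum[:, None, None] * w_sum / npix) / denom
    ncc = np.where(denom > _EPS, np.clip(ncc, -1.0, 1.0), -np.inf)

    o = 2 * sr + 1
    flat_idx = ncc.reshape(n, -1).argmax(axis=1)
    py, px = np.divmod(flat_idx, o)
    scores = ncc.reshape(n, -1)[np.arange(n), flat_idx]

    dx = (px - sr + scx - cx).astype(float)
    dy = (py - sr + scy - cy).astype(float)
    # an exact integer-lag match needs no refinement; fitting a parabola
    # through a perfect peak with asymmetric shoulders would bias it
    perfect = scores >= 1.0 - 1e-7
    if params.subpixel == "parabolic":
        interior = (px > 0) & (px < o - 1) & (py > 0) & (py < o - 1) & ~perfect
        idx = np.flatnonzero(interior)
        c0 = ncc[idx, py[idx], px[idx]]
        cl = ncc[idx, py[idx], px[idx] - 1]
        cr = ncc[idx, py[idx], px[idx] + 1]
        cu = ncc[idx, py[idx] - 1, px[idx]]
        cd = ncc[idx, py[idx] + 1, px[idx]]
        den_x = cl - 2 * c0 + cr
        den_y = cu - 2 * c0 + cd
        with np.errstate(invalid="ignore", divide="ignore"):
            sub_x = np.where(np.abs(den_x) > _EPS, 0.5 * (cl - cr) / den_x, 0.0)
            sub_y = np.where(np.abs(den_y) > _EPS, 0.5 * (cu - cd) / den_y, 0.0)
        sub_x = np.where(np.isfinite(sub_x), sub_x, 0.0)
        sub_y = np.where(np.isfinite(sub_y), sub_y, 0.0)
        dx[idx] += np.clip(sub_x, -0.5, 0.5)
        dy[idx] += np.clip(sub_y, -0.5, 0.5)
        if params.refine_iters > 0 and idx.size:
            rdx, rdy = _refine_subpixel(
                frame_b, blocks[idx], cx[idx], cy[idx], dx[idx], dy[idx],
                hw, params.refine_iters,
            )
            dx[idx], dy[idx] = rdx, rdy

    valid = ~(out_of_image | flat) & np.isfinite(scores)
    dx[~valid] = 0.0
    dy[~valid] = 0.0
    scores = np.where(valid, scores, 0.0)
    disp_mm = np.column_stack((dx, dy)) * pixel_spacing
    return disp_mm, scores, valid


def regularize(
    increments: np.ndarray,
    scores: np.ndarray,
    valid: np.ndarray,
    mesh: WallMesh,
    params: TrackingParams,
) -> np.ndarray:
    """Affine-preserving graph-Laplacian smoothing of one field on the mesh.

    Nodes flagged invalid or scoring below ``min_correlation`` are first
    replaced by the mean of their valid neighbors (falling back to the field
    median for nodes with no valid neighbors).  The field is then split into
    its global rigid part — translation plus the antisymmetric (rotation)
    component of a least-squares affine fit u = b + A·(x − x̄) — and a
    residual; only the residual is smoothed, with ``smoothing_iters`` rounds
    blending each node with its neighbor mean by ``smoothing_weight``.
    Leaving the rigid part untouched matters on a wall mesh only a few
    layers thick: plain neighbor averaging would flatten the real radial
    gradient of a rotation field (u_θ = θ·r) and manufacture shear strain
    from rigid motion, while the deformation-carrying symmetric part stays
    subject to smoothing.  A zero weight or zero iterations leaves valid
    increments untouched.
    """
    x = np.array(increments, dtype=float)
    if x.shape != (len(mesh.nodes), 2):
        raise ValueError("one increment per mesh node required")
    adj = mesh.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    good = valid & (scores >= params.min_correlation)
    if not good.any():
        logger.warning("regularize: no valid nodes; returning zeros")
        return np.zeros_like(x)
    bad = ~good
    if bad.any():
        filled = good.copy()
        for _ in range(len(x)):  # bounded flood fill
            todo = np.flatnonzero(~filled)
            if todo.size == 0:
                break
            n_good_nb = adj[todo] @ filled.astype(float)
            ready = todo[n_good_nb > 0]
            if ready.size == 0:
                med = np.median(x[good], axis=0)
                x[todo] = med
                logger.warning(
                    "regularize: %d isolated invalid nodes set to field median", todo.size
                )
                filled[todo] = True
                break
            w_nb = adj[ready].multiply(filled.astype(float))
            x[ready] = (w_nb @ x) / np.asarray(w_nb.sum(axis=1))
            filled[ready] = True
    if params.smoothing_iters > 0 and params.smoothing_weight > 0:
        centered = mesh.nodes - mesh.nodes.mean(axis=0)
        basis = np.column_stack((np.ones(len(x)), centered))  # (N, 3)
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
        grad = coef[1:].T  # (2, 2) displacement gradient of the affine fit
        spin = 0.5 * (grad - grad.T)
        rigid = coef[0] + centered @ spin.T
        res = x - rigid
        for _ in range(params.smoothing_iters):
            nb_mean = (adj @ res) / deg[:, None]
            res = (1.0 - params.smoothing_weight) * res + params.smoothing_weight * nb_mean
        x = rigid + res
    return x


def accumulate(increments: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Cumulative displacement from ordered per-frame increments.

    ``increments`` is (T−1, N, 2); the result is (T, N, 2) with frame 0 zero.
    """
    inc = np.asarray(increments, dtype=float)
    if inc.ndim != 3 or inc.shape[2] != 2:
        raise ValueError("increments must be (T-1, N, 2)")
    cum = np.zeros((inc.shape[0] + 1, inc.shape[1], 2))
    np.cumsum(inc, axis=0, out=cum[1:])
    return cum


def track_cine(
    cine: CineLoop, mesh: WallMesh, params: TrackingParams | None = None
) -> DisplacementField:
    """Track mesh nodes through a cine loop.

    In the default ``"reference"`` mode each frame's cumulative displacement
    is measured directly against the end-diastolic reference frame: blocks
    stay anchored at the frame-0 node positions while the search window is
    re-centered at the previous frame's cumulative estimate (rounded to the
    nearest pixel), so large cyclic motions stay inside the search range but
    frame-to-frame estimation bias cannot accumulate.  ``"incremental"``
    mode instead estimates consecutive frame-to-frame increments (blocks
    re-centered at node + cumulative displacement) and accumulates them;
    it follows the classical cumulative formulation but lets any persistent
    per-node increment bias grow linearly with frame count.

    Both modes optionally symmetrize each estimate with the time-reversed
    estimate (cancelling the odd, speckle-pattern-dependent part of the
    subpixel bias) and regularize every per-frame field on the mesh graph.
    """
    if params is None:
        params = TrackingParams()
    ps = cine.pixel_spacing
    nodes_px = mesh.nodes / ps
    n_frames = cine.n_frames
    n_nodes = len(mesh.nodes)
    disp = np.zeros((n_frames, n_nodes, 2))
    scores = np.ones((n_frames, n_nodes))
    cum_mm = np.zeros((n_nodes, 2))
    for t in range(n_frames - 1):
        if params.mode == "reference":
            center = nodes_px + np.rint(cum_mm / ps)
            est_mm, sc, valid = track_pair(
                cine.frames[0], cine.frames[t + 1], nodes_px, params,
                pixel_spacing=ps, search_center=center,
            )
            if params.symmetric:
                back_mm, sc_b, valid_b = track_pair(
                    cine.frames[t + 1], cine.frames[0],
                    nodes_px + np.rint(est_mm / ps), params,
                    pixel_spacing=ps, search_center=nodes_px,
                )
                est_mm = 0.5 * (est_mm - back_mm)
                sc = 0.5 * (sc + sc_b)
                valid = valid & valid_b
            cum_mm = regularize(est_mm, sc, valid, mesh, params)
        else:
            points = nodes_px + np.rint(cum_mm / ps)
            inc_mm, sc, valid = track_pair(
                cine.frames[t], cine.frames[t + 1], points, params, pixel_spacing=ps
            )
            if params.symmetric:
                back_mm, sc_b, valid_b = track_pair(
                    cine.frames[t + 1], cine.frames[t],
                    points + np.rint(inc_mm / ps), params, pixel_spacing=ps,
                )
                inc_mm = 0.5 * (inc_mm - back_mm)
                sc = 0.5 * (sc + sc_b)
                valid = valid & valid_b
            inc_mm = regularize(inc_mm, sc, valid, mesh, params)
            cum_mm = cum_mm + inc_mm
        disp[t + 1] = cum_mm
        scores[t + 1] = sc
    return DisplacementField(displacements=disp, scores=scores)
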