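"""Vessel endpoint detection and centerline extraction from binary masks.

Endpoint candidates are leaves of the 3D skeleton, ordered superior
first.  When more than two candidates exist, the first candidate and
the one farthest from it (Euclidean) are kept as inlet and outlet.
The centerline itself is a least-cost path through the 26-connected
foreground voxel graph, with step costs inversely weighted by the
distance-to-background transform so the path hugs the medial axis; it
is then smoothed and resampled to uniform arc-length steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .volume_io import ImageVolume

__all__ = ["Centerline", "detect_endpoints", "select_inlet_outlet",
           "extract_centerline"]

_DT_EPS_MM = 0.1          # guards 1/DT at boundary voxels
_SMOOTH_WINDOW = 5        # moving-average window (points) before resampling

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Centerline:
    """Ordered centerline in world millimetres.

    ``arclength`` is the cumulative chord length starting at 0;
    ``step_mm`` is the uniform resampling interval.
    """

    points: np.ndarray      # (N, 3) mm
    arclength: np.ndarray   # (N,)
    step_mm: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a centerline needs at least 2 points")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def length_mm(self) -> float:
        return float(self.arclength[-1])

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(),
                          self.arclength[-1] - self.arclength[::-1],
                          self.step_mm)

    def project(self, point) -> float:
        """Arc length of the centerline sample nearest to a world point."""
        d = np.linalg.norm(self.points - np.asarray(point, dtype=float), axis=1)
        return float(self.arclength[int(np.argmin(d))])

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "points_mm": self.points.tolist(),
            "arclength_mm": self.arclength.tolist(),
            "step_mm": self.step_mm,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x_mm,y_mm,z_mm",
                   comments="", fmt="%.6f")


def _require_single_component(mask: ImageVolume) -> np.ndarray:
    fg = mask.data.astype(bool)
    if not fg.any():
        raise ValueError("mask is empty")
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n != 1:
        raise ValueError(f"mask must have exactly one connected component, got {n}")
    return fg


def detect_endpoints(mask: ImageVolume) -> np.ndarray:
    """Skeleton-leaf endpoint candidates, in world mm.

    Candidates are skeleton voxels with at most one 26-neighbor, ordered
    by descending world z (most superior first), ties by scan order.
    """
    from skimage.morphology import skeletonize

    fg = _require_single_component(mask)
    skel = skeletonize(fg)
    if not skel.any():  # tiny blobs can skeletonize to nothing
        skel = fg.copy()
    dt = ndimage.distance_transform_edt(fg, sampling=mask.spacing)
    skel = _prune_spurs(skel, dt, mask.spacing)
    neighbor_count = ndimage.convolve(skel.astype(np.uint8),
                                      _STRUCT26.astype(np.uint8),
                                      mode="constant", cval=0) - 1
    leaves = skel & (neighbor_count <= 1)
    if not leaves.any():
        leaves = skel  # e.g. closed loops: fall back to all skeleton voxels
    idx = np.argwhere(leaves)
    idx = np.asarray([_extend_leaf(fg, skel, dt, leaf, mask.spacing)
                      for leaf in idx])
    world = mask.index_to_world(idx).reshape(-1, 3)
    flat = np.ravel_multi_index(idx.T, mask.shape)
    order = np.lexsort((flat, -world[:, 2]))
    return world[order]


def _neighbors26(skel, voxel):
    i, j, k = voxel
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                c = (i + di, j + dj, k + dk)
                if (0 <= c[0] < skel.shape[0] and 0 <= c[1] < skel.shape[1]
                        and 0 <= c[2] < skel.shape[2] and skel[c]):
                    out.append(c)
    return out


def _prune_spurs(skel, dt, spacing, factor: float = 1.5, max_iter: int = 10):
    """Remove short skeleton side branches (voxelization-noise spurs).

    A leaf branch is pruned when its geodesic length up to the first
    junction is below ``factor`` times the vessel radius (distance
    transform) at that junction — such branches point at boundary bumps,
    not real vessel ends.
    """
    skel = skel.copy()
    for _ in range(max_iter):
        neighbor_count = ndimage.convolve(skel.astype(np.uint8),
                                          _STRUCT26.astype(np.uint8),
                                          mode="constant", cval=0) - 1
        leaves = np.argwhere(skel & (neighbor_count <= 1))
        if len(leaves) <= 2:
            break
        removed = False
        for leaf in leaves:
            path = [tuple(leaf)]
            visited = {tuple(leaf)}
            length = 0.0
            cur = tuple(leaf)
            junction = None
            while True:
                if neighbor_count[cur] >= 3 and cur != tuple(leaf):
                    junction = cur
                    break
                nbrs = [n for n in _neighbors26(skel, cur) if n not in visited]
                if len(nbrs) == 0:
                    break
                nxt = nbrs[0]
                length += float(np.linalg.norm((np.asarray(nxt) - cur) * spacing))
                cur = nxt
                path.append(cur)
                visited.add(cur)
                if length > factor * dt.max() + 1:  # certainly a real branch
                    break
            if junction is not None and length < factor * dt[junction]:
                for v in path[:-1]:  # keep the junction itself
                    skel[v] = False
                removed = True
        if not removed:
            break
    return skel


def _extend_leaf(fg, skel, dt, leaf, spacing, depth: int = 16):
    """Push a skeleton leaf along its terminal direction to the mask boundary.

    Thinning retracts tube ends (sometimes by several radii on jagged
    resampled surfaces), so the leaf is marched outward along a direction
    fitted to its terminal skeleton chain.  At every step the position is
    re-centered on the local distance-transform ridge perpendicular to
    the march, which keeps a long march from drifting off the vessel axis
    or sliding along an end face.
    """
    chain = [tuple(leaf)]
    visited = {tuple(leaf)}
    cur = tuple(leaf)
    for _ in range(depth):
        nbrs = [n for n in _neighbors26(skel, cur) if n not in visited]
        if not nbrs:
            break
        cur = nbrs[0]
        chain.append(cur)
        visited.add(cur)
    if len(chain) < 2:
        return leaf
    pts_mm = np.asarray(chain, dtype=float) * spacing
    # least-squares line fit; orient from chain interior toward the leaf
    centered = pts_mm - pts_mm.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ (pts_mm[0] - pts_mm[-1]) < 0:
        direction = -direction

    # two unit vectors spanning the plane perpendicular to the march
    ref = np.zeros(3)
    ref[np.argmin(np.abs(direction))] = 1.0
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    perp_offsets = sorted((a * e1 + b * e2
                           for a in (-1.0, -0.5, 0.0, 0.5, 1.0)
                           for b in (-1.0, -0.5, 0.0, 0.5, 1.0)),
                          key=lambda v: float(v @ v))

    shape = np.asarray(fg.shape)
    step_mm = 0.5 * float(spacing.min())
    pos = np.asarray(leaf, dtype=float) * spacing
    best = np.asarray(leaf)
    for _ in range(400):
        pos = pos + direction * step_mm
        # re-center: hop to the in-plane neighbor with the largest DT
        cand_best, dt_best = None, -1.0
        for off in perp_offsets:  # smallest offsets first: ties don't drift
            p = pos + off * step_mm
            ridx = np.floor(p / spacing + 0.5).astype(int)
            if np.any(ridx < 0) or np.any(ridx >= shape) or not fg[tuple(ridx)]:
                continue
            if dt[tuple(ridx)] > dt_best + 1e-9:
                dt_best = dt[tuple(ridx)]
                cand_best = p
        if cand_best is None:
            break
        pos = cand_best
        best = np.floor(pos / spacing + 0.5).astype(int)
    return best


def select_inlet_outlet(candidates) -> tuple:
    """First candidate and the candidate farthest (Euclidean) from it.

    Ties in the farthest distance are broken by list order.
    """
    cand = np.asarray(candidates, dtype=float).reshape(-1, 3)
    if cand.shape[0] < 2:
        raise ValueError(f"need at least 2 endpoint candidates, got {cand.shape[0]}")
    inlet = cand[0]
    d = np.linalg.norm(cand - inlet, axis=1)
    outlet = cand[int(np.argmax(d))]  # argmax returns the first maximum
    return inlet, outlet


def _recenter_on_ridge(pts, mask, fg, dt, n_iter: int = 6, step_mm: float = 0.5):
    """Pull each path point up the distance-transform ridge.

    Moves are restricted to the plane perpendicular to the local tangent,
    so points climb toward the medial axis and stop once the in-plane
    gradient vanishes (the ridge).  Near flat tube ends the transform's
    gradient points along the axis and is projected away, leaving those
    points untouched instead of dragging them into clipped cross-sections.
    """
    from scipy.ndimage import map_coordinates

    grad = np.gradient(dt, *mask.spacing)
    n_pts = len(pts)
    h = min(3, n_pts - 1)
    hi = np.minimum(np.arange(n_pts) + h, n_pts - 1)
    lo = np.maximum(np.arange(n_pts) - h, 0)
    tangents = pts[hi] - pts[lo]
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True),
                           1e-12)
    pts = pts.copy()
    for _ in range(n_iter):
        idx = np.atleast_2d(mask.world_to_index(pts)).T
        g = np.stack([map_coordinates(gc, idx, order=1, mode="nearest")
                      for gc in grad], axis=1)
        # mask gradient is index-aligned only for identity directions;
        # rotate into world space
        g = (mask.direction @ g.T).T
        g_perp = g - np.sum(g * tangents, axis=1, keepdims=True) * tangents
        norm = np.linalg.norm(g_perp, axis=1, keepdims=True)
        move = norm[:, 0] > 0.3
        if not move.any():
            break
        pts[move] += step_mm * (g_perp[move] / norm[move])
    return pts


def _straighten_terminals(pts, dt, mask, step_mm):
    """Replace each terminal segment with a straight extrapolation.

    Endpoint detection can land a couple of millimetres off-axis, and
    neither ridge re-centering nor smoothing can correct points closer to
    a flat tube end than the local radius (the distance transform there
    measures the face, not the wall).  Extrapolating the stable interior
    direction across that terminal window removes the resulting bend,
    which would otherwise tilt the first cross-section planes.
    """
    n = len(pts)
    shape = np.asarray(mask.shape)
    idx = np.clip(np.rint(np.atleast_2d(mask.world_to_index(pts))).astype(int),
                  0, shape - 1)
    dtv = dt[tuple(idx.T)]
    out = pts.copy()
    for head in (True, False):
        p = out if head else out[::-1]
        d_local = dtv if head else dtv[::-1]
        m = int(np.ceil(1.2 * d_local[:20].max() / step_mm))
        if m < 1 or 2 * m + 8 >= n:
            continue
        # interior direction fitted just beyond the terminal window
        a, b = m, min(m + 10, n - 1)
        seg = p[a:b + 1]
        centered = seg - seg.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        if direction @ (p[a] - p[b]) < 0:
            direction = -direction
        for k in range(m):
            p[k] = p[a] + direction * (a - k) * step_mm
    return out


def _march_to_boundary(start, direction, fg, mask, max_mm: float = 20.0):
    """Last in-mask point marching from *start* along *direction* (mm)."""
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return None
    step_mm = 0.5 * float(mask.spacing.min())
    step = direction / norm * step_mm
    shape = np.asarray(mask.shape)
    pos = np.asarray(start, dtype=float)
    best = None
    for _ in range(int(max_mm / step_mm)):
        pos = pos + step
        idx = np.floor(mask.world_to_index(pos) + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape) or not fg[tuple(idx)]:
            break
        best = pos.copy()
    if best is None or np.linalg.norm(best - start) < step_mm:
        return None
    return best


def _snap_to_foreground(mask: ImageVolume, fg: np.ndarray, point) -> tuple:
    idx = np.rint(mask.world_to_index(point)).astype(int)
    idx = np.clip(idx, 0, np.asarray(mask.shape) - 1)
    if fg[tuple(idx)]:
        return tuple(idx)
    from scipy.spatial import cKDTree

    fg_idx = np.argwhere(fg)
    tree = cKDTree(fg_idx * mask.spacing)
    _, j = tree.query(idx * mask.spacing)
    return tuple(fg_idx[j])


def extract_centerline(mask: ImageVolume, inlet, outlet,
                       step_mm: float = 1.0) -> Centerline:
    """Least-cost medial path from inlet to outlet, smoothed and resampled.

    Edge cost from voxel u to v is ``|u - v|_mm / (DT(v) + eps)`` with DT
    the spacing-aware Euclidean distance to background and eps = 0.1 mm.
    The voxel path is smoothed with a 5-point moving average and
    resampled at uniform ``step_mm`` arc spacing.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    inlet = np.asarray(inlet, dtype=float)
    outlet = np.asarray(outlet, dtype=float)
    if np.allclose(inlet, outlet):
        raise ValueError("inlet and outlet coincide; cannot extract a path")

    fg = _require_single_component(mask)
    spacing = mask.spacing
    dt = ndimage.distance_transform_edt(fg, sampling=spacing)

    fg_idx = np.argwhere(fg)
    n_nodes = len(fg_idx)
    node_id = np.full(mask.shape, -1, dtype=np.int32)
    node_id[tuple(fg_idx.T)] = np.arange(n_nodes, dtype=np.int32)

    rows, cols, weights = [], [], []
    dt_flat = dt[tuple(fg_idx.T)]
    shape = np.asarray(mask.shape)
    offsets = [(di, dj, dk)
               for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
               if (di, dj, dk) != (0, 0, 0)]
    for off in offsets:
        nbr = fg_idx + off
        ok = np.all((nbr >= 0) & (nbr < shape), axis=1)
        tgt = np.full(n_nodes, -1, dtype=np.int32)
        tgt[ok] = node_id[tuple(nbr[ok].T)]
        valid = tgt >= 0
        step = float(np.linalg.norm(np.asarray(off) * spacing))
        rows.append(np.arange(n_nodes, dtype=np.int32)[valid])
        cols.append(tgt[valid])
        weights.append(step / (dt_flat[tgt[valid]] + _DT_EPS_MM))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_nodes, n_nodes)).tocsr()

    src = node_id[_snap_to_foreground(mask, fg, inlet)]
    dst = node_id[_snap_to_foreground(mask, fg, outlet)]
    if src == dst:
        raise ValueError("inlet and outlet map to the same voxel")
    _, predecessors = dijkstra(graph, directed=True, indices=src,
                               return_predecessors=True)
    if predecessors[dst] < 0 and src != dst:
        raise ValueError("inlet and outlet are not connected in the foreground")

    path = [dst]
    while path[-1] != src:
        path.append(predecessors[path[-1]])
    path = np.asarray(path[::-1])
    pts = mask.index_to_world(fg_idx[path]).reshape(-1, 3)

    if len(pts) >= _SMOOTH_WINDOW:
        ends = pts[0].copy(), pts[-1].copy()
        pts = ndimage.uniform_filter1d(pts, size=_SMOOTH_WINDOW, axis=0,
                                       mode="nearest")
        pts[0], pts[-1] = ends  # keep endpoints anchored at the detected ends
    # extend the ends along their terminal tangents to the mask boundary so
    # the path spans the whole vessel (thinning/smoothing retract it slightly)
    head = _march_to_boundary(pts[0], pts[0] - pts[min(4, len(pts) - 1)],
                              fg, mask)
    tail = _march_to_boundary(pts[-1], pts[-1] - pts[max(-5, -len(pts))],
                              fg, mask)
    if head is not None:
        pts = np.vstack([head, pts])
    if tail is not None:
        pts = np.vstack([pts, tail])
    if len(pts) >= _SMOOTH_WINDOW:
        # second anchored pass rounds the kink at the extension joints
        ends = pts[0].copy(), pts[-1].copy()
        pts = ndimage.uniform_filter1d(pts, size=_SMOOTH_WINDOW, axis=0,
                                       mode="nearest")
        pts[0], pts[-1] = ends
    pts = _recenter_on_ridge(pts, mask, fg, dt)
    if len(pts) >= _SMOOTH_WINDOW:
        pts = ndimage.uniform_filter1d(pts, size=_SMOOTH_WINDOW, axis=0,
                                       mode="nearest")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < step_mm:
        raise ValueError("path shorter than one resampling step")
    # drop duplicate-arclength points before interpolation
    keep = np.concatenate([[True], np.diff(s) > 1e-9])
    pts, s = pts[keep], s[keep]
    s_new = np.arange(0.0, s[-1] + step_mm / 2, step_mm)
    if s_new[-1] > s[-1]:
        s_new = s_new[:-1]
    resampled = np.column_stack([np.interp(s_new, s, pts[:, d]) for d in range(3)])

    resampled = _straighten_terminals(resampled, dt, mask, step_mm)

    # safety: pull any stray point back inside the mask
    ridx = np.rint(
        np.atleast_2d(mask.world_to_index(resampled))).astype(int)
    ridx = np.clip(ridx, 0, shape - 1)
    outside = ~fg[tuple(ridx.T)]
    if outside.any():
        from scipy.spatial import cKDTree

        tree = cKDTree(mask.index_to_world(fg_idx).reshape(-1, 3))
        _, j = tree.query(resampled[outside])
        resampled[outside] = mask.index_to_world(fg_idx[j]).reshape(-1, 3)

    seg = np.linalg.norm(np.diff(resampled, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(resampled, arclength, float(step_mm))
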