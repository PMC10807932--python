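"""Ostium-rooted centerline extraction from a coronary label map.

The approach works directly on the interior voxel graph of the lumen mask
(26-connectivity, Euclidean edge lengths in mm):

1. **Ostium seeding** — for each 26-connected coronary component, the seed is
   the lumen voxel closest to the aorta mask (the coronary ostium).
2. **Normalized geodesic distance** — shortest-path distance ``g`` from the
   seed over the voxel graph, normalized to [0, 1] over the component.
3. **Recursive endpoint detection** — superlevel sets ``g > 1 - delta`` are
   thresholded for a growing ``delta`` schedule; each new connected region
   that does not already contain a claimed endpoint contributes its argmax-g
   voxel as a branch endpoint.
4. **Medialness path tracing** — a minimal path from seed to each endpoint
   with edge weight ``euclidean_step / (eps + distance_to_boundary)``, which
   pulls the path onto the vessel axis; the path is resampled at a fixed step
   and smoothed with a short moving average.

``g`` also defines the anatomical zones used throughout the package:
proximal (g <= 0.33), medial (0.33 < g <= 0.66), distal (g > 0.66).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .volume import LabelMap

__all__ = [
    "CenterlineParams",
    "CenterlineBranch",
    "CenterlineTree",
    "find_ostium_seed",
    "geodesic_field",
    "detect_endpoints",
    "trace_centerline",
    "assign_zone",
    "build_tree",
    "branch_from_points",
    "all_branches",
    "tree_points",
    "save_trees_json",
    "load_trees_json",
    "save_trees_vtk",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CenterlineParams:
    """Tunables of the extraction.

    delta_step : increment of the endpoint-detection threshold schedule.
    resample_mm : arc-length step of the output polylines.
    smooth_window : moving-average window (points) applied after tracing.
    min_branch_mm : minimum arc length for a branch to count as a main branch.
    medialness_eps_voxel : epsilon of the medialness edge weight, in voxels.
    dedup_share : fraction of shared points above which a branch is a
        duplicate of a longer one.
    extend_tips : prolong traced paths along their end tangents to the mask
        boundary (recovers arc length clipped by on-axis endpoint snapping).
    """

    delta_step: float = 0.05
    resample_mm: float = 0.5
    smooth_window: int = 5
    min_branch_mm: float = 20.0
    medialness_eps_voxel: float = 0.1
    dedup_share: float = 0.9
    extend_tips: bool = True


@dataclass
class CenterlineBranch:
    """One seed-to-endpoint polyline with abscissa and normalized geodesic g."""

    points: np.ndarray            # (N, 3) mm
    abscissa: np.ndarray          # (N,) mm from the ostium, strictly increasing
    g: np.ndarray                 # (N,) normalized geodesic distance, non-decreasing
    component: int = 0
    parent: int | None = None     # index of the longer branch sharing the prefix

    @property
    def length_mm(self) -> float:
        return float(self.abscissa[-1])

    def zone_mask(self, zone: str) -> np.ndarray:
        lo, hi = {"proximal": (-np.inf, 0.33), "medial": (0.33, 0.66),
                  "distal": (0.66, np.inf)}[zone]
        return (self.g > lo) & (self.g <= hi)


@dataclass
class CenterlineTree:
    """All branches of one 26-connected coronary component, rooted at its ostium."""

    ostium: np.ndarray            # (3,) mm
    branches: list[CenterlineBranch] = field(default_factory=list)
    component: int = 0


def all_branches(trees: "CenterlineTree | Sequence[CenterlineTree]") -> list[CenterlineBranch]:
    if isinstance(trees, CenterlineTree):
        return list(trees.branches)
    out: list[CenterlineBranch] = []
    for t in trees:
        out.extend(t.branches)
    return out


def tree_points(trees) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate (points, abscissa, g) over all branches of one or more trees."""
    brs = all_branches(trees)
    if not brs:
        raise ValueError("empty centerline tree")
    return (np.vstack([b.points for b in brs]),
            np.concatenate([b.abscissa for b in brs]),
            np.concatenate([b.g for b in brs]))


# ---------------------------------------------------------------------------
# voxel graph helpers


def _mask_graph(mask: np.ndarray, spacing: np.ndarray, weights: np.ndarray | None = None):
    """Sparse 26-neighbour graph over True voxels.

    Edge weight is the Euclidean step in mm, optionally divided by a per-voxel
    medialness factor of the *target* voxel (directed graph in that case).
    Returns (graph, flat_index_of_mask_voxels, inverse_lookup_volume).
    """
    idx_vol = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    idx_vol[mask] = np.arange(len(coords))
    rows, cols, vals = [], [], []
    for off in np.ndindex(3, 3, 3):
        d = np.array(off) - 1
        if np.all(d == 0):
            continue
        step = float(np.linalg.norm(d * spacing))
        src = coords
        tgt = coords + d
        ok = np.all((tgt >= 0) & (tgt < mask.shape), axis=1)
        src, tgt = src[ok], tgt[ok]
        ti = idx_vol[tgt[:, 0], tgt[:, 1], tgt[:, 2]]
        ok = ti >= 0
        si = idx_vol[src[ok][:, 0], src[ok][:, 1], src[ok][:, 2]]
        ti = ti[ok]
        w = np.full(len(ti), step)
        if weights is not None:
            w = w / weights[tgt[ok][:, 0], tgt[ok][:, 1], tgt[ok][:, 2]]
        rows.append(si)
        cols.append(ti)
        vals.append(w)
    n = len(coords)
    graph = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return graph, coords, idx_vol


def _voxel_center(idx, spacing, origin):
    return np.asarray(origin) + np.asarray(idx) * np.asarray(spacing)


# ---------------------------------------------------------------------------
# operations


def find_ostium_seed(coronary: LabelMap, aorta: LabelMap) -> list[tuple[int, np.ndarray]]:
    """Seed voxel per 26-connected coronary component: the lumen voxel whose
    center is closest (Euclidean, mm) to the aorta voxel set.

    Returns a list of ``(component_label, voxel_index)`` pairs, components
    labelled from 1.  Ties are broken by lexicographic voxel index.  There is
    no distance cutoff: the argmin always exists for a non-empty mask.
    """
    coronary.check_same_grid(aorta, "coronary and aorta masks")
    if coronary.data.sum() == 0 or aorta.data.sum() == 0:
        raise ValueError("empty coronary or aorta mask")
    labels, ncomp = ndimage.label(coronary.data > 0, structure=_STRUCT26)
    ao_pts = np.argwhere(aorta.data > 0) * coronary.spacing
    ao_tree = cKDTree(ao_pts)
    seeds = []
    for comp in range(1, ncomp + 1):
        vox = np.argwhere(labels == comp)  # argwhere is lexicographic
        d, _ = ao_tree.query(vox * coronary.spacing, k=1)
        best = int(np.argmin(d))  # first minimum -> lexicographic tie-break
        seeds.append((comp, vox[best]))
    return seeds


def _geodesic_mm(coronary: LabelMap, seed) -> tuple[np.ndarray, float]:
    """Unnormalized geodesic distance field (mm) and its maximum."""
    mask = coronary.data > 0
    seed = tuple(int(v) for v in seed)
    if not mask[seed]:
        raise ValueError(f"seed {seed} lies outside the coronary mask")
    graph, coords, idx_vol = _mask_graph(mask, coronary.spacing)
    dist = csgraph.dijkstra(graph, directed=False, indices=idx_vol[seed])
    field = np.full(coronary.shape, np.nan)
    reach = np.isfinite(dist)
    gmax = float(dist[reach].max())
    vals = np.full(len(coords), np.nan)
    vals[reach] = dist[reach]
    field[mask] = vals
    return field, gmax


def geodesic_field(coronary: LabelMap, seed: np.ndarray) -> np.ndarray:
    """Normalized geodesic distance from ``seed`` over the 26-connected voxel
    graph with Euclidean (mm) edge lengths.

    Returns a full-grid array with ``g`` in [0, 1] on the seed's component
    (g(seed) = 0, max g = 1) and NaN elsewhere, including voxels of other
    components, which are unreachable.
    """
    field, gmax = _geodesic_mm(coronary, seed)
    if gmax == 0:
        gmax = 1.0  # single-voxel component
    return field / gmax


def detect_endpoints(g: np.ndarray, delta_step: float = 0.05) -> list[np.ndarray]:
    """Recursive endpoint detection on the normalized geodesic field.

    Thresholds the superlevel set ``g > 1 - delta`` for ``delta = step,
    2*step, ..., 1``; each 26-connected region that does not contain an
    already-claimed endpoint emits its voxel of maximal ``g`` (lexicographic
    tie-break).  Every local maximum of ``g`` — i.e. every branch tip — is
    eventually claimed.
    """
    if not 0 < delta_step <= 1:
        raise ValueError("delta_step must lie in (0, 1]")
    finite = np.nan_to_num(g, nan=-1.0)
    endpoints: list[np.ndarray] = []
    claimed = np.zeros(g.shape, dtype=bool)
    n_steps = int(np.ceil(1.0 / delta_step))
    for k in range(1, n_steps + 1):
        delta = min(k * delta_step, 1.0)
        above = finite > 1.0 - delta
        labels, ncomp = ndimage.label(above, structure=_STRUCT26)
        for comp in range(1, ncomp + 1):
            region = labels == comp
            if np.any(claimed & region):
                continue
            flat = np.where(region.ravel(), finite.ravel(), -np.inf)
            best = np.unravel_index(int(np.argmax(flat)), g.shape)
            endpoints.append(np.array(best))
            claimed[best] = True
    return endpoints


def assign_zone(g: float) -> str:
    """Map normalized geodesic distance to the anatomical zone.

    proximal: g <= 0.33; medial: 0.33 < g <= 0.66; distal: g > 0.66.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"g={g} outside [0, 1]")
    if g <= 0.33:
        return "proximal"
    if g <= 0.66:
        return "medial"
    return "distal"


def _dt_hill_climb(dt: np.ndarray, mask: np.ndarray, voxel: np.ndarray) -> np.ndarray:
    """Steepest ascent on the interior distance transform (26-neighbourhood).

    Moves a surface voxel onto the medial axis so that traced paths start and
    end on-axis; deterministic (first maximal neighbour in lexicographic
    offset order wins)."""
    cur = tuple(int(v) for v in voxel)
    shape = mask.shape
    while True:
        best, best_val = cur, dt[cur]
        for off in np.ndindex(3, 3, 3):
            d = (off[0] - 1, off[1] - 1, off[2] - 1)
            if d == (0, 0, 0):
                continue
            nb = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if any(c < 0 or c >= s for c, s in zip(nb, shape)) or not mask[nb]:
                continue
            if dt[nb] > best_val + 1e-12:
                best, best_val = nb, dt[nb]
        if best == cur:
            return np.array(cur)
        cur = best


def branch_from_points(points: np.ndarray, resample_mm: float = 0.5,
                       g_max_mm: float | None = None) -> CenterlineBranch:
    """Build a branch from an explicit polyline (e.g. an analytic centerline).

    The polyline is resampled at ``resample_mm``; ``g`` is the abscissa
    normalized by ``g_max_mm`` (default: the polyline's own length).
    """
    pts = _resample_polyline(np.asarray(points, dtype=float), resample_mm)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    denom = g_max_mm if g_max_mm else (s[-1] if s[-1] > 0 else 1.0)
    return CenterlineBranch(points=pts, abscissa=s, g=np.clip(s / denom, 0, 1))


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        return pts[:1]
    n = max(2, int(np.round(s[-1] / step)) + 1)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(pts) < 3:
        return pts
    return ndimage.uniform_filter1d(pts, size=window, axis=0, mode="nearest")


def _inside(mask_lab, p) -> bool:
    idx = np.rint((p - mask_lab.origin) / mask_lab.spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask_lab.shape)):
        return False
    return bool(mask_lab.data[tuple(idx)])


def _extend_to_boundary(pts, mask_lab, step, max_steps=200):
    """Prolong both ends along the local tangent until the path leaves the
    mask; recovers the arc length clipped when endpoints are pulled onto the
    medial axis away from the end caps."""
    if len(pts) < 2:
        return pts
    out = pts
    for end in (0, -1):
        d = out[1] - out[0] if end == 0 else out[-1] - out[-2]
        n = np.linalg.norm(d)
        if n == 0:
            continue
        d = d / n
        base = out[0] if end == 0 else out[-1]
        ext = []
        for k in range(1, max_steps + 1):
            p = base + (-d if end == 0 else d) * (k * step)
            if not _inside(mask_lab, p):
                break
            ext.append(p)
        if ext:
            out = (np.vstack([ext[::-1], out]) if end == 0
                   else np.vstack([out, ext]))
    return out


def _branch_from_path(path_vox, coronary, g_max_mm, params) -> CenterlineBranch:
    pts = _voxel_center(np.asarray(path_vox), coronary.spacing, coronary.origin)
    pts = _resample_polyline(pts, params.resample_mm)
    pts = _smooth_polyline(pts, params.smooth_window)
    if params.extend_tips:
        pts = _extend_to_boundary(pts, coronary, params.resample_mm)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    # along the branch the geodesic distance from the ostium is the arc
    # length itself, so g is the abscissa normalized by the component's
    # maximal geodesic distance: exact 0 at the ostium, monotone, no
    # nearest-voxel sampling jitter
    denom = g_max_mm if g_max_mm > 0 else 1.0
    gs = np.clip(s / denom, 0.0, 1.0)
    return CenterlineBranch(points=pts, abscissa=s, g=gs)


def trace_centerline(
    coronary: LabelMap,
    seed: np.ndarray,
    endpoint: np.ndarray,
    params: CenterlineParams | None = None,
) -> CenterlineBranch:
    """Minimal medialness-weighted path from seed to endpoint.

    Edge weight is the Euclidean step divided by ``eps + distance transform``
    of the target voxel, so the shortest path hugs the vessel axis; the path
    is then resampled at ``params.resample_mm`` and smoothed.
    """
    params = params or CenterlineParams()
    _, gmax = _geodesic_mm(coronary, seed)  # validates seed; scales per-point g
    pred, idx_vol, coords = _medial_predecessors(coronary, seed, params)
    return _backtrack_branch(pred, idx_vol, coords, coronary, gmax, seed, endpoint, params)


def _medial_predecessors(coronary, seed, params):
    mask = coronary.data > 0
    dt = ndimage.distance_transform_edt(mask, sampling=coronary.spacing)
    eps = params.medialness_eps_voxel * float(np.min(coronary.spacing))
    graph, coords, idx_vol = _mask_graph(mask, coronary.spacing, weights=eps + dt)
    _, pred = csgraph.dijkstra(
        graph, directed=True, indices=idx_vol[tuple(seed)], return_predecessors=True
    )
    return pred, idx_vol, coords


def _backtrack_branch(pred, idx_vol, coords, coronary, g_max_mm, seed, endpoint, params):
    target = idx_vol[tuple(int(v) for v in endpoint)]
    if target < 0:
        raise ValueError("endpoint outside the coronary mask")
    path = []
    node = target
    while node >= 0:
        path.append(coords[node])
        node = pred[node]
    if not np.array_equal(path[-1], np.asarray(seed)):
        raise ValueError("endpoint not connected to the seed")
    path.reverse()
    return _branch_from_path(path, coronary, g_max_mm, params)


def build_tree(
    coronary: LabelMap,
    aorta: LabelMap,
    params: CenterlineParams | None = None,
) -> list[CenterlineTree]:
    """Full extraction: one :class:`CenterlineTree` per coronary component.

    Per component: ostium seeding -> geodesic field -> recursive endpoint
    detection -> medialness tracing of every endpoint; branches sharing at
    least ``params.dedup_share`` of their points with a longer branch are
    dropped as duplicates, and each remaining branch records as ``parent``
    the longer branch it shares its prefix with.
    """
    params = params or CenterlineParams()
    seeds = find_ostium_seed(coronary, aorta)
    mask_all = coronary.data > 0
    dt = ndimage.distance_transform_edt(mask_all, sampling=coronary.spacing)
    trees: list[CenterlineTree] = []
    for comp, seed in seeds:
        seed = _dt_hill_climb(dt, mask_all, seed)  # surface -> medial axis
        field, gmax = _geodesic_mm(coronary, seed)
        g = field / (gmax if gmax > 0 else 1.0)
        comp_mask = ~np.isnan(g)
        comp_lab = LabelMap(comp_mask.astype(np.uint8), coronary.spacing,
                            coronary.origin, coronary.direction)
        endpoints = detect_endpoints(g, params.delta_step)
        endpoints = [_dt_hill_climb(dt, comp_mask, ep) for ep in endpoints]
        pred, idx_vol, coords = _medial_predecessors(comp_lab, seed, params)
        branches = []
        for ep in endpoints:
            try:
                br = _backtrack_branch(pred, idx_vol, coords, comp_lab, gmax,
                                       seed, ep, params)
            except ValueError:
                continue
            br.component = comp
            branches.append(br)
        branches = _dedup_branches(branches, params)
        trees.append(CenterlineTree(
            ostium=_voxel_center(seed, coronary.spacing, coronary.origin),
            branches=branches, component=comp))
    return trees


def _dedup_branches(branches, params):
    order = np.argsort([-b.length_mm for b in branches])
    kept: list[CenterlineBranch] = []
    tol = 1.5 * params.resample_mm
    for oi in order:
        b = branches[oi]
        parent = None
        dup = False
        best_shared = 0
        for ki, kb in enumerate(kept):
            d, _ = cKDTree(kb.points).query(b.points, k=1)
            shared = int(np.sum(d <= tol))
            if shared >= params.dedup_share * len(b.points):
                dup = True
                break
            if shared > best_shared:
                best_shared, parent = shared, ki
        if not dup:
            b.parent = parent
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# serialization


def save_trees_json(trees: Sequence[CenterlineTree], path: str | Path) -> None:
    payload = [{
        "ostium": t.ostium.tolist(),
        "component": t.component,
        "branches": [{
            "points": b.points.tolist(),
            "abscissa": b.abscissa.tolist(),
            "g": b.g.tolist(),
            "parent": b.parent,
        } for b in t.branches],
    } for t in trees]
    Path(path).write_text(json.dumps(payload))


def load_trees_json(path: str | Path) -> list[CenterlineTree]:
    payload = json.loads(Path(path).read_text())
    trees = []
    for t in payload:
        branches = [CenterlineBranch(
            points=np.asarray(b["points"], dtype=float),
            abscissa=np.asarray(b["abscissa"], dtype=float),
            g=np.asarray(b["g"], dtype=float),
            component=t["component"], parent=b["parent"],
        ) for b in t["branches"]]
        trees.append(CenterlineTree(ostium=np.asarray(t["ostium"], dtype=float),
                                    branches=branches, component=t["component"]))
    return trees


def save_trees_vtk(trees: Sequence[CenterlineTree], path: str | Path) -> None:
    """Export all branches as VTK legacy polydata (ASCII polylines)."""
    brs = all_branches(list(trees))
    pts = np.vstack([b.points for b in brs]) if brs else np.zeros((0, 3))
    lines = []
    off = 0
    for b in brs:
        n = len(b.points)
        lines.append([n] + list(range(off, off + n)))
        off += n
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncorochar centerlines\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            f.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        total = sum(len(l) for l in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            f.write(" ".join(map(str, l)) + "\n")
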