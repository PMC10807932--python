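"""Pointwise and per-zone tortuosity of coronary centerlines.

Two pointwise measures are computed over a sliding reference arc of fixed
length (default 1 cm) centered at each centerline point:

* **local tortuosity (LT)** — ratio of the arc length of the reference arc to
  the Euclidean distance between its two endpoints; 1.0 for a straight
  vessel, larger for winding ones.
* **tortuosity angle (TA)** — the angle ``arccos(v_up . v_dw)`` between the
  least-squares line directions fitted to the upstream and downstream halves
  of the reference arc, both oriented along increasing abscissa.

A **bend** is a maximal contiguous run of valid points with TA above a
threshold (45 degrees), runs separated by at least 2 mm of abscissa below the
threshold; its angle is the maximum TA in the run.  The **tortuosity score
(TS)** of a patient is the number of main branches (arc length at least
``min_branch_mm``) with three or more bends; TS = 0 means no tortuosity and
TS >= 4 severe tortuosity.  Per-zone **tract tortuosity** applies the
arc/chord ratio to the maximal contiguous sub-tract of a branch lying in one
geodesic zone.  Points whose reference arc would extend beyond the branch are
flagged invalid and excluded from all summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .centerline import CenterlineBranch, CenterlineTree, all_branches

__all__ = [
    "TortuosityParams",
    "TortuosityProfile",
    "Bend",
    "TortuositySummary",
    "compute_profile",
    "local_tortuosity",
    "tortuosity_angle",
    "detect_bends",
    "tract_tortuosity",
    "tortuosity_score",
    "summarize_tortuosity",
]

ZONES = ("proximal", "medial", "distal")


@dataclass
class TortuosityParams:
    window_mm: float = 10.0        # reference arc length (1 cm)
    ta_threshold_deg: float = 45.0
    min_bend_gap_mm: float = 2.0   # below-threshold abscissa separating bends
    min_bends: int = 3             # bends needed for a branch to count in TS
    min_branch_mm: float = 20.0    # a "main" branch must be at least this long
    percentile: float = 95.0       # outlier-robust summary percentile


@dataclass
class TortuosityProfile:
    """Pointwise LT/TA along one branch; invalid windows are flagged."""

    lt: np.ndarray
    ta_deg: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lt[self.valid] < 1.0 - 1e-9):
            raise ValueError("local tortuosity below 1 on a valid window")


@dataclass
class Bend:
    branch: int
    angle_deg: float
    start_abscissa_mm: float
    end_abscissa_mm: float

    @property
    def abscissa_mm(self) -> float:
        return 0.5 * (self.start_abscissa_mm + self.end_abscissa_mm)


@dataclass
class TortuositySummary:
    """Patient-level tortuosity: per-zone tracts, robust percentiles, bends, TS."""

    tract_tortuosity: dict = field(default_factory=dict)   # zone -> mean over branches
    lt_p95: float = float("nan")
    ta_p95_deg: float = float("nan")
    lt_p95_by_zone: dict = field(default_factory=dict)
    ta_p95_by_zone: dict = field(default_factory=dict)
    bends: list[Bend] = field(default_factory=list)
    ts: int = 0
    n_branches: int = 0

    @property
    def severity(self) -> str:
        if self.ts == 0:
            return "none"
        return "severe" if self.ts >= 4 else "moderate"


# ---------------------------------------------------------------------------
# pointwise measures


def _interp_point(branch: CenterlineBranch, s: float) -> np.ndarray:
    return np.array([np.interp(s, branch.abscissa, branch.points[:, k]) for k in range(3)])


def _window_points(branch: CenterlineBranch, s_lo: float, s_hi: float) -> np.ndarray:
    """Branch samples in [s_lo, s_hi] with exactly interpolated end points."""
    inside = (branch.abscissa > s_lo + 1e-9) & (branch.abscissa < s_hi - 1e-9)
    return np.vstack([_interp_point(branch, s_lo),
                      branch.points[inside],
                      _interp_point(branch, s_hi)])


def _fit_direction(pts: np.ndarray) -> np.ndarray | None:
    """Least-squares line direction of a point set, oriented start -> end."""
    centered = pts - pts.mean(axis=0)
    if len(pts) < 2 or np.allclose(centered, 0):
        return None
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    span = pts[-1] - pts[0]
    if np.dot(d, span) < 0:
        d = -d
    return d


def _window_bounds(branch: CenterlineBranch, i: int, window_mm: float):
    s = branch.abscissa[i]
    lo, hi = s - window_mm / 2, s + window_mm / 2
    if lo < -1e-9 or hi > branch.abscissa[-1] + 1e-9:
        return None
    return max(lo, 0.0), min(hi, branch.abscissa[-1]), s


def local_tortuosity(branch: CenterlineBranch, i: int, window_mm: float = 10.0) -> float:
    """Arc/chord ratio of the reference arc centered at point ``i``.

    NaN when the window extends beyond the branch (flagged invalid).  The arc
    length equals ``window_mm`` by the abscissa parameterization; the chord is
    the distance between the interpolated window end points.
    """
    b = _window_bounds(branch, i, window_mm)
    if b is None:
        return float("nan")
    lo, hi, _ = b
    chord = float(np.linalg.norm(_interp_point(branch, hi) - _interp_point(branch, lo)))
    if chord == 0:
        return float("inf")
    return max((hi - lo) / chord, 1.0)


def tortuosity_angle(branch: CenterlineBranch, i: int, window_mm: float = 10.0) -> float:
    """Angle (degrees) between the least-squares directions of the upstream
    and downstream half-arcs at point ``i``; NaN for invalid windows, 0 with a
    warning for degenerate (collapsed) fits."""
    b = _window_bounds(branch, i, window_mm)
    if b is None:
        return float("nan")
    lo, hi, s = b
    up = _fit_direction(_window_points(branch, lo, s))
    dw = _fit_direction(_window_points(branch, s, hi))
    if up is None or dw is None:
        warnings.warn("degenerate half-arc fit; TA set to 0")
        return 0.0
    # atan2 form of arccos(up . dw): identical value, well conditioned at 0
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(up, dw)),
                                       np.dot(up, dw))))


def compute_profile(
    branch: CenterlineBranch, params: TortuosityParams | None = None
) -> TortuosityProfile:
    """LT and TA at every point of the branch."""
    params = params or TortuosityParams()
    n = len(branch.points)
    lt = np.full(n, np.nan)
    ta = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if _window_bounds(branch, i, params.window_mm) is None:
            continue
        lt[i] = local_tortuosity(branch, i, params.window_mm)
        ta[i] = tortuosity_angle(branch, i, params.window_mm)
        valid[i] = True
    return TortuosityProfile(lt=lt, ta_deg=ta, valid=valid)


# ---------------------------------------------------------------------------
# bends, score, tracts


def detect_bends(
    profile: TortuosityProfile,
    branch: CenterlineBranch,
    branch_index: int = 0,
    params: TortuosityParams | None = None,
) -> list[Bend]:
    """Maximal runs of valid points with TA above threshold.

    Runs separated by less than ``min_bend_gap_mm`` of below-threshold
    abscissa are merged into one bend; the bend angle is the maximum TA of
    the run.
    """
    params = params or TortuosityParams()
    above = profile.valid & (np.nan_to_num(profile.ta_deg, nan=-1.0)
                             >= params.ta_threshold_deg)
    runs: list[tuple[int, int]] = []  # [start, end] inclusive index ranges
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if runs and (branch.abscissa[i] - branch.abscissa[runs[-1][1]]
                     < params.min_bend_gap_mm):
            runs[-1] = (runs[-1][0], j)
        else:
            runs.append((i, j))
        i = j + 1
    return [
        Bend(
            branch=branch_index,
            angle_deg=float(np.nanmax(profile.ta_deg[a:b + 1])),
            start_abscissa_mm=float(branch.abscissa[a]),
            end_abscissa_mm=float(branch.abscissa[b]),
        )
        for a, b in runs
    ]


def tract_tortuosity(branch: CenterlineBranch, zone: str) -> float | None:
    """Arc/chord ratio of the maximal contiguous sub-tract of the branch whose
    points fall in the given geodesic zone; None when the zone is absent or
    carries fewer than 2 points."""
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    mask = branch.zone_mask(zone)
    if mask.sum() < 2:
        return None
    # longest contiguous run
    best = (0, -1)
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        if j - i > best[1] - best[0]:
            best = (i, j)
        i = j + 1
    a, b = best
    if b - a < 1:
        return None
    arc = float(branch.abscissa[b] - branch.abscissa[a])
    chord = float(np.linalg.norm(branch.points[b] - branch.points[a]))
    if chord == 0:
        return float("inf")
    return max(arc / chord, 1.0)


def tortuosity_score(
    bends_per_branch: Sequence[Sequence[Bend]],
    branch_lengths_mm: Sequence[float],
    params: TortuosityParams | None = None,
) -> int:
    """Number of main branches (length >= ``min_branch_mm``) with at least
    ``min_bends`` bends."""
    params = params or TortuosityParams()
    return sum(
        1
        for bends, length in zip(bends_per_branch, branch_lengths_mm)
        if length >= params.min_branch_mm and len(bends) >= params.min_bends
    )


def summarize_tortuosity(
    trees: CenterlineTree | Sequence[CenterlineTree],
    params: TortuosityParams | None = None,
) -> TortuositySummary:
    """Patient-level tortuosity summary over all branches of the tree(s)."""
    params = params or TortuosityParams()
    branches = all_branches(trees)
    profiles = [compute_profile(b, params) for b in branches]
    bends_per_branch = [
        detect_bends(p, b, i, params) for i, (p, b) in enumerate(zip(profiles, branches))
    ]

    tract: dict[str, float] = {}
    lt_zone: dict[str, float] = {}
    ta_zone: dict[str, float] = {}
    for zone in ZONES:
        vals = [t for b in branches if (t := tract_tortuosity(b, zone)) is not None]
        tract[zone] = float(np.mean(vals)) if vals else float("nan")
        lt_vals, ta_vals = [], []
        for b, p in zip(branches, profiles):
            m = p.valid & b.zone_mask(zone)
            lt_vals.append(p.lt[m])
            ta_vals.append(p.ta_deg[m])
        lt_all = np.concatenate(lt_vals) if lt_vals else np.array([])
        ta_all = np.concatenate(ta_vals) if ta_vals else np.array([])
        lt_zone[zone] = float(np.percentile(lt_all, params.percentile)) if lt_all.size else float("nan")
        ta_zone[zone] = float(np.percentile(ta_all, params.percentile)) if ta_all.size else float("nan")

    lt_all = np.concatenate([p.lt[p.valid] for p in profiles]) if profiles else np.array([])
    ta_all = np.concatenate([p.ta_deg[p.valid] for p in profiles]) if profiles else np.array([])
    return TortuositySummary(
        tract_tortuosity=tract,
        lt_p95=float(np.percentile(lt_all, params.percentile)) if lt_all.size else float("nan"),
        ta_p95_deg=float(np.percentile(ta_all, params.percentile)) if ta_all.size else float("nan"),
        lt_p95_by_zone=lt_zone,
        ta_p95_by_zone=ta_zone,
        bends=[b for bl in bends_per_branch for b in bl],
        ts=tortuosity_score(bends_per_branch, [b.length_mm for b in branches], params),
        n_branches=len(branches),
    )
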