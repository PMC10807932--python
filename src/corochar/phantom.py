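"""Synthetic CCTA-like phantoms with exact analytic ground truth.

Every downstream stage of the pipeline (centerline extraction, tortuosity,
calcium scoring, segmentation smoke training) is validated against phantoms
generated here: tapering tubular vessels of 1.5-4 mm caliber swept along
parametric centerlines (straight / circular arc / helix / filleted polyline
with prescribed bend angles), an attached aortic cylinder, hyperdense
ellipsoidal calcific inclusions, a soft-tissue background, Gaussian PSF blur
and i.i.d. Gaussian noise.  The generator records ground truth analytically
(true centerlines with arc-length parameterization, per-bend angles,
per-lesion volume/extent/abscissa) *before* rasterization, so recovery errors
measured downstream are attributable to the algorithms, not the truth.

Intensity defaults (blood pool 400 +/- 30 HU, background 50 +/- 20 HU,
lesions 800 HU peak) place lesions near the top of the [-30, 800] HU window
used by the segmentation preprocessing, and make the patient-specific
calcium threshold (aortic mean + 2.5 SD) nontrivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import ImageVolume, LabelMap

__all__ = [
    "VesselSpec",
    "LesionSpec",
    "AortaSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "make_bent_branch",
    "analytic_tortuosity",
    "sample_centerline",
    "generate_phantom",
]

#: minimum lumen radius (mm): half the 1.5 mm caliber floor below which
#: branches are not clinically relevant.
MIN_RADIUS_MM = 0.75

_FINE_STEP_MM = 0.1  # ground-truth centerline sampling step


# ---------------------------------------------------------------------------
# specifications


@dataclass
class VesselSpec:
    """Parametric description of one vessel: centerline + swept radius profile.

    ``kind`` selects the centerline family:

    ``straight``
        segment of ``length_mm`` from ``start`` along ``direction``.
    ``circular_arc``
        planar arc of radius ``arc_radius_mm`` subtending ``arc_angle_deg``.
    ``helix``
        circular helix of radius ``helix_radius_mm``, pitch (rise per turn)
        ``helix_pitch_mm``, over ``turns`` full turns.
    ``polyline_with_bends``
        straight segments of ``segment_len_mm`` joined by circular fillets of
        radius ``fillet_radius_mm``; the direction change at bend *k* equals
        ``bend_angles_deg[k]`` (use :func:`make_bent_branch`).

    The lumen radius tapers linearly from ``radius_start_mm`` to
    ``radius_end_mm``; an optional ``stenosis`` triple
    ``(abscissa_mm, length_mm, severity)`` carves a smooth fractional radius
    reduction around the given abscissa.
    """

    kind: str
    length_mm: float = 0.0
    arc_radius_mm: float = 0.0
    arc_angle_deg: float = 0.0
    helix_radius_mm: float = 0.0
    helix_pitch_mm: float = 0.0
    turns: float = 0.0
    bend_angles_deg: tuple[float, ...] = ()
    segment_len_mm: float = 0.0
    fillet_radius_mm: float = 1.0
    radius_start_mm: float = 2.0
    radius_end_mm: float = 2.0
    stenosis: tuple[float, float, float] | None = None
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "circular_arc", "helix", "polyline_with_bends"):
            raise ValueError(f"unknown centerline kind {self.kind!r}")
        for r in (self.radius_start_mm, self.radius_end_mm):
            if r < MIN_RADIUS_MM:
                raise ValueError(f"lumen radius {r} mm below floor {MIN_RADIUS_MM} mm")
        if self.kind == "straight" and self.length_mm <= 0:
            raise ValueError("straight vessel needs length_mm > 0")
        if self.kind == "circular_arc" and (
            self.arc_radius_mm <= 0 or not 0 < self.arc_angle_deg <= 360
        ):
            raise ValueError("circular arc needs radius > 0 and angle in (0, 360]")
        if self.kind == "helix" and (
            self.helix_radius_mm <= 0 or self.turns <= 0 or self.helix_pitch_mm < 0
        ):
            raise ValueError("helix needs radius > 0, turns > 0, pitch >= 0")
        for a in self.bend_angles_deg:
            if not 0 < a < 180:
                raise ValueError(f"bend angle {a} deg outside (0, 180)")
        if self.stenosis is not None:
            _, ln, sev = self.stenosis
            if ln <= 0 or not 0 <= sev < 1:
                raise ValueError("stenosis needs length > 0 and severity in [0, 1)")

    # -- geometry -----------------------------------------------------------

    def arc_length(self) -> float:
        if self.kind == "straight":
            return self.length_mm
        if self.kind == "circular_arc":
            return self.arc_radius_mm * np.deg2rad(self.arc_angle_deg)
        if self.kind == "helix":
            a, b = self.helix_radius_mm, self.helix_pitch_mm / (2 * np.pi)
            return float(2 * np.pi * self.turns * np.hypot(a, b))
        # filleted polyline
        pts, s, _ = sample_centerline(self, step=_FINE_STEP_MM)
        return float(s[-1])

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        """Lumen radius (mm) at abscissa ``s`` (mm), taper plus optional stenosis."""
        total = self.arc_length()
        t = np.clip(np.asarray(s, dtype=float) / total, 0.0, 1.0)
        r = self.radius_start_mm + t * (self.radius_end_mm - self.radius_start_mm)
        if self.stenosis is not None:
            s0, ln, sev = self.stenosis
            in_win = np.abs(np.asarray(s) - s0) <= ln / 2
            bump = 0.5 * (1 + np.cos(2 * np.pi * (np.asarray(s) - s0) / ln))
            r = np.where(in_win, r * (1 - sev * bump), r)
        return r


@dataclass
class LesionSpec:
    """Ellipsoidal calcific inclusion on a parent vessel.

    The first semi-axis is aligned with the local vessel tangent, so the true
    extent along the vessel is ``2 * axis_lengths_mm[0]`` and the true minimum
    abscissa is ``center_abscissa_mm - axis_lengths_mm[0]``.  The peak
    intensity must exceed the blood-pool mean by more than 2.5 blood-pool SDs,
    which guarantees detectability by the patient-specific threshold rule.

    Calcifications are not uniformly dense: attenuation is maximal in the
    core and falls off where calcium mixes with soft plaque and blood.  The
    painted density is therefore 1 inside the core and decays linearly to 0
    across a band of width ``margin_mm`` (about one PSF width by default)
    centered on the stated ellipsoid surface — the stated surface is the
    half-density contour, the convention under which attenuation-threshold
    volumetry is unbiased.
    """

    center_abscissa_mm: float
    axis_lengths_mm: tuple[float, float, float]
    peak_intensity: float = 800.0
    margin_mm: float = 0.5
    vessel_index: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.axis_lengths_mm):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.margin_mm < 0:
            raise ValueError("margin must be non-negative")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.axis_lengths_mm
        return float(4.0 / 3.0 * np.pi * a * b * c)


@dataclass
class AortaSpec:
    """Aortic cylinder attached at the tree root (surface within 2 mm of it)."""

    radius_mm: float = 6.0
    length_mm: float = 24.0
    gap_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("aorta radius/length must be positive")
        if not 0 <= self.gap_mm <= 2.0:
            raise ValueError("aorta surface must be within 2 mm of the tree root")


@dataclass
class PhantomSpec:
    """Full phantom: vessels, lesions, aorta, intensities, PSF, noise, grid."""

    vessels: list[VesselSpec]
    lesions: list[LesionSpec] = field(default_factory=list)
    aorta: AortaSpec = field(default_factory=AortaSpec)
    blood_mean_hu: float = 400.0
    blood_sd_hu: float = 30.0
    background_mean_hu: float = 50.0
    background_sd_hu: float = 20.0
    blur_sigma_mm: float = 0.35
    noise_sd_hu: float = 20.0
    texture_corr_mm: float = 1.5
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    seed: int = 0
    margin_mm: float = 6.0

    def __post_init__(self) -> None:
        if not self.vessels:
            raise ValueError("phantom needs at least one vessel")
        if any(not 0.3 <= s <= 0.7 for s in self.spacing):
            raise ValueError("spacing components must lie in [0.3, 0.7] mm")
        for les in self.lesions:
            if les.vessel_index >= len(self.vessels):
                raise ValueError("lesion references a missing vessel")
            if les.peak_intensity <= self.blood_mean_hu + 2.5 * self.blood_sd_hu:
                raise ValueError(
                    "lesion peak must exceed blood-pool mean + 2.5 SD "
                    "(detectability by the patient-specific threshold)"
                )


@dataclass
class PhantomGroundTruth:
    """Analytic truth recorded before rasterization."""

    centerlines: list[np.ndarray]           # (N, 3) mm, fine sampling
    abscissae: list[np.ndarray]             # (N,) mm arc length
    bends: list[dict]                       # {"branch": i, "angle_deg": a, "abscissa_mm": s}
    lesions: list[dict]                     # {"volume_mm3", "extent_mm", "min_abscissa_mm", ...}
    analytic_tortuosity: list[float | None]  # per vessel, 1 cm window, or None
    ostium: np.ndarray = None  # type: ignore[assignment]

    def true_ts(self, ta_threshold_deg: float = 45.0, min_bends: int = 3) -> int:
        """Tortuosity score implied by the prescribed bend angles."""
        count = 0
        for i in range(len(self.centerlines)):
            n = sum(1 for b in self.bends
                    if b["branch"] == i and b["angle_deg"] >= ta_threshold_deg)
            if n >= min_bends:
                count += 1
        return count

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centerlines": [c.tolist() for c in self.centerlines],
            "bends": self.bends,
            "lesions": self.lesions,
            "analytic_tortuosity": self.analytic_tortuosity,
            "ostium": None if self.ostium is None else self.ostium.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# centerline constructors


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _perp(u: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to u."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def make_bent_branch(
    bend_angles_deg: list[float],
    segment_len_mm: float,
    *,
    fillet_radius_mm: float = 1.0,
    radius_mm: float = 2.0,
    start: tuple[float, float, float] = (0.0, 0.0, 0.0),
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> VesselSpec:
    """Planar polyline of straight segments joined by circular fillets.

    The direction change at bend ``k`` equals ``bend_angles_deg[k]``; turn
    signs alternate so the branch does not curl onto itself.  The fillet
    tangent length is ``fillet_radius * tan(angle/2)``; segments must be long
    enough to accommodate the fillets of both ends.
    """
    for a in bend_angles_deg:
        if not 0 < a < 180:
            raise ValueError(f"bend angle {a} outside (0, 180) deg")
    tangents = [fillet_radius_mm * np.tan(np.deg2rad(a) / 2) for a in bend_angles_deg]
    for i, t in enumerate(tangents):
        prev_t = tangents[i - 1] if i > 0 else 0.0
        if segment_len_mm < t + prev_t + 1e-9:
            raise ValueError("segment shorter than the fillet arcs it must carry")
    if not bend_angles_deg:
        return VesselSpec(kind="straight", length_mm=segment_len_mm,
                          radius_start_mm=radius_mm, radius_end_mm=radius_mm,
                          start=start, direction=direction)
    return VesselSpec(
        kind="polyline_with_bends",
        bend_angles_deg=tuple(bend_angles_deg),
        segment_len_mm=segment_len_mm,
        fillet_radius_mm=fillet_radius_mm,
        radius_start_mm=radius_mm,
        radius_end_mm=radius_mm,
        start=start,
        direction=direction,
    )


def _sample_polyline_with_bends(spec: VesselSpec, step: float):
    """Sample the filleted polyline; returns (points, bends metadata)."""
    u = _unit(spec.direction)
    v = _perp(u)  # in-plane normal
    angles = np.deg2rad(np.asarray(spec.bend_angles_deg, dtype=float))
    signs = [1 if k % 2 == 0 else -1 for k in range(len(angles))]
    Rf = spec.fillet_radius_mm
    L = spec.segment_len_mm

    pts: list[np.ndarray] = []
    bends: list[dict] = []
    pos = np.asarray(spec.start, dtype=float)
    theta = 0.0  # heading in the (u, v) plane
    s_acc = 0.0

    def heading(th):
        return np.cos(th) * u + np.sin(th) * v

    n_seg = len(angles) + 1
    for k in range(n_seg):
        t_in = Rf * np.tan(angles[k - 1] / 2) if k > 0 else 0.0
        t_out = Rf * np.tan(angles[k] / 2) if k < len(angles) else 0.0
        straight = L - t_in - t_out
        d = heading(theta)
        n = max(2, int(np.ceil(straight / step)) + 1)
        seg = pos + np.outer(np.linspace(0.0, straight, n), d)
        pts.append(seg if k == 0 else seg[1:])
        pos = pos + straight * d
        s_acc += straight
        if k < len(angles):
            ang, sgn = angles[k], signs[k]
            arc_len = Rf * ang
            # fillet arc: rotate heading by sgn*ang about the fillet center
            center = pos + Rf * (np.cos(theta + sgn * np.pi / 2) * u
                                 + np.sin(theta + sgn * np.pi / 2) * v)
            phi0 = theta - sgn * np.pi / 2
            m = max(3, int(np.ceil(arc_len / step)) + 1)
            phis = phi0 + sgn * np.linspace(0.0, ang, m)
            arc = center + Rf * (np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v)
            pts.append(arc[1:])
            bends.append({
                "branch": None,
                "angle_deg": float(np.rad2deg(ang)),
                "abscissa_mm": float(s_acc + arc_len / 2),
            })
            pos = arc[-1]
            theta += sgn * ang
            s_acc += arc_len
    return np.vstack(pts), bends


def sample_centerline(spec: VesselSpec, step: float = _FINE_STEP_MM):
    """Sample the true centerline at ~``step`` mm.

    Returns ``(points, abscissa, bends)`` where ``points`` is (N, 3) in mm,
    ``abscissa`` the cumulative arc length and ``bends`` the per-bend metadata
    (empty for kinds other than ``polyline_with_bends``).
    """
    start = np.asarray(spec.start, dtype=float)
    u = _unit(spec.direction)
    bends: list[dict] = []
    if spec.kind == "straight":
        n = max(2, int(np.ceil(spec.length_mm / step)) + 1)
        t = np.linspace(0.0, spec.length_mm, n)
        pts = start + np.outer(t, u)
    elif spec.kind == "circular_arc":
        R = spec.arc_radius_mm
        ang = np.deg2rad(spec.arc_angle_deg)
        v = _perp(u)
        n = max(2, int(np.ceil(R * ang / step)) + 1)
        phis = np.linspace(0.0, ang, n)
        # starts at `start` with tangent u, curving toward v
        center = start + R * v
        pts = center + R * (np.sin(phis)[:, None] * u - np.cos(phis)[:, None] * v)
    elif spec.kind == "helix":
        a = spec.helix_radius_mm
        b = spec.helix_pitch_mm / (2 * np.pi)
        t_max = 2 * np.pi * spec.turns
        n = max(2, int(np.ceil(t_max * np.hypot(a, b) / step)) + 1)
        t = np.linspace(0.0, t_max, n)
        v = _perp(u)
        w = np.cross(u, v)
        # axis along u; transverse circle in (v, w); tangent at t=0 is along w+pitch
        pts = (start + a * (np.cos(t)[:, None] - 1) * v + a * np.sin(t)[:, None] * w
               + b * t[:, None] * u)
    else:
        pts, bends = _sample_polyline_with_bends(spec, step)
    deltas = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(deltas)])
    return pts, s, bends


def analytic_tortuosity(spec: VesselSpec, window_mm: float = 10.0) -> float:
    """Closed-form arc/chord tortuosity for a window centered mid-vessel.

    straight -> 1; circular arc -> s / (2R sin(s/2R)); helix -> s over the
    helical chord.  Filleted polylines have no closed form (use the sampled
    centerline as oracle instead).
    """
    if window_mm <= 0:
        raise ValueError("window must be positive")
    if spec.kind == "straight":
        return 1.0
    if spec.kind == "circular_arc":
        R = spec.arc_radius_mm
        s = min(window_mm, spec.arc_length())
        return float(s / (2 * R * np.sin(s / (2 * R))))
    if spec.kind == "helix":
        a = spec.helix_radius_mm
        b = spec.helix_pitch_mm / (2 * np.pi)
        s = min(window_mm, spec.arc_length())
        dt = s / np.hypot(a, b)
        chord = np.hypot(2 * a * np.sin(dt / 2), b * dt)
        return float(s / chord)
    raise ValueError("no closed form for polyline_with_bends; use the sampled oracle")


# ---------------------------------------------------------------------------
# rasterization


def _rasterize_tube(shape, spacing, origin, pts, radii, chunk=400_000):
    """Binary mask of the tube swept along ``pts`` with per-point ``radii``.

    A voxel center x is inside when, for its nearest centerline sample i with
    tangent t_i, the perpendicular distance to the local axis is <= r_i and x
    does not lie beyond the flat end caps.
    """
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    tree = cKDTree(pts)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    rmax = float(np.max(radii))
    lo = np.maximum(np.floor((pts.min(0) - rmax - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((pts.max(0) + rmax - origin) / spacing).astype(int) + 2,
                    np.asarray(shape))
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    sub = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    for beg in range(0, len(sub), chunk):
        idx = sub[beg:beg + chunk]
        x = origin + idx * spacing
        dist, i = tree.query(x, k=1)
        near = dist <= radii[i] + 1e-9
        if not np.any(near):
            continue
        xi, ii = x[near], i[near]
        d = xi - pts[ii]
        ax = np.einsum("ij,ij->i", d, tangents[ii])
        perp2 = np.einsum("ij,ij->i", d, d) - ax**2
        inside = perp2 <= radii[ii] ** 2 + 1e-9
        # flat end caps
        inside &= ~((ii == 0) & (ax < 0)) & ~((ii == len(pts) - 1) & (ax > 0))
        keep = idx[near][inside]
        mask[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    return mask


def _rasterize_ellipsoid(shape, spacing, origin, center, axes_dirs, semi_axes,
                         reach=1.0):
    """Ellipsoid mask plus the normalized radial coordinate (0 center,
    1 at the stated surface) of the inside voxels; the mask extends out to
    ``reach`` in that radial coordinate."""
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    amax = max(semi_axes) * reach
    lo = np.maximum(np.floor((center - amax - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((center + amax - origin) / spacing).astype(int) + 2,
                    np.asarray(shape))
    mask = np.zeros(shape, dtype=bool)
    rhat = np.ones(shape)
    if np.any(lo >= hi):
        return mask, rhat
    sub = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    x = origin + sub * spacing - center
    q = np.zeros(len(x))
    for e, a in zip(axes_dirs, semi_axes):
        q += (x @ e) ** 2 / a**2
    inside = q <= reach**2
    keep = sub[inside]
    mask[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    rhat[keep[:, 0], keep[:, 1], keep[:, 2]] = np.sqrt(q[inside])
    return mask, rhat


def _pair_overlap_ok(parent, child) -> bool:
    """True when the two tubes touch only at a declared junction.

    A junction means the child's start lies on the parent centerline; from
    there the lumens may share one initial contact run while the child peels
    away, as long as the centerline separation never re-approaches (which
    would re-merge the lumens and make abscissae ambiguous)."""
    (pp, sp, rp), (pc, sc, rc) = parent, child
    tree = cKDTree(pp)
    d, idx = tree.query(pc, k=1)
    touching = d < rp[idx] + rc
    if not np.any(touching):
        return True
    if d[0] > 0.5:  # no declared junction: no touching allowed at all
        return False
    run_end = int(np.argmin(touching)) if not touching.all() else len(touching)
    if np.any(touching[run_end:]):
        return False  # re-contact downstream of the junction
    run_d = d[:run_end]
    return bool(np.all(np.maximum.accumulate(run_d) - run_d < 0.5))


def _check_no_spurious_merge(spec: PhantomSpec, samples):
    """Vessels may touch only at declared junctions (a child's start lying on
    a parent); any other lumen overlap makes ground-truth abscissae ambiguous."""
    geo = [(p, s, spec.vessels[k].radius_at(s))
           for k, (p, s, _) in enumerate(samples)]
    for i in range(len(geo)):
        for j in range(i + 1, len(geo)):
            if not (_pair_overlap_ok(geo[i], geo[j]) or _pair_overlap_ok(geo[j], geo[i])):
                raise ValueError(
                    f"vessels {i} and {j} merge lumens away from any declared junction"
                )


def generate_phantom(spec: PhantomSpec):
    """Rasterize a :class:`PhantomSpec`.

    Returns ``(image, coronary_labels, aorta_labels, truth)``.  The image is
    painted from the label maps with the stated intensities, convolved with a
    Gaussian PSF of ``blur_sigma_mm`` and corrupted with seeded i.i.d.
    Gaussian noise; ground truth is populated analytically beforehand.  The
    output is a deterministic function of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    samples = [sample_centerline(v, step=min(spec.spacing) / 2) for v in spec.vessels]
    _check_no_spurious_merge(spec, samples)

    # ground truth (analytic, pre-rasterization)
    truth_cls, truth_abs, truth_bends, truth_tort = [], [], [], []
    for i, (v, (pts, s, bends)) in enumerate(zip(spec.vessels, samples)):
        truth_cls.append(pts)
        truth_abs.append(s)
        for b in bends:
            b = dict(b)
            b["branch"] = i
            truth_bends.append(b)
        try:
            truth_tort.append(analytic_tortuosity(v))
        except ValueError:
            truth_tort.append(None)

    root = np.asarray(spec.vessels[0].start, dtype=float)
    u0 = _unit(spec.vessels[0].direction)
    w = _perp(u0)
    ao_center = root - (spec.aorta.radius_mm + spec.aorta.gap_mm) * w
    ao_axis = _unit(np.cross(u0, w))
    ao_pts = ao_center + np.outer(
        np.linspace(-spec.aorta.length_mm / 2, spec.aorta.length_mm / 2,
                    max(2, int(spec.aorta.length_mm / min(spec.spacing) * 2))), ao_axis)

    all_pts = np.vstack([p for p, _, _ in samples] + [ao_pts])
    rmax = max(max(v.radius_start_mm, v.radius_end_mm) for v in spec.vessels)
    rmax = max(rmax, spec.aorta.radius_mm)
    lo = all_pts.min(0) - rmax - spec.margin_mm
    hi = all_pts.max(0) + rmax + spec.margin_mm
    spacing = np.asarray(spec.spacing, dtype=float)
    # fixed sub-voxel offset: keeps analytically axis-aligned structures from
    # degenerate lattice alignment (voxel centers exactly on tube boundaries),
    # which would bias voxel-counting volumes
    origin = lo - spacing * np.array([0.2347, 0.3719, 0.4583])
    shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 1)

    coronary = np.zeros(shape, dtype=bool)
    for v, (pts, s, _) in zip(spec.vessels, samples):
        coronary |= _rasterize_tube(shape, spacing, origin, pts, v.radius_at(s))
    aorta = _rasterize_tube(shape, spacing, origin, ao_pts,
                            np.full(len(ao_pts), spec.aorta.radius_mm))

    lesion_masks, lesion_truth = [], []
    for les in spec.lesions:
        pts, s, _ = samples[les.vessel_index]
        k = int(np.searchsorted(s, les.center_abscissa_mm))
        k = min(max(k, 1), len(pts) - 2)
        center = pts[k]
        tang = _unit(pts[k + 1] - pts[k - 1])
        e2 = _perp(tang)
        e3 = np.cross(tang, e2)
        a_mean = float(np.mean(les.axis_lengths_mm))
        reach = 1.0 + (les.margin_mm / a_mean) / 2 if a_mean > 0 else 1.0
        m, rhat = _rasterize_ellipsoid(shape, spacing, origin, center,
                                       [tang, e2, e3], les.axis_lengths_mm,
                                       reach=reach)
        lesion_masks.append((m, rhat))
        lesion_truth.append({
            "center_xyz_mm": center.tolist(),
            "volume_mm3": les.volume_mm3,
            "extent_mm": 2 * les.axis_lengths_mm[0],
            "min_abscissa_mm": les.center_abscissa_mm - les.axis_lengths_mm[0],
            "center_abscissa_mm": les.center_abscissa_mm,
            "vessel_index": les.vessel_index,
            "peak_intensity": les.peak_intensity,
        })

    # tissue texture is spatially correlated (contrast mixing, perfusion),
    # not voxel-i.i.d., so it survives the PSF with its stated SD
    field = rng.standard_normal(shape)
    if spec.texture_corr_mm > 0:
        field = ndimage.gaussian_filter(field, sigma=spec.texture_corr_mm / spacing)
    sd = field.std()
    field /= sd if sd > 0 else 1.0
    blood = coronary | aorta
    img = np.where(blood,
                   spec.blood_mean_hu + field * spec.blood_sd_hu,
                   spec.background_mean_hu + field * spec.background_sd_hu)
    for (m, rhat), les in zip(lesion_masks, spec.lesions):
        # linear density ramp of width margin_mm centered on the stated
        # surface (r_hat = 1): surface voxels carry half density
        a_mean = float(np.mean(les.axis_lengths_mm))
        margin = min(les.margin_mm / a_mean, 1.0) if a_mean > 0 else 0.0
        if margin > 0:
            density = np.clip((1.0 + margin / 2 - rhat[m]) / margin, 0.0, 1.0)
        else:
            density = (rhat[m] <= 1.0).astype(float)
        paint = spec.blood_mean_hu + (les.peak_intensity - spec.blood_mean_hu) * density
        img[m] = np.maximum(img[m], paint)
    if spec.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma_mm / spacing)
    img = img + rng.normal(0.0, spec.noise_sd_hu, shape)

    image = ImageVolume(img.astype(np.float32), spacing, origin)
    cor_lab = LabelMap(coronary.astype(np.uint8), spacing, origin)
    ao_lab = LabelMap(aorta.astype(np.uint8), spacing, origin)
    truth = PhantomGroundTruth(
        centerlines=truth_cls, abscissae=truth_abs, bends=truth_bends,
        lesions=lesion_truth, analytic_tortuosity=truth_tort, ostium=root,
    )
    return image, cor_lab, ao_lab, truth
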