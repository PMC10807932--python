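"""Seeded recovery suites that quantify how well the pipeline recovers
phantom ground truth.

Two suites are frozen here so that tests and the reproduction script measure
the same conditions:

* **bend/TS recovery** — 20 filleted-polyline branches with prescribed bend
  angles drawn from a 5-degree grid over 20-80 degrees.  The 45-degree value
  itself is omitted from the grid: a bend exactly at the counting threshold
  is ill-posed under any finite measurement precision.  The tortuosity stage
  runs on the analytic centerlines, isolating the estimator from
  voxelization.
* **calcium recovery** — 20 ellipsoidal lesions (semi-axes 1.5-4 mm) spread
  over five two-vessel phantoms at 0.4 mm spacing; the full chain
  (rasterize, centerline, threshold, grow, project) runs and detected
  lesions are matched to truth by centroid.  Errors are summarized as mean
  absolute deviations across the suite: at 0.4 mm voxels a half-voxel
  surface shell on the smallest lesions is already a ~35% volume change, so
  per-lesion volume accuracy is resolution-limited while the suite mean is
  meaningful.
"""

from __future__ import annotations

import numpy as np

from .calcium import analyze_calcium
from .centerline import branch_from_points, build_tree
from .phantom import (LesionSpec, PhantomSpec, VesselSpec, generate_phantom,
                      make_bent_branch, sample_centerline)
from .tortuosity import TortuosityParams, compute_profile, detect_bends

__all__ = ["bend_recovery_suite", "calcium_recovery_suite"]

#: prescribed bend-angle grid (degrees); 45 is the TS counting threshold and
#: deliberately absent
BEND_ANGLE_GRID = [20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 55.0,
                   60.0, 65.0, 70.0, 75.0, 80.0]


def bend_recovery_suite(n_branches: int = 20, seed: int = 0,
                        params: TortuosityParams | None = None) -> dict:
    """Recover prescribed bend angles and per-branch TS qualification.

    Returns ``ts_matches`` (branches whose >=3-bends status matches the
    prescription), ``n_branches``, ``bend_angle_mae_deg`` (over detected
    bends, paired to the nearest prescribed bend) and the per-branch detail.
    """
    params = params or TortuosityParams()
    rng = np.random.default_rng(seed)
    matches = 0
    abs_errors: list[float] = []
    detail = []
    for _ in range(n_branches):
        n_bends = int(rng.integers(2, 5))
        angles = [float(rng.choice(BEND_ANGLE_GRID)) for _ in range(n_bends)]
        spec = make_bent_branch(angles, 25.0, fillet_radius_mm=1.0)
        pts, _, true_bends = sample_centerline(spec, step=0.1)
        branch = branch_from_points(pts, resample_mm=0.5)
        bends = detect_bends(compute_profile(branch, params), branch, 0, params)
        true_qualifies = sum(a >= params.ta_threshold_deg for a in angles) >= params.min_bends
        found_qualifies = len(bends) >= params.min_bends
        matches += true_qualifies == found_qualifies
        for b in bends:
            nearest = min(true_bends, key=lambda t: abs(t["abscissa_mm"] - b.abscissa_mm))
            abs_errors.append(abs(b.angle_deg - nearest["angle_deg"]))
        detail.append({"angles": angles, "n_detected": len(bends),
                       "true_qualifies": true_qualifies,
                       "found_qualifies": found_qualifies})
    return {
        "n_branches": n_branches,
        "ts_matches": matches,
        "bend_angle_mae_deg": float(np.mean(abs_errors)) if abs_errors else 0.0,
        "detail": detail,
    }


def _calcium_phantom(index: int, seed: int) -> PhantomSpec:
    radii_pool = [1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
    v1 = VesselSpec(kind="straight", length_mm=90.0,
                    radius_start_mm=3.0, radius_end_mm=2.0)
    v2 = VesselSpec(kind="straight", length_mm=60.0, radius_start_mm=2.5,
                    radius_end_mm=1.8, start=(25.0, 0.0, 0.0),
                    direction=(0.8, 0.6, 0.0))
    radii = [radii_pool[(index * 4 + k) % len(radii_pool)] for k in range(4)]
    lesions = [
        LesionSpec(center_abscissa_mm=c, axis_lengths_mm=(a, 0.8 * a, 0.8 * a))
        for c, a in zip((20.0, 45.0, 70.0), radii[:3])
    ]
    lesions.append(LesionSpec(center_abscissa_mm=35.0, vessel_index=1,
                              axis_lengths_mm=(radii[3], 0.8 * radii[3], 0.8 * radii[3])))
    return PhantomSpec(vessels=[v1, v2], lesions=lesions, seed=seed)


def calcium_recovery_suite(n_phantoms: int = 5, seed: int = 0) -> dict:
    """Full-chain lesion recovery over ``4 * n_phantoms`` seeded lesions."""
    vol_err, extent_err, minabs_err = [], [], []
    n_true = n_detected = 0
    for ph in range(n_phantoms):
        spec = _calcium_phantom(ph, seed=(seed * 1000 + ph) % (2**31 - 1))
        image, coronary, aorta, truth = generate_phantom(spec)
        trees = build_tree(coronary, aorta)
        report = analyze_calcium(image, coronary, aorta, trees)
        n_true += len(truth.lesions)
        n_detected += len(report.lesions)
        centroids = [image.index_to_world(l.voxels).mean(axis=0)
                     for l in report.lesions]
        # junction offset: vessel 1 joins the root vessel at abscissa 25 mm
        for t in truth.lesions:
            if not centroids:
                continue
            c = np.asarray(t["center_xyz_mm"])
            j = int(np.argmin([np.linalg.norm(c - x) for x in centroids]))
            det = report.lesions[j]
            vol_err.append(det.volume_mm3 / t["volume_mm3"] - 1.0)
            extent_err.append(det.extent_mm - t["extent_mm"])
            offset = 25.0 if t["vessel_index"] == 1 else 0.0
            minabs_err.append(det.min_abscissa_mm - (t["min_abscissa_mm"] + offset))
    return {
        "n_true_lesions": n_true,
        "n_detected_lesions": n_detected,
        "volume_mean_abs_rel_err": float(np.mean(np.abs(vol_err))),
        "extent_mean_abs_err_mm": float(np.mean(np.abs(extent_err))),
        "min_abscissa_mean_abs_err_mm": float(np.mean(np.abs(minabs_err))),
        "volume_rel_errors": [float(v) for v in vol_err],
    }
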