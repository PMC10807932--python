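"""Coronary calcium detection and scoring with a patient-specific threshold.

Calcium cannot be detected in contrast-enhanced CT with the fixed 130 HU rule
used on non-contrast scans, because the opacified lumen itself exceeds it.
Instead, a patient-specific attenuation threshold is derived from the aortic
blood pool::

    theta_HU = mu_Ao + k_sigma * sigma_Ao        (k_sigma = 2.5)

Voxels at or above ``theta_HU`` inside the (dilated) coronary volume are the
lesion candidates; each candidate lesion is refined by region growing into
26-neighbours whose attenuation exceeds the 98th percentile of the
attenuation inside the coronary search volume, until a fixpoint.  Lesions
whose maximal axial cross-section is below 1 mm^2 are removed as artifacts
(a volumetric 1 mm^3 reading is available via ``area_mode="volume"``).

Each lesion is projected onto the centerline tree: its distance from the
ostium is the minimum abscissa over the mapped points, its extent the
max-min abscissa difference, and its zone the geodesic zone of the
min-abscissa point.  Scoring reports the volume score (VS, mm^3) per zone and
total, and the percentage of plaque volume PPV = 100 * VS_total / lumen
volume.  The coronary mask is dilated by ``search_dilation_mm`` before
candidate search because lumen annotations may exclude wall plaque.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .centerline import CenterlineTree, assign_zone, tree_points
from .volume import ImageVolume, LabelMap

__all__ = [
    "CacParams",
    "CalciumLesion",
    "CalciumReport",
    "patient_threshold",
    "search_volume",
    "detect_candidates",
    "grow_lesions",
    "filter_artifacts",
    "project_to_centerline",
    "score",
    "analyze_calcium",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CacParams:
    k_sigma: float = 2.5            # multiplier on the aortic SD
    growth_percentile: float = 98.0  # region-growing attenuation gate
    min_lesion_area_mm2: float = 1.0  # artifact filter
    search_dilation_mm: float = 2.0   # lumen dilation for the search volume
    area_mode: str = "axial_area"     # or "volume" (then the filter is mm^3)

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if not 50.0 < self.growth_percentile < 100.0:
            raise ValueError("growth_percentile must lie in (50, 100)")
        if self.area_mode not in ("axial_area", "volume"):
            raise ValueError("area_mode must be 'axial_area' or 'volume'")


@dataclass
class CalciumLesion:
    """One connected calcific lesion (26-connectivity)."""

    voxels: np.ndarray              # (N, 3) voxel indices
    volume_mm3: float
    mean_hu: float
    min_abscissa_mm: float = float("nan")
    max_abscissa_mm: float = float("nan")
    zone: str | None = None

    @property
    def extent_mm(self) -> float:
        return self.max_abscissa_mm - self.min_abscissa_mm


@dataclass
class CalciumReport:
    lesions: list[CalciumLesion] = field(default_factory=list)
    vs_by_zone: dict = field(default_factory=dict)   # zone -> mm^3
    vs_total_mm3: float = 0.0
    ppv_percent: float = 0.0
    shortest_distance_mm: float = float("nan")       # nearest lesion from ostium
    longest_distance_mm: float = float("nan")
    theta_hu: float = float("nan")


# ---------------------------------------------------------------------------


def patient_threshold(image: ImageVolume, aorta: LabelMap, k_sigma: float = 2.5) -> float:
    """theta_HU = mean + k_sigma * SD of image attenuation inside the aorta."""
    image.check_same_grid(aorta, "image and aorta mask")
    vals = image.data[aorta.data > 0]
    if vals.size == 0:
        raise ValueError("empty aorta mask")
    return float(vals.mean() + k_sigma * vals.std())


def search_volume(coronary: LabelMap, dilation_mm: float) -> np.ndarray:
    """Coronary mask dilated by a ball of ``dilation_mm`` (grid-anisotropic)."""
    if dilation_mm <= 0:
        return coronary.data > 0
    dt = ndimage.distance_transform_edt(coronary.data == 0, sampling=coronary.spacing)
    return dt <= dilation_mm


def detect_candidates(
    image: ImageVolume,
    coronary: LabelMap,
    theta_hu: float,
    search_dilation_mm: float = 2.0,
) -> np.ndarray:
    """Boolean mask of candidate calcium voxels: attenuation >= theta_HU
    within the dilated coronary volume."""
    image.check_same_grid(coronary, "image and coronary mask")
    return (image.data >= theta_hu) & search_volume(coronary, search_dilation_mm)


def grow_lesions(
    image: ImageVolume,
    candidates: np.ndarray,
    coronary: LabelMap,
    growth_percentile: float = 98.0,
    search_dilation_mm: float = 2.0,
) -> np.ndarray:
    """Region growing to a fixpoint.

    26-neighbours of the current lesion set are added whenever their
    attenuation exceeds the given percentile of the attenuation inside the
    coronary arteries (the lumen mask proper: with a calcific burden present
    that percentile sits at the foot of the calcium intensities, which is
    what makes the expansion selective); growth is confined to the dilated
    search volume so the plaque can extend beyond the lumen annotation
    without leaking into the aortic blood pool.  The output is a superset of
    the input.
    """
    sv = search_volume(coronary, search_dilation_mm)
    vals = image.data[coronary.data > 0]
    if vals.size == 0:
        return candidates.copy()
    gate = float(np.percentile(vals, growth_percentile))
    allowed = (image.data > gate) & sv
    grown = candidates.copy()
    while True:
        nxt = grown | (ndimage.binary_dilation(grown, structure=_STRUCT26) & allowed)
        if np.array_equal(nxt, grown):
            return nxt
        grown = nxt


def _split_lesions(mask: np.ndarray, image: ImageVolume) -> list[CalciumLesion]:
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    voxvol = image.voxel_volume_mm3
    out = []
    for comp in range(1, n + 1):
        vox = np.argwhere(labels == comp)
        out.append(CalciumLesion(
            voxels=vox,
            volume_mm3=len(vox) * voxvol,
            mean_hu=float(image.data[labels == comp].mean()),
        ))
    return out


def filter_artifacts(
    lesions: Sequence[CalciumLesion],
    image: ImageVolume,
    min_lesion_area_mm2: float = 1.0,
    area_mode: str = "axial_area",
) -> list[CalciumLesion]:
    """Remove lesions below the artifact size floor.

    ``axial_area`` (default): the maximal per-axial-slice (z) cross-sectional
    area must reach ``min_lesion_area_mm2``.  ``volume``: the lesion volume
    must reach the same number read as mm^3.
    """
    pixel_area = float(image.spacing[0] * image.spacing[1])
    kept = []
    for les in lesions:
        if area_mode == "volume":
            size = les.volume_mm3
        else:
            _, counts = np.unique(les.voxels[:, 2], return_counts=True)
            size = float(counts.max()) * pixel_area
        if size >= min_lesion_area_mm2:
            kept.append(les)
    return kept


def project_to_centerline(
    lesion: CalciumLesion,
    trees: CenterlineTree | Sequence[CenterlineTree],
    image: ImageVolume,
) -> CalciumLesion:
    """Map every lesion voxel to its nearest centerline point (Euclidean, mm)
    and derive min/max abscissa, extent and zone (zone of the min-abscissa
    mapped point); fills the lesion in place and returns it."""
    pts, abscissa, g = tree_points(trees)
    tree = cKDTree(pts)
    world = image.index_to_world(lesion.voxels)
    _, idx = tree.query(world, k=1)
    mapped_s = abscissa[idx]
    k = int(np.argmin(mapped_s))
    lesion.min_abscissa_mm = float(mapped_s[k])
    lesion.max_abscissa_mm = float(mapped_s.max())
    lesion.zone = assign_zone(float(np.clip(g[idx[k]], 0.0, 1.0)))
    return lesion


def score(lesions: Sequence[CalciumLesion], coronary_volume_mm3: float,
          theta_hu: float = float("nan")) -> CalciumReport:
    """Aggregate characterized lesions into a :class:`CalciumReport`."""
    if coronary_volume_mm3 <= 0:
        raise ValueError("coronary vessel volume must be positive")
    vs_by_zone = {z: 0.0 for z in ("proximal", "medial", "distal")}
    for les in lesions:
        if les.zone is None:
            raise ValueError("lesions must be projected onto the centerline first")
        vs_by_zone[les.zone] += les.volume_mm3
    total = sum(vs_by_zone.values())
    dists = [les.min_abscissa_mm for les in lesions]
    return CalciumReport(
        lesions=list(lesions),
        vs_by_zone=vs_by_zone,
        vs_total_mm3=total,
        ppv_percent=100.0 * total / coronary_volume_mm3,
        shortest_distance_mm=float(min(dists)) if dists else float("nan"),
        longest_distance_mm=float(max(dists)) if dists else float("nan"),
        theta_hu=theta_hu,
    )


def analyze_calcium(
    image: ImageVolume,
    coronary: LabelMap,
    aorta: LabelMap,
    trees: CenterlineTree | Sequence[CenterlineTree],
    params: CacParams | None = None,
) -> CalciumReport:
    """Full calcium stage: threshold -> candidates -> growing -> artifact
    filter -> centerline projection -> scoring."""
    params = params or CacParams()
    theta = patient_threshold(image, aorta, params.k_sigma)
    cand = detect_candidates(image, coronary, theta, params.search_dilation_mm)
    if np.any(cand):
        grown = grow_lesions(image, cand, coronary, params.growth_percentile,
                             params.search_dilation_mm)
    else:
        grown = cand
    lesions = _split_lesions(grown, image)
    lesions = filter_artifacts(lesions, image, params.min_lesion_area_mm2,
                               params.area_mode)
    lesions = [project_to_centerline(les, trees, image) for les in lesions]
    return score(lesions, coronary.volume_mm3, theta)
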