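"""Intensity preprocessing, seeded augmentation and multi-view fusion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volume import ImageVolume, LabelMap

__all__ = ["PosteriorVolume", "preprocess", "augment", "fuse_multiview"]

CLIP_HU = (-30.0, 800.0)


@dataclass
class PosteriorVolume(ImageVolume):
    """Per-voxel foreground probability on the grid model of ImageVolume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("posterior probabilities must lie in [0, 1]")


def preprocess(vol: ImageVolume) -> ImageVolume:
    """Clip attenuation to [-30, 800] HU, then z-score over the clipped volume.

    The clipping window brackets soft tissue through dense calcium; the
    z-score decouples network inputs from scanner offsets.  A constant volume
    has zero SD and is rejected.
    """
    data = np.clip(vol.data.astype(float), *CLIP_HU)
    sd = data.std()
    if sd == 0:
        raise ValueError("constant image cannot be normalized (zero SD)")
    return ImageVolume((data - data.mean()) / sd, vol.spacing, vol.origin, vol.direction)


def augment(
    vol: ImageVolume,
    labels: LabelMap,
    seed: int,
    *,
    p_blur: float = 0.2,
    blur_sigma_mm: tuple[float, float] = (0.25, 0.75),
    p_affine: float = 0.3,
    max_rotation_deg: float = 10.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> tuple[ImageVolume, LabelMap]:
    """Seeded random Gaussian smoothing + small affine, applied jointly.

    The image is interpolated linearly, the labels with nearest neighbour so
    they stay binary.  With both probabilities forced to zero this is the
    identity; the same seed always reproduces the same pair.
    """
    vol.check_same_grid(labels, "image and labels")
    rng = np.random.default_rng(seed)
    img = vol.data.astype(float).copy()
    lab = labels.data.copy()
    if rng.random() < p_blur:
        sigma_mm = rng.uniform(*blur_sigma_mm)
        img = ndimage.gaussian_filter(img, sigma=sigma_mm / vol.spacing)
    if rng.random() < p_affine:
        angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
        scale = rng.uniform(*scale_range)
        axis = rng.integers(0, 3)
        # rotation about one grid axis, uniform scaling, centered on the grid
        c, s = np.cos(angle), np.sin(angle)
        rot = np.eye(3)
        ax = [i for i in range(3) if i != axis]
        rot[np.ix_(ax, ax)] = np.array([[c, -s], [s, c]])
        mat = rot / scale
        center = (np.asarray(vol.shape) - 1) / 2
        offset = center - mat @ center
        img = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                       mode="nearest")
        lab = ndimage.affine_transform(lab, mat, offset=offset, order=0,
                                       mode="constant", cval=0)
    return (ImageVolume(img, vol.spacing, vol.origin, vol.direction),
            LabelMap(lab, labels.spacing, labels.origin, labels.direction))


def fuse_multiview(
    y_ax: PosteriorVolume,
    y_cor: PosteriorVolume,
    y_sag: PosteriorVolume,
    threshold: float = 0.5,
) -> LabelMap:
    """Element-wise maximum of the three per-view foreground posteriors,
    thresholded into a binary label map."""
    y_ax.check_same_grid(y_cor, "axial and coronal posteriors")
    y_ax.check_same_grid(y_sag, "axial and sagittal posteriors")
    fused = np.maximum(np.maximum(y_ax.data, y_cor.data), y_sag.data)
    return LabelMap((fused >= threshold).astype(np.uint8),
                    y_ax.spacing, y_ax.origin, y_ax.direction)
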