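"""Smoke-scale training of the segmentation stages on synthetic phantoms.

This trains small-width networks for a handful of epochs on a handful of
straight-tube phantoms — enough to demonstrate that the losses, gradients and
data plumbing are correct (loss decreases, validation Dice clears an easy
floor), not to reproduce cohort-scale segmentation accuracy.  Stage 1 trains
a 2D network on slices of one view; stage 2 trains the 3D network on small
patches with the preliminary mask as a second channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..phantom import AortaSpec, PhantomSpec, VesselSpec, generate_phantom
from ..volume import ImageVolume, LabelMap
from .losses import LossParams, dice_focal_grad, dice_focal_loss
from .preprocess import preprocess
from .unet import Adam, UNet, UNetConfig, build_unet

__all__ = ["SmokeTrainResult", "make_smoke_phantoms", "smoke_train"]


@dataclass
class SmokeTrainResult:
    model: UNet
    epoch_losses: list[float]
    val_dsc: float
    stage: int
    seed: int
    history: dict = field(default_factory=dict)


def make_smoke_phantoms(n: int = 8, seed: int = 0) -> list[tuple[ImageVolume, LabelMap]]:
    """Small straight-tube phantoms (varied radius/length/direction) for
    segmentation smoke tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        radius = float(rng.uniform(1.5, 2.5))
        length = float(rng.uniform(18.0, 24.0))
        tilt = rng.normal(0, 0.08, 3)
        direction = np.array([1.0, 0.0, 0.0]) + tilt
        spec = PhantomSpec(
            vessels=[VesselSpec(kind="straight", length_mm=length,
                                radius_start_mm=radius, radius_end_mm=radius,
                                direction=tuple(direction / np.linalg.norm(direction)))],
            aorta=AortaSpec(radius_mm=3.0, length_mm=10.0),
            spacing=(0.5, 0.5, 0.5),
            margin_mm=4.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, coronary, _, _ = generate_phantom(spec)
        out.append((image, coronary))
    return out


def _fit_plane(arr: np.ndarray, size: int) -> np.ndarray:
    """Center crop/pad the first two axes of a 2D array to (size, size)."""
    out = np.zeros((size, size), dtype=arr.dtype)
    sx, sy = arr.shape
    cx, cy = sx // 2, sy // 2
    hx, hy = min(size, sx), min(size, sy)
    ox, oy = (size - hx) // 2, (size - hy) // 2
    x0, y0 = cx - hx // 2, cy - hy // 2
    out[ox:ox + hx, oy:oy + hy] = arr[x0:x0 + hx, y0:y0 + hy]
    return out


def _slice_stack(image: ImageVolume, labels: LabelMap, size: int):
    """(n, size, size) image and label slices along the axial (z) axis."""
    img = preprocess(image).data
    lab = labels.data
    xs = np.stack([_fit_plane(img[:, :, k], size) for k in range(img.shape[2])])
    ys = np.stack([_fit_plane(lab[:, :, k], size) for k in range(lab.shape[2])])
    return xs, ys


def _dsc_arrays(pred: np.ndarray, ref: np.ndarray) -> float:
    tp = float(np.sum((pred > 0) & (ref > 0)))
    denom = float(pred.sum() + ref.sum())
    return 1.0 if denom == 0 else 2.0 * tp / denom


def smoke_train(
    phantoms: list[tuple[ImageVolume, LabelMap]],
    stage: int = 1,
    epochs: int = 5,
    seed: int = 0,
    *,
    base_width: int = 8,
    lr: float = 3e-3,
    batch_size: int = 8,
    slice_size: int = 48,
    slices_per_epoch: int = 192,
    patch_size: int = 16,
    patches_per_epoch: int = 16,
    n_val: int = 2,
) -> SmokeTrainResult:
    """Train a small-width model for a few epochs; returns per-epoch mean
    losses and the held-out Dice.  Deterministic for a fixed seed; raises if
    the loss diverges to NaN (reporting the seed)."""
    if len(phantoms) < 4:
        raise ValueError("smoke training needs at least 4 phantoms")
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    rng = np.random.default_rng(seed)
    train, val = phantoms[:-n_val], phantoms[-n_val:]
    loss_params = LossParams.stage1() if stage == 1 else LossParams.stage2()

    if stage == 1:
        model = build_unet(2, UNetConfig(base_width=base_width), seed=seed)
        xs, ys = [], []
        for image, labels in train:
            a, b = _slice_stack(image, labels, slice_size)
            xs.append(a)
            ys.append(b)
        xs, ys = np.concatenate(xs), np.concatenate(ys)
        fg = np.flatnonzero(ys.reshape(len(ys), -1).any(axis=1))
        n_draw = min(slices_per_epoch, len(xs))

        def sample():
            # foreground-biased sampling: empty slices dominate the stacks,
            # so draw ~70% of each epoch from vessel-bearing slices
            n_fg = min(int(0.7 * n_draw), len(fg))
            pick_fg = rng.choice(fg, size=n_fg, replace=False)
            pick_any = rng.choice(len(xs), size=n_draw - n_fg, replace=False)
            idx = np.concatenate([pick_fg, pick_any])
            rng.shuffle(idx)
            return idx

        get_batch = lambda idx: (xs[idx][:, None], ys[idx][:, None])
    else:
        model = build_unet(3, UNetConfig(base_width=max(4, base_width // 2)), seed=seed)
        vols = []
        for image, labels in train:
            img = preprocess(image).data
            # preliminary mask channel: a deliberately rough version of the
            # labels, as stage 1 would provide
            rough = ndimage.binary_dilation(labels.data > 0, iterations=2)
            vols.append((img, rough.astype(float), labels.data))

        def sample():
            return rng.integers(0, len(vols), size=patches_per_epoch)

        def get_batch(idx):
            ims, labs = [], []
            for i in idx:
                img, rough, lab = vols[i]
                lo = [rng.integers(0, max(1, s - patch_size)) for s in img.shape]
                sl = tuple(slice(l, l + patch_size) for l in lo)
                im = np.stack([_fit3(img[sl], patch_size), _fit3(rough[sl], patch_size)])
                ims.append(im)
                labs.append(_fit3(lab[sl], patch_size)[None])
            return np.stack(ims), np.stack(labs)

    opt = Adam(model, lr=lr)
    epoch_losses: list[float] = []
    for _ in range(epochs):
        idx = sample()
        losses = []
        for beg in range(0, len(idx), batch_size):
            bx, by = get_batch(idx[beg:beg + batch_size])
            logits = model.forward(bx)
            p = 1.0 / (1.0 + np.exp(-logits))
            loss = dice_focal_loss(p, by, loss_params)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"smoke training diverged (loss={loss}, seed={seed})")
            dp = dice_focal_grad(p, by, loss_params)
            model.backward(dp * p * (1.0 - p))
            opt.step()
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))

    # held-out Dice
    tp = fp = fn = 0.0
    if stage == 1:
        for image, labels in val:
            a, b = _slice_stack(image, labels, slice_size)
            for beg in range(0, len(a), batch_size):
                proba = model.predict_proba(a[beg:beg + batch_size][:, None])
                pred = proba[:, 0] >= 0.5
                ref = b[beg:beg + batch_size] > 0
                tp += np.sum(pred & ref)
                fp += np.sum(pred & ~ref)
                fn += np.sum(~pred & ref)
    else:
        vrng = np.random.default_rng(seed + 1)
        for image, labels in val:
            img = preprocess(image).data
            rough = ndimage.binary_dilation(labels.data > 0, iterations=2)
            for _ in range(8):
                lo = [vrng.integers(0, max(1, s - patch_size)) for s in img.shape]
                sl = tuple(slice(l, l + patch_size) for l in lo)
                x = np.stack([_fit3(img[sl], patch_size),
                              _fit3(rough[sl].astype(float), patch_size)])[None]
                pred = model.predict_proba(x)[0, 0] >= 0.5
                ref = _fit3(labels.data[sl], patch_size) > 0
                tp += np.sum(pred & ref)
                fp += np.sum(pred & ~ref)
                fn += np.sum(~pred & ref)
    denom = 2 * tp + fp + fn
    val_dsc = 1.0 if denom == 0 else 2 * tp / denom
    return SmokeTrainResult(model=model, epoch_losses=epoch_losses,
                            val_dsc=float(val_dsc), stage=stage, seed=seed)


def _fit3(arr: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros((size,) * 3, dtype=float)
    sl = tuple(slice(0, min(size, s)) for s in arr.shape)
    out[sl] = arr[sl]
    return out
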