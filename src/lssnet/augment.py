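"""Stochastic training-time augmentation.

Four transforms are applied in a fixed order — scale, translate, rotate,
vertical flip — with parameters drawn uniformly from the ranges used for the
lumbar-ROI task: scale in [0.8, 1.2], translation in [-20, 20] pixels per
axis, rotation in [-15, 15] degrees, vertical flip with probability 0.5.
Geometric resampling is bilinear (matching the resize step); exposed borders
are filled with a constant (0 by default, background-like).

The same module provides offline minority-class oversampling: augmented
copies of minority images are appended until the requested class balance is
reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LabeledImage

__all__ = ["AugmentConfig", "sample_params", "apply_affine", "augment",
           "oversample_minority"]


class AugmentValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AugmentConfig:
    scale_range: tuple[float, float] = (0.8, 1.2)
    translate_range: tuple[float, float] = (-20.0, 20.0)
    rotate_range: tuple[float, float] = (-15.0, 15.0)
    vflip_prob: float = 0.5
    fill_value: float = 0.0
    fill_mode: str = "constant"  # or "reflect"
    seed: int = 0

    def __post_init__(self):
        for name in ("scale_range", "translate_range", "rotate_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise AugmentValidationError(f"{name} is not well-ordered")
        if not 0.0 <= self.vflip_prob <= 1.0:
            raise AugmentValidationError("vflip_prob must be in [0, 1]")
        if self.fill_mode not in ("constant", "reflect"):
            raise AugmentValidationError("fill_mode must be constant or reflect")


def sample_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters (uniform ranges, Bernoulli flip)."""
    return {
        "scale": float(rng.uniform(*cfg.scale_range)),
        "tx": float(rng.uniform(*cfg.translate_range)),
        "ty": float(rng.uniform(*cfg.translate_range)),
        "angle": float(rng.uniform(*cfg.rotate_range)),
        "vflip": bool(rng.random() < cfg.vflip_prob),
    }


def apply_affine(img: np.ndarray, params: dict, cfg: AugmentConfig) -> np.ndarray:
    """Apply scale -> translate -> rotate -> vertical flip about the centre.

    Output has the input's shape; resampling is bilinear (order 1).
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise AugmentValidationError("augment expects a single-channel HxW image")
    H, W = arr.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    s = params["scale"]
    th = math.radians(params["angle"])
    # forward map (applied in order) about the centre:
    #   p_out = R @ (T + S @ p_in)  with all ops centre-relative
    # scipy's affine_transform needs the inverse: p_in = S^-1 @ (R^-1 @ p_out - T)
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    t = np.array([params["ty"], params["tx"]])  # (row, col) displacement
    A = R @ (s * np.eye(2))
    Ainv = np.linalg.inv(A)
    centre = np.array([cy, cx])
    # p_in = Ainv @ (p_out - centre) - Ainv @ R @ t ... careful:
    # p_out = R @ (S @ (p_in - c) + t) + c  =>
    # p_in = S^-1 @ (R^-1 @ (p_out - c) - t) + c
    Sinv = np.eye(2) / s
    M = Sinv @ R.T
    offset = centre - M @ centre - Sinv @ t
    mode = "constant" if cfg.fill_mode == "constant" else "reflect"
    out = ndimage.affine_transform(
        arr, M, offset=offset, order=1, mode=mode, cval=cfg.fill_value)
    if params["vflip"]:
        out = out[::-1, :].copy()
    return out


def augment(img: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """One stochastic augmentation draw; fully determined by `rng` state."""
    return apply_affine(img, sample_params(cfg, rng), cfg)


def oversample_minority(dataset: list[LabeledImage], cfg: AugmentConfig,
                        target_ratio: float) -> list[LabeledImage]:
    """Append augmented copies of minority images until its fraction reaches
    ``target_ratio``. Originals are kept untouched; seeded by ``cfg.seed``.
    """
    labels = np.array([d.label for d in dataset])
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise AugmentValidationError("oversampling requires both classes")
    if not 0.0 <= target_ratio <= 1.0:
        raise AugmentValidationError("target_ratio must be in [0, 1]")
    minority = 1 if n1 < n0 else 0
    n_min, n_maj = (n1, n0) if minority == 1 else (n0, n1)
    if n_min / (n_min + n_maj) >= target_ratio:
        return list(dataset)
    if target_ratio >= 1.0:
        raise AugmentValidationError(
            "target_ratio == 1 is unreachable with the majority class present")
    # smallest n_extra with (n_min + n_extra) / (total + n_extra) >= target_ratio
    n_extra = math.ceil(
        (target_ratio * (n_min + n_maj) - n_min) / (1.0 - target_ratio))
    rng = np.random.default_rng(cfg.seed)
    pool = [d for d in dataset if d.label == minority]
    out = list(dataset)
    for i in range(n_extra):
        src = pool[int(rng.integers(len(pool)))]
        aug = augment(src.image.astype(np.float64), cfg, rng)
        aug16 = np.clip(np.rint(aug), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        out.append(LabeledImage(aug16, src.label, src.condition))
    return out
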