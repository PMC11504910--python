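"""Deterministic image preprocessing: intensity normalization, bilinear
resize, and per-channel demeaning.

The pipeline mirrors what the classifier expects at its input: raw
acquisitions arrive with device-dependent intensity ranges, are min-max
rescaled per image to 0-255, resampled to 224 x 224 with bilinear
interpolation, and finally demeaned per channel. Demeaning statistics are
computed on the training split only and reused for held-out images to avoid
leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessConfig",
    "normalize_intensity",
    "resize_bilinear",
    "standardize",
    "channel_means",
    "apply_demean",
]


class PreprocessValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the deterministic pipeline.

    ``corner_convention`` records the resize convention: half-pixel centres,
    chosen so that identity resize is exact.
    """

    target_size: int = 224
    normalize_lo: float = 0.0
    normalize_hi: float = 255.0
    demean: bool = True
    divide_by_sd: bool = False
    corner_convention: str = "half_pixel"

    def __post_init__(self):
        if not self.normalize_lo < self.normalize_hi:
            raise PreprocessValidationError("normalize_lo must be < normalize_hi")
        if self.target_size < 1:
            raise PreprocessValidationError("target_size must be positive")


def _as_float_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise PreprocessValidationError("image must be HxW or CxHxW")
    return arr


def normalize_intensity(img: np.ndarray,
                        cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Min-max rescale a single image into [normalize_lo, normalize_hi].

    Constant images map to ``normalize_lo`` (deterministic convention that
    avoids division by zero). Idempotent.
    """
    arr = _as_float_image(img)
    if not np.all(np.isfinite(arr)):
        raise PreprocessValidationError("image contains NaN or Inf pixels")
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.full_like(arr, PreprocessConfig().normalize_lo
                            if cfg is None else cfg.normalize_lo)
    scaled = (arr - lo) / (hi - lo)
    return cfg.normalize_lo + scaled * (cfg.normalize_hi - cfg.normalize_lo)


def resize_bilinear(img: np.ndarray,
                    cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Bilinear resample to target_size x target_size (half-pixel centres).

    Identity when the input already has the target size; a 1x1 input yields a
    constant fill of its value.
    """
    arr = _as_float_image(img)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    C, H, W = arr.shape
    Ht = Wt = cfg.target_size
    if (H, W) == (Ht, Wt):
        out = arr.copy()
        return out[0] if squeeze else out
    if H == 1 and W == 1:
        out = np.full((C, Ht, Wt), arr[0, 0, 0], dtype=arr.dtype)
        return out[0] if squeeze else out

    def _coords(n_out: int, n_in: int):
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = src - i0
        return i0, i1, frac

    r0, r1, fr = _coords(Ht, H)
    c0, c1, fc = _coords(Wt, W)
    top = arr[:, r0][:, :, c0] * (1 - fc) + arr[:, r0][:, :, c1] * fc
    bot = arr[:, r1][:, :, c0] * (1 - fc) + arr[:, r1][:, :, c1] * fc
    out = top * (1 - fr)[None, :, None] + bot * fr[None, :, None]
    return out[0] if squeeze else out


def _stack(imgs: list[np.ndarray]) -> np.ndarray:
    arrs = [_as_float_image(im) for im in imgs]
    if not arrs:
        raise PreprocessValidationError("empty image collection")
    arrs = [a[None] if a.ndim == 2 else a for a in arrs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise PreprocessValidationError("images have mismatched shapes")
    return np.stack(arrs)


def channel_means(imgs: list[np.ndarray]) -> np.ndarray:
    """Per-channel mean intensity over a collection (training split)."""
    x = _stack(imgs)
    return x.mean(axis=(0, 2, 3))


def apply_demean(imgs: list[np.ndarray], means: np.ndarray,
                 sds: np.ndarray | None = None) -> list[np.ndarray]:
    """Subtract precomputed per-channel means (and optionally divide by sds)."""
    out = []
    for im in imgs:
        a = _as_float_image(im)
        sq = a.ndim == 2
        if sq:
            a = a[None]
        a = a - means[:, None, None]
        if sds is not None:
            a = a / sds[:, None, None]
        out.append(a[0] if sq else a)
    return out


def standardize(imgs: list[np.ndarray],
                cfg: PreprocessConfig = PreprocessConfig()) -> list[np.ndarray]:
    """Demean each channel over the collection; optional unit-variance scaling.

    The guard ``sd < 1e-8 -> divide by 1`` keeps constant channels finite.
    """
    x = _stack(imgs)
    means = x.mean(axis=(0, 2, 3))
    sds = None
    if cfg.divide_by_sd:
        sds = x.std(axis=(0, 2, 3))
        sds = np.where(sds < 1e-8, 1.0, sds)
    if not cfg.demean:
        means = np.zeros_like(means)
    return apply_demean(list(imgs), means, sds)
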