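"""Synthetic lumbar-ROI phantom generator.

Real inputs for this classifier are 224 x 224 single-channel MRI crops of the
L4-L5 disc level, labelled per lesion as normal/mild (0) vs severe (1). The
phantom generator stands in for that data: each image is a textured dark
background (DICOM-like intensity range, 0-4095) carrying a bright ellipse —
an analog of the dural sac / central canal. Severity is encoded geometrically:
severe images get a smaller, flatter ellipse, mimicking canal narrowing. The
class imbalance of the five lesion categories is reproduced via per-condition
severe fractions.

No radiological realism is attempted; the phantoms exist so that every
downstream stage (preprocessing, augmentation, network, training harness) is
exercisable and separable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

__all__ = [
    "CONDITION_COUNTS",
    "CONDITION_SEVERE_FRACTIONS",
    "PhantomSpec",
    "LabeledImage",
    "generate_phantoms",
    "generate_condition_phantoms",
    "phantom_to_files",
    "load_phantom_files",
]

# (normal/mild, severe) counts per lesion category in the source collection
CONDITION_COUNTS: dict[str, tuple[int, int]] = {
    "spinal_stenosis": (1429, 203),
    "left_neural_foraminal_narrowing": (1517, 115),
    "right_neural_foraminal_narrowing": (1525, 107),
    "left_subarticular_stenosis": (1243, 389),
    "right_subarticular_stenosis": (1244, 388),
}

CONDITION_SEVERE_FRACTIONS: dict[str, float] = {
    k: s / (m + s) for k, (m, s) in CONDITION_COUNTS.items()
}


class PhantomValidationError(ValueError):
    """Raised when a PhantomSpec field violates its invariant."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a synthetic ROI dataset.

    Intensities are deliberately NOT 0-255 (default peak 4095, emulating a
    12-bit DICOM range) so that intensity normalization downstream does real
    work.
    """

    image_size: int = 224
    n_images: int = 400
    severe_fraction: float = 0.25
    canal_radius_mild: float = 28.0
    canal_radius_severe: float = 14.0
    canal_contrast: float = 1500.0
    background_level: float = 800.0
    background_texture_sd: float = 150.0
    jitter_sd: float = 4.0
    condition: str = "spinal_stenosis"
    seed: int = 0

    def validate(self) -> None:
        if self.n_images <= 0:
            raise PhantomValidationError("n_images must be > 0")
        if not 0.0 <= self.severe_fraction <= 1.0:
            raise PhantomValidationError("severe_fraction must be in [0, 1]")
        if not self.canal_radius_severe < self.canal_radius_mild:
            raise PhantomValidationError(
                "canal_radius_severe must be < canal_radius_mild")
        if self.image_size < 8:
            raise PhantomValidationError("image_size must be >= 8")
        if self.background_texture_sd < 0:
            raise PhantomValidationError("background_texture_sd must be >= 0")
        if self.jitter_sd < 0:
            raise PhantomValidationError("jitter_sd must be >= 0")
        if self.canal_contrast < 0:
            raise PhantomValidationError("canal_contrast must be >= 0")


@dataclass(frozen=True)
class LabeledImage:
    """A single-channel image with its binary severity label."""

    image: np.ndarray  # (H, W) uint16
    label: int         # 0 = normal/mild, 1 = severe
    condition: str = "spinal_stenosis"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise PhantomValidationError("label must be 0 or 1")


# intensity ceiling of the simulated 12-bit acquisition
_INTENSITY_MAX = 4095.0


def _render(spec: PhantomSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size
    img = spec.background_level + rng.normal(
        0.0, spec.background_texture_sd, size=(n, n))
    if label == 1:
        a = spec.canal_radius_severe
        b = 0.6 * spec.canal_radius_severe  # flattened: stenotic sac
    else:
        a = spec.canal_radius_mild
        b = 0.8 * spec.canal_radius_mild
    cy = n / 2.0 + rng.normal(0.0, spec.jitter_sd)
    cx = n / 2.0 + rng.normal(0.0, spec.jitter_sd)
    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    # soft-edged ellipse: ~contrast inside, ~0 outside, smooth boundary
    img = img + spec.canal_contrast / (1.0 + np.exp(8.0 * (rho - 1.0)))
    return np.clip(np.rint(img), 0, _INTENSITY_MAX).astype(np.uint16)


def generate_phantoms(spec: PhantomSpec) -> list[LabeledImage]:
    """Generate `spec.n_images` phantoms with exactly
    round(n_images * severe_fraction) severe labels, bit-reproducible by seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_severe = int(round(spec.n_images * spec.severe_fraction))
    labels = np.zeros(spec.n_images, dtype=np.int64)
    labels[:n_severe] = 1
    rng.shuffle(labels)
    return [
        LabeledImage(_render(spec, int(lab), rng), int(lab), spec.condition)
        for lab in labels
    ]


def generate_condition_phantoms(
    condition: str, n_images: int | None = None, seed: int = 0, **overrides
) -> list[LabeledImage]:
    """Generate a per-condition dataset with that condition's severe fraction.

    With ``n_images=None`` the condition's full count (1632) is used.
    """
    if condition not in CONDITION_SEVERE_FRACTIONS:
        raise PhantomValidationError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(CONDITION_SEVERE_FRACTIONS)}")
    mild, severe = CONDITION_COUNTS[condition]
    spec = PhantomSpec(
        n_images=n_images if n_images is not None else mild + severe,
        severe_fraction=CONDITION_SEVERE_FRACTIONS[condition],
        condition=condition,
        seed=seed,
    )
    if overrides:
        spec = replace(spec, **overrides)
    return generate_phantoms(spec)


def phantom_to_files(images: list[LabeledImage], directory: str | Path) -> Path:
    """Write one 16-bit grayscale PNG per image plus a CSV manifest.

    Returns the manifest path. Round-trip via :func:`load_phantom_files` is
    pixel-exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(images):
        fname = f"phantom_{i:05d}.png"
        PILImage.fromarray(item.image.astype(np.uint16)).save(directory / fname)
        rows.append({"filename": fname, "label": item.label,
                     "condition": item.condition})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=["filename", "label", "condition"]).to_csv(
        manifest, index=False)
    return manifest


def load_phantom_files(manifest: str | Path) -> list[LabeledImage]:
    """Read a manifest written by :func:`phantom_to_files`."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    out = []
    for _, row in df.iterrows():
        arr = np.asarray(PILImage.open(manifest.parent / row["filename"]))
        out.append(LabeledImage(arr.astype(np.uint16), int(row["label"]),
                                str(row["condition"])))
    return out
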