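"""Seeded synthetic texture cohorts for exercising the full pipeline.

The original micrograph database is not public, so test cohorts are
generated: groups of images that differ in variance and in
spatial-frequency content, which is exactly the structure the three
descriptors respond to. Plane waves give analytic single-frequency
textures; Gaussian random fields with a power-law spectrum
S(w) ~ |w|^-beta span white noise (beta = 0) through smooth, long-range
correlated textures (beta = 2), emulating the fine-to-coarse granularity
differences between pollen taxa without any photorealism.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .image_prep import GrayImage

__all__ = ["TextureSpec", "plane_wave", "gaussian_random_field", "make_cohort", "render_image"]


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic texture; (kind, parameters, seed) fully determine it."""

    kind: str = "gaussian_random_field"
    shape: tuple[int, int] = (256, 256)
    amplitude: float = 1.0
    frequency: float = 1 / 32  # cycles/pixel, plane_wave only
    theta: float | None = None  # wave direction (radians); None = seed-jittered
    spectral_exponent: float = 0.0  # power-spectrum slope, random field only
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("plane_wave", "gaussian_random_field"):
            raise ConfigurationError(f"unknown texture kind {self.kind!r}")
        if self.kind == "plane_wave" and not (0.0 < self.frequency <= 0.5):
            raise ConfigurationError(
                f"plane-wave frequency must be in (0, 0.5] cycles/pixel, got {self.frequency}"
            )
        if min(self.shape) < 3:
            raise ConfigurationError(f"shape must be at least 3x3, got {self.shape}")
        if self.amplitude <= 0:
            raise ConfigurationError(f"amplitude must be positive, got {self.amplitude}")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def plane_wave(spec: TextureSpec) -> GrayImage:
    """I(x, y) = A sin(2 pi f (x cos t + y sin t)), offset to be non-negative."""
    if spec.kind != "plane_wave":
        raise ConfigurationError(f"spec kind is {spec.kind!r}, expected 'plane_wave'")
    rows, cols = spec.shape
    theta = spec.theta
    if theta is None:
        theta = float(_rng(spec.seed).uniform(0, np.pi))
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    img = spec.amplitude * np.sin(2 * np.pi * spec.frequency * (x * np.cos(theta) + y * np.sin(theta)))
    if spec.noise_sd > 0:
        img = img + _rng(spec.seed + 1).normal(0.0, spec.noise_sd, size=img.shape)
    img -= img.min()
    return GrayImage(img, provenance="raw")


def gaussian_random_field(spec: TextureSpec) -> GrayImage:
    """Stationary Gaussian field with power spectrum ~ |w|^-spectral_exponent.

    White Gaussian noise is shaped in the Fourier domain by the
    amplitude filter |w|^(-beta/2) (so the *power* falls off as
    |w|^-beta), inverse-transformed, mean-removed, scaled to the
    requested standard deviation and offset to a non-negative range.
    beta = 0 reproduces white noise.
    """
    if spec.kind != "gaussian_random_field":
        raise ConfigurationError(
            f"spec kind is {spec.kind!r}, expected 'gaussian_random_field'"
        )
    rows, cols = spec.shape
    rng = _rng(spec.seed)
    white = rng.normal(size=(rows, cols))
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = np.inf  # kill DC: field is mean-free by construction
    filt = radius ** (-spec.spectral_exponent / 2.0)
    fld = np.fft.ifft2(np.fft.fft2(white) * filt).real
    fld -= fld.mean()
    sd = fld.std()
    if sd > 0:
        fld *= spec.amplitude / sd
    if spec.noise_sd > 0:
        fld = fld + rng.normal(0.0, spec.noise_sd, size=fld.shape)
    fld -= fld.min()
    return GrayImage(fld, provenance="raw")


def render_texture(spec: TextureSpec) -> GrayImage:
    """Dispatch on spec.kind."""
    if spec.kind == "plane_wave":
        return plane_wave(spec)
    return gaussian_random_field(spec)


def derive_seed(master_seed: int, label: str, index: int) -> int:
    """Stable per-image seed < 2^31 from (master seed, group label, index).

    Hash-based so adding or reordering groups never shifts the images of
    existing groups.
    """
    digest = hashlib.sha256(f"{master_seed}|{label}|{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def render_image(img: GrayImage, path: str | Path, bit_depth: str = "u8") -> None:
    """Write an image to disk: 8-bit PNG (min–max scaled) or float TIFF.

    The 8-bit path mimics the acquisition depth of camera micrographs;
    the float TIFF path preserves exact values for numerical tests.
    """
    path = Path(path)
    px = img.pixels
    if bit_depth == "u8":
        rng_ = px.max() - px.min()
        scaled = np.zeros_like(px) if rng_ == 0 else (px - px.min()) / rng_ * 255.0
        iio.imwrite(path, np.round(scaled).astype(np.uint8))
    elif bit_depth == "f32":
        iio.imwrite(path, px.astype(np.float32))
    else:
        raise ConfigurationError(f"unknown bit depth {bit_depth!r}")


def make_cohort(
    group_specs: list[tuple[str, TextureSpec, int]],
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    bit_depth: str = "u8",
) -> tuple[list[tuple[str, str, GrayImage]], pd.DataFrame]:
    """Generate n seeded images per group; optionally write them + a manifest.

    Returns (images, manifest) where images is a list of
    (image_id, group, GrayImage) and the manifest records
    (image_id, group, seed) — enough to regenerate any cohort exactly.
    """
    labels = [lab for lab, _, _ in group_specs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate group labels: {labels}")
    if any(n < 1 for _, _, n in group_specs):
        raise ConfigurationError("each group needs n >= 1 images")

    images: list[tuple[str, str, GrayImage]] = []
    rows = []
    for label, spec, n in group_specs:
        for i in range(n):
            seed = derive_seed(master_seed, label, i)
            img = render_texture(replace(spec, seed=seed))
            image_id = f"{label}_{i:03d}"
            images.append((image_id, label, img))
            rows.append({"image_id": image_id, "group": label, "seed": seed})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = "png" if bit_depth == "u8" else "tiff"
        for image_id, _, img in images:
            render_image(img, out_dir / f"{image_id}.{ext}", bit_depth)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, manifest
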