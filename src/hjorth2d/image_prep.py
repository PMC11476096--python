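"""Image loading, grayscale conversion, min–max normalization and smoothing.

These are the preparation stages run before derivative-based texture
descriptors are computed: an RGB micrograph is collapsed to a single
intensity plane, rescaled to [0, 1], and low-pass filtered so that the
finite-difference derivatives downstream are not dominated by pixel noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError, DimensionError, InputError

logger = logging.getLogger("hjorth2d")

#: BT.601 luma weights, the conventional RGB -> intensity projection.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Minimum image side: second-order central differences need 3 samples.
MIN_SIDE = 3

_BORDER_MODES = {"replicate": "nearest", "reflect": "reflect"}


@dataclass(frozen=True, eq=False)
class GrayImage:
    """A single-channel intensity field, the unit of analysis.

    ``pixels`` is a 2D float array in (row, col) order with row 0 at the
    top; the x axis of derivative operators runs along columns, y along
    rows. ``provenance`` tracks the preparation stage the image is at
    (``raw`` | ``normalized`` | ``filtered``).
    """

    pixels: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DimensionError(f"expected a 2D intensity field, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise DimensionError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise InputError("image contains non-finite pixel values")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SmoothingSpec:
    """Pre-derivative smoothing filter.

    kind:   'box' (all-equal coefficients) or 'gaussian' (discretized
            isotropic Gaussian, renormalized over the window).
    window: odd kernel side in pixels; 1 means identity.
    sigma:  Gaussian standard deviation in pixels (gaussian only).
    border: 'replicate' (nearest-edge, default — adds no spurious edge
            gradients) or 'reflect'.
    """

    kind: str = "box"
    window: int = 3
    sigma: float = 1.0
    border: str = "replicate"

    def __post_init__(self) -> None:
        if self.kind not in ("box", "gaussian"):
            raise ConfigurationError(f"unknown smoothing kind {self.kind!r}")
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError(f"window must be odd and >= 1, got {self.window}")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ConfigurationError(f"sigma must be positive, got {self.sigma}")
        if self.border not in _BORDER_MODES:
            raise ConfigurationError(f"unknown border mode {self.border!r}")

    def kernel(self) -> np.ndarray:
        """The unit-sum convolution kernel this spec describes."""
        w = self.window
        if self.kind == "box":
            return np.full((w, w), 1.0 / (w * w))
        half = w // 2
        ax = np.arange(-half, half + 1, dtype=float)
        g1 = np.exp(-0.5 * (ax / self.sigma) ** 2)
        k = np.outer(g1, g1)
        return k / k.sum()


def load_image(path: str | Path) -> GrayImage | tuple[GrayImage, GrayImage, GrayImage]:
    """Read a PNG/TIFF/JPEG raster from disk.

    Returns a :class:`GrayImage` for single-channel input, or the
    (R, G, B) planes for color input. Values are kept on the native
    integer scale converted to floats (8-bit in [0, 255]); an alpha
    channel is dropped with a logged warning.
    """
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise InputError(f"image file not found: {path}") from None
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise InputError(f"unreadable image file {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[-1] in (2, 4):
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[..., :-1]
        if arr.shape[-1] == 1:
            arr = arr[..., 0]

    if arr.ndim == 2:
        return GrayImage(arr.astype(float), provenance="raw")
    if arr.ndim == 3 and arr.shape[-1] == 3:
        planes = arr.astype(float)
        return tuple(GrayImage(planes[..., c], provenance="raw") for c in range(3))
    raise InputError(f"unsupported image layout {arr.shape} in {path}")


def to_grayscale(
    r: GrayImage | np.ndarray,
    g: GrayImage | np.ndarray,
    b: GrayImage | np.ndarray,
    weights: tuple[float, float, float] = BT601_WEIGHTS,
) -> GrayImage:
    """Weighted luma projection of three equal-shaped color planes."""
    rp, gp, bp = (p.pixels if isinstance(p, GrayImage) else np.asarray(p, float) for p in (r, g, b))
    if not (rp.shape == gp.shape == bp.shape):
        raise DimensionError(
            f"color planes differ in shape: {rp.shape}, {gp.shape}, {bp.shape}"
        )
    wr, wg, wb = weights
    return GrayImage(wr * rp + wg * gp + wb * bp, provenance="raw")


def load_gray(
    path: str | Path, weights: tuple[float, float, float] = BT601_WEIGHTS
) -> GrayImage:
    """Load an image and collapse color input to grayscale in one step."""
    loaded = load_image(path)
    if isinstance(loaded, GrayImage):
        return loaded
    return to_grayscale(*loaded, weights=weights)


def minmax_normalize(img: GrayImage) -> GrayImage:
    """Affine rescale of intensities so min = 0 and max = 1 exactly.

    A strictly monotone map: pixel ordering is preserved. A constant
    image has zero range and is rejected rather than returning NaNs.
    """
    px = img.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        raise DegenerateInputError(
            "constant image: min-max normalization undefined (max == min)"
        )
    return GrayImage((px - lo) / (hi - lo), provenance="normalized")


def smooth(img: GrayImage, spec: SmoothingSpec | None = None) -> GrayImage:
    """Linear convolution with the unit-sum kernel described by ``spec``.

    Constant regions are preserved exactly (the kernel sums to 1);
    borders are handled by replication or reflection per the spec.
    """
    spec = spec or SmoothingSpec()
    if spec.window > min(img.height, img.width):
        raise ConfigurationError(
            f"smoothing window {spec.window} exceeds image size {img.shape}"
        )
    if spec.window == 1:
        return replace(img, provenance="filtered")
    out = ndimage.convolve(img.pixels, spec.kernel(), mode=_BORDER_MODES[spec.border])
    return GrayImage(out, provenance="filtered")
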