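"""Non-directional derivative-magnitude fields.

The texture descriptors downstream use the *magnitudes* of the first and
second image derivatives,

    I'  = sqrt((dI/dx)^2 + (dI/dy)^2)
    I'' = sqrt((d2I/dx2)^2 + (d2I/dy2)^2)

i.e. combined pure-partial filters with no mixed term, because the
direction of local intensity change carries no information for these
descriptors. x runs along columns, y along rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .image_prep import GrayImage

SCHEMES = ("central", "sobel")


@dataclass(frozen=True, eq=False)
class DerivativeFields:
    """First (d1) and second (d2) derivative-magnitude fields of one image.

    Both fields have the shape of the source image; values are >= 0.
    """

    d1: np.ndarray
    d2: np.ndarray
    scheme: str = "central"


def _axis_index(axis: str) -> int:
    if axis == "x":
        return 1  # columns
    if axis == "y":
        return 0  # rows
    raise ConfigurationError(f"axis must be 'x' or 'y', got {axis!r}")


def partial_derivative(img: GrayImage | np.ndarray, axis: str, order: int) -> np.ndarray:
    """Pure partial derivative along one axis by finite differences.

    Order 1: central difference (f[i+1] - f[i-1]) / 2 in the interior,
    one-sided differences at the two border lines. Order 2: the standard
    second-difference stencil f[i+1] - 2 f[i] + f[i-1], with the nearest
    interior value replicated onto the border lines.
    """
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    ax = _axis_index(axis)
    if order == 1:
        return np.gradient(px, axis=ax)
    if order != 2:
        raise ConfigurationError(f"order must be 1 or 2, got {order}")
    d2 = np.empty_like(px)
    sl = [slice(None), slice(None)]

    def at(i):
        s = sl.copy()
        s[ax] = i
        return tuple(s)

    inner = np.diff(px, n=2, axis=ax)
    d2[at(slice(1, -1))] = inner
    d2[at(0)] = d2[at(1)]
    d2[at(-1)] = d2[at(-2)]
    return d2


def _sobel(px: np.ndarray, ax: int) -> np.ndarray:
    # ndimage.sobel has gain 8 relative to the unit-spacing derivative
    return ndimage.sobel(px, axis=ax, mode="nearest") / 8.0


def first_derivative_magnitude(img: GrayImage | np.ndarray, scheme: str = "central") -> np.ndarray:
    """sqrt((dI/dx)^2 + (dI/dy)^2), pixel-wise."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    if scheme == "central":
        gx = partial_derivative(px, "x", 1)
        gy = partial_derivative(px, "y", 1)
    elif scheme == "sobel":
        gx, gy = _sobel(px, 1), _sobel(px, 0)
    else:
        raise ConfigurationError(f"unknown derivative scheme {scheme!r}")
    return np.hypot(gx, gy)


def second_derivative_magnitude(img: GrayImage | np.ndarray, scheme: str = "central") -> np.ndarray:
    """sqrt((d2I/dx2)^2 + (d2I/dy2)^2), pixel-wise; no mixed partials."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    if scheme == "central":
        sxx = partial_derivative(px, "x", 2)
        syy = partial_derivative(px, "y", 2)
    elif scheme == "sobel":
        sxx = _sobel(_sobel(px, 1), 1)
        syy = _sobel(_sobel(px, 0), 0)
    else:
        raise ConfigurationError(f"unknown derivative scheme {scheme!r}")
    return np.hypot(sxx, syy)


def derivative_fields(img: GrayImage, scheme: str = "central") -> DerivativeFields:
    """Both magnitude fields of one image, same shape as the source."""
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown derivative scheme {scheme!r}")
    return DerivativeFields(
        d1=first_derivative_magnitude(img, scheme),
        d2=second_derivative_magnitude(img, scheme),
        scheme=scheme,
    )


def crop_border(field: np.ndarray, n: int) -> np.ndarray:
    """Drop an n-pixel frame; used for border-sensitivity checks."""
    if n < 0:
        raise ConfigurationError(f"crop_border must be >= 0, got {n}")
    if n == 0:
        return field
    if 2 * n >= min(field.shape):
        raise ConfigurationError(
            f"crop_border {n} leaves no interior for shape {field.shape}"
        )
    return field[n:-n, n:-n]
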