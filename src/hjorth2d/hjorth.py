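"""The three Hjorth descriptors of a 2D intensity field.

Hjorth's parameters, introduced for EEG traces, summarize a signal by
variance ratios of its derivatives:

    Activity   = var(I)                 (signal power)
    Mobility   = std(I') / std(I)       (dominant-frequency proxy)
    Complexity = (std(I'')/std(I')) / (std(I')/std(I))   (bandwidth proxy)

Here I is an image and I', I'' are the non-directional derivative
magnitudes of :mod:`hjorth2d.differential`. All variances are population
(1/N) moments over every retained pixel; Mobility and Complexity are
ratios, so the 1/N-vs-1/(N-1) choice only affects Activity's absolute
value. Activity also equals the total spectral power of the mean-removed
image (Parseval), exposed as :func:`spectral_total_power` as a numerical
cross-check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .differential import crop_border, derivative_fields
from .errors import DegenerateInputError
from .image_prep import BT601_WEIGHTS, GrayImage, SmoothingSpec, minmax_normalize, smooth, to_grayscale

__all__ = [
    "PipelineConfig",
    "HjorthDescriptors",
    "activity",
    "mobility",
    "complexity",
    "descriptors",
    "spectral_total_power",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that parametrizes descriptor extraction for one image.

    compute_on: 'filtered' computes descriptors on the normalized and
    smoothed image (the default processing order); 'unfiltered' skips the
    smoothing stage. ddof is the variance denominator offset (0 =
    population moments, the default).
    """

    grayscale_weights: tuple[float, float, float] = BT601_WEIGHTS
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    scheme: str = "central"
    crop_border: int = 0
    compute_on: str = "filtered"
    normalize: bool = True
    ddof: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grayscale_weights"] = list(self.grayscale_weights)
        return d


@dataclass(frozen=True)
class HjorthDescriptors:
    """The (Activity, Mobility, Complexity) triple for one image."""

    activity: float
    mobility: float
    complexity: float
    image_id: str = ""
    group: str | None = None
    config: dict | None = None


def _std(values: np.ndarray, ddof: int = 0) -> float:
    return float(np.std(values, ddof=ddof))


def activity(img: GrayImage | np.ndarray, crop: int = 0, ddof: int = 0) -> float:
    """Population variance of pixel intensities."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    return float(np.var(crop_border(px, crop), ddof=ddof))


def mobility(
    img: GrayImage | np.ndarray, d1: np.ndarray, crop: int = 0, ddof: int = 0
) -> float:
    """std(I') / std(I); undefined (error) for a constant image."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    s_i = _std(crop_border(px, crop), ddof)
    if s_i == 0.0:
        raise DegenerateInputError("mobility undefined: image has zero variance")
    return _std(crop_border(np.asarray(d1, float), crop), ddof) / s_i


def complexity(
    d1: np.ndarray,
    d2: np.ndarray,
    img: GrayImage | np.ndarray,
    crop: int = 0,
    ddof: int = 0,
) -> float:
    """(std(I'')/std(I')) / (std(I')/std(I)).

    Requires both the image and its first-derivative magnitude to have
    nonzero spread.
    """
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    s_i = _std(crop_border(px, crop), ddof)
    s_d1 = _std(crop_border(np.asarray(d1, float), crop), ddof)
    if s_i == 0.0:
        raise DegenerateInputError("complexity undefined: image has zero variance")
    if s_d1 == 0.0:
        raise DegenerateInputError(
            "complexity undefined: first-derivative magnitude has zero variance"
        )
    s_d2 = _std(crop_border(np.asarray(d2, float), crop), ddof)
    return (s_d2 / s_d1) / (s_d1 / s_i)


def descriptors(
    img: GrayImage | tuple[GrayImage, GrayImage, GrayImage],
    config: PipelineConfig | None = None,
    image_id: str = "",
    group: str | None = None,
) -> HjorthDescriptors:
    """Full per-image pipeline: grayscale -> normalize -> smooth -> descriptors.

    Stage failures are re-raised with the stage name attached. The
    resolved config is recorded in the result for provenance.
    """
    cfg = config or PipelineConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            exc.args = (f"[{name}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
            raise

    if isinstance(img, tuple):
        img = stage("grayscale", to_grayscale, *img, weights=cfg.grayscale_weights)
    if cfg.normalize:
        img = stage("normalize", minmax_normalize, img)
    if cfg.compute_on == "filtered":
        img = stage("smooth", smooth, img, cfg.smoothing)
    fields = stage("derivatives", derivative_fields, img, cfg.scheme)
    act = stage("activity", activity, img, cfg.crop_border, cfg.ddof)
    mob = stage("mobility", mobility, img, fields.d1, cfg.crop_border, cfg.ddof)
    cpx = stage("complexity", complexity, fields.d1, fields.d2, img, cfg.crop_border, cfg.ddof)
    return HjorthDescriptors(
        activity=act,
        mobility=mob,
        complexity=cpx,
        image_id=image_id,
        group=group,
        config=cfg.to_dict(),
    )


def spectral_total_power(img: GrayImage | np.ndarray) -> float:
    """Total power of the mean-removed image from its 2D DFT.

    Normalized so that, by Parseval's theorem, the result equals the
    population variance of the pixel intensities: sum |F|^2 / N^2 with
    N the pixel count and F the DFT of I - mean(I).
    """
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    n = px.size
    f = np.fft.fft2(px - px.mean())
    return float(np.sum(np.abs(f) ** 2) / (n * n))
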