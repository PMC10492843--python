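"""Pre-processing chain for polarized laparoscopy frames.

Per-frame processing runs on the L channel of Lab space only (a and b
are untouched): Gaussian denoising (sigma 0.5 px), homomorphic
illumination correction (log-transform, subtract a sigma-15 Gaussian
low-pass, exponentiate), and 1%/1% percentile contrast saturation.
Specular glare is excluded with a percentile rule on the frame pair: a
pixel bright in the co-polarized frame (above its 99.5th luminance
percentile) and dark in the cross-polarized frame (below its 0.5th
percentile) is a glare candidate; candidate regions are delimited with
Canny edges, filled, dilated and removed from all downstream statistics.

The Lab conversion uses sRGB primaries with a D65 white point applied to
*linear* intensities (no gamma decoding — the frames are linear camera
counts, not display-encoded images).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import color, feature, morphology

from .mpel import (
    DerivedImages,
    MpelCoefficients,
    PolarizedFramePair,
    apply_mpel,
    compute_pel,
    compute_wll,
    published_coefficients,
)

__all__ = ["PipelineConfig", "ProcessedImage", "preprocess", "glare_mask", "run_frame"]

# linear sRGB -> XYZ (D65)
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ2RGB = np.linalg.inv(_RGB2XYZ)


@dataclass
class PipelineConfig:
    """Tunable constants of the pre-processing chain (pixel units)."""

    denoise_sigma: float = 0.5
    homomorphic_sigma: float = 15.0
    saturation_low: float = 1.0  # percent
    saturation_high: float = 1.0  # percent
    glare_co_percentile: float = 99.5
    glare_cross_percentile: float = 0.5
    glare_dilation_radius: int = 2
    # recorded processing order; tests assert the chain matches
    order: tuple = ("rgb2lab", "denoise", "homomorphic", "saturate", "lab2rgb")

    def __post_init__(self) -> None:
        if self.denoise_sigma <= 0 or self.homomorphic_sigma <= 0:
            raise ValueError("filter sigmas must be > 0")
        for p in (
            self.saturation_low, self.saturation_high,
            self.glare_co_percentile, self.glare_cross_percentile,
        ):
            if not 0.0 < p < 100.0:
                raise ValueError("percentiles must lie in (0, 100)")


@dataclass
class ProcessedImage:
    """An RGB frame after Lab-domain processing."""

    rgb: np.ndarray
    excluded_mask: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))


def _linear_rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    xyz = rgb @ _RGB2XYZ.T
    return color.xyz2lab(xyz)


def _lab_to_linear_rgb(lab: np.ndarray) -> np.ndarray:
    xyz = color.lab2xyz(lab)
    return xyz @ _XYZ2RGB.T


def _homomorphic(L: np.ndarray, sigma: float) -> np.ndarray:
    """Remove the low-frequency multiplicative illumination field from L.

    Works in the log domain; an epsilon of 1e-6 of the maximum guards
    zeros.  The global log-mean is restored so overall brightness is
    preserved and a flat field passes through unchanged.
    """
    eps = 1e-6 * max(float(np.nanmax(L)), 1e-30)
    logL = np.log(L + eps)
    lowpass = ndimage.gaussian_filter(logL, sigma, mode="reflect")
    out = logL - lowpass + logL.mean()
    return np.exp(out) - eps


def preprocess(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    exclude: np.ndarray | None = None,
) -> ProcessedImage:
    """Run the per-frame chain on one RGB raster (linear intensities).

    ``exclude`` marks pixels (specular glare) that must not influence
    the global steps: they are median-filled before the illumination
    estimate and ignored by the saturation percentiles, so a bright
    glare blob cannot shift the processed statistics of the rest of the
    frame.
    """
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB raster")
    lab = _linear_rgb_to_lab(image)
    L = lab[..., 0]
    valid = np.ones(L.shape, dtype=bool) if exclude is None else ~np.asarray(exclude, bool)
    if not valid.all():
        # normalized-convolution inpainting at the illumination scale, so
        # the low-pass estimate sees a locally plausible value
        num = ndimage.gaussian_filter(np.where(valid, L, 0.0), config.homomorphic_sigma)
        den = ndimage.gaussian_filter(valid.astype(float), config.homomorphic_sigma)
        L = np.where(valid, L, num / np.maximum(den, 1e-12))
    L = ndimage.gaussian_filter(L, config.denoise_sigma, mode="reflect")
    L = _homomorphic(L, config.homomorphic_sigma)
    # contrast adjustment: saturate (clip) the bottom/top percentiles
    lo, hi = np.percentile(
        L[valid], [config.saturation_low, 100.0 - config.saturation_high]
    )
    if hi > lo:
        L = np.clip(L, lo, hi)
    lab_out = lab.copy()
    lab_out[..., 0] = np.clip(L, 0.0, 100.0)
    return ProcessedImage(rgb=_lab_to_linear_rgb(lab_out))


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return rgb.sum(axis=2)


def glare_mask(pair: PolarizedFramePair, config: PipelineConfig | None = None) -> np.ndarray:
    """Boolean raster of specular-glare pixels to exclude.

    Invariant to global linear rescaling of both frames (thresholds are
    percentiles of each frame's own luminance histogram).
    """
    if config is None:
        config = PipelineConfig()
    lum_co = _luminance(pair.co)
    lum_cross = _luminance(pair.cross)
    co_thr = np.percentile(lum_co, config.glare_co_percentile)
    cross_thr = np.percentile(lum_cross, config.glare_cross_percentile)
    candidates = (lum_co >= co_thr) & (lum_cross <= cross_thr)
    if not candidates.any():
        return np.zeros_like(candidates)
    edges = feature.canny(candidates.astype(float), sigma=1.0)
    mask = ndimage.binary_fill_holes(candidates | edges)
    if config.glare_dilation_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(config.glare_dilation_radius))
    return mask


def run_frame(
    pair: PolarizedFramePair,
    config: PipelineConfig | None = None,
    coefficients: MpelCoefficients | None = None,
    do_preprocess: bool = True,
) -> DerivedImages:
    """Full per-frame analysis: preprocess, glare-exclude, derive WLL/PEL/mPEL.

    Co and cross frames are preprocessed independently, the glare mask
    is taken on the *raw* pair (the percentile rule describes acquisition
    glare, not processed intensities), and the derived images carry the
    combined exclusion mask.  Deterministic: no randomness anywhere.
    """
    if config is None:
        config = PipelineConfig()
    if coefficients is None:
        coefficients = published_coefficients()
    excluded = glare_mask(pair, config) | ~pair.valid_mask
    if do_preprocess:
        co = preprocess(pair.co, config, exclude=excluded).rgb
        cross = preprocess(pair.cross, config, exclude=excluded).rgb
    else:
        co, cross = pair.co, pair.cross
    proc_pair = PolarizedFramePair(
        np.clip(co, 0.0, None), np.clip(cross, 0.0, None),
        valid_mask=~excluded, bit_depth=pair.bit_depth,
    )
    wll = compute_wll(proc_pair)
    pel = compute_pel(proc_pair)
    mpel = apply_mpel(proc_pair.co - proc_pair.cross, coefficients, saturate=False)
    for img in (wll, pel, mpel):
        img[excluded] = np.nan
    from .mpel import saturate_percentiles

    mpel = saturate_percentiles(mpel, config.saturation_low, config.saturation_high)
    return DerivedImages(
        wll=wll, pel=pel, mpel=mpel, valid_mask=~excluded,
        coefficients=coefficients, config=asdict(config),
    )
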