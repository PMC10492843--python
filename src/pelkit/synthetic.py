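"""Synthetic test data: polarized phantom frame pairs and SHG-like fiber images.

The phantom generator emulates the acquisition conditions of polarized
laparoscopy on a flat tissue field: per-pixel co/cross RGB values come
from a simulated reflectance lookup table (so lesion/background optics
are physically grounded in the Monte Carlo), a uniform depolarized
"deep tissue" term is added equally to both frames, a smooth radial
vignette multiplies both frames, specular glare ellipses saturate the
co frame and darken the cross frame, and signal-dependent Poisson noise
plus Gaussian read noise is applied on the 12-bit digital-number scale.

Fiber images are anti-aliased line segments with von Mises-distributed
axial orientations of known concentration, so the true directional
variance of each image is available analytically from the sampled angles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .mpel import PolarizedFramePair

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "FiberSpec",
    "load_packaged_lut",
    "render_phantom",
    "render_fibers",
    "make_fixture_suite",
]

FULL_SCALE_DN = 4095.0  # 12-bit
FULL_WELL_ELECTRONS = 10_000.0
READ_NOISE_DN = 2.0


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates."""

    cy: float
    cx: float
    ry: float
    rx: float

    def mask(self, shape) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return ((yy - self.cy) / self.ry) ** 2 + ((xx - self.cx) / self.rx) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """Everything needed to render one deterministic phantom frame pair."""

    shape: tuple = (96, 96)
    musp_ref: float = 25.0
    bvf: float = 0.004
    background_sigma_um2: float = 6.0  # large scatterers: low scattering power
    lesion_sigma_um2: float = 1.0  # small scatterers: high scattering power
    lesions: tuple = (Ellipse(48.0, 48.0, 16.0, 20.0),)
    glare: tuple = ()
    deep_fraction: float = 0.6  # depolarized deep signal, fraction of background co level
    vignette_ratio: float = 1.0  # center/edge illumination ratio (1 = flat)
    noise: bool = False
    misregistration_px: tuple = (0.0, 0.0)
    seed: int = 0


def load_packaged_lut():
    """The small pre-built lookup table shipped with the package.

    Produced by ``scripts/build_packaged_lut.py`` with the package's own
    Monte Carlo (seeds recorded per row); kept small so phantom fixtures
    build in milliseconds.
    """
    from .mc import ReflectanceLookupTable

    ref = resources.files("pelkit.data") / "lookup_table_small.csv"
    with resources.as_file(ref) as path:
        return ReflectanceLookupTable.from_csv(path)


def _lut_rgb(lut, musp: float, sigma: float, bvf: float):
    """(co_rgb, cross_rgb, b) at a grid point, interpolating over sigma.

    musp and bvf must match packaged grid values exactly; sigma may lie
    between grid values (linear interpolation).  Raises outside the hull.
    """
    pts = lut.points
    sel = pts[(np.isclose(pts.musp_ref, musp)) & (np.isclose(pts.bvf, bvf))]
    if sel.empty:
        raise ValueError(
            f"lookup table has no musp={musp}, bvf={bvf} "
            f"(available: musp {sorted(pts.musp_ref.unique())}, bvf {sorted(pts.bvf.unique())})"
        )
    sel = sel.sort_values("sigma_um2")
    sig = sel.sigma_um2.to_numpy()
    if not sig[0] <= sigma <= sig[-1]:
        raise ValueError(f"sigma={sigma} outside lookup table hull [{sig[0]}, {sig[-1]}]")

    def interp(col):
        return float(np.interp(sigma, sig, sel[col].to_numpy()))

    co = np.array([interp("co_r"), interp("co_g"), interp("co_b")])
    cross = np.array([interp("cross_r"), interp("cross_g"), interp("cross_b")])
    return co, cross, interp("b")


def render_phantom(spec: PhantomSpec, lut=None):
    """Render one phantom pair plus ground truth.

    Returns (pair, truth) where truth is a dict with the per-pixel
    scattering-power map ``b_map``, ``lesion_mask`` and ``glare_mask``.
    Deterministic for a fixed spec (noise realization set by spec.seed).
    """
    if lut is None:
        lut = load_packaged_lut()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    co_bg, cross_bg, b_bg = _lut_rgb(lut, spec.musp_ref, spec.background_sigma_um2, spec.bvf)
    co_le, cross_le, b_le = _lut_rgb(lut, spec.musp_ref, spec.lesion_sigma_um2, spec.bvf)

    co = np.tile(co_bg, (h, w, 1)).astype(float)
    cross = np.tile(cross_bg, (h, w, 1)).astype(float)
    b_map = np.full((h, w), b_bg)
    lesion_mask = np.zeros((h, w), dtype=bool)
    for ell in spec.lesions:
        m = ell.mask((h, w))
        lesion_mask |= m
        co[m] = co_le
        cross[m] = cross_le
        b_map[m] = b_le

    # depolarized deep-tissue term: equal in co and cross, cancels in PEL
    deep = spec.deep_fraction * co_bg.mean()
    co += deep
    cross += deep

    # digital gain so the brightest channel sits near 70% of full scale
    gain = 0.7 * FULL_SCALE_DN / co.max()
    co *= gain
    cross *= gain

    if spec.vignette_ratio != 1.0:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        vignette = 1.0 / (1.0 + (spec.vignette_ratio - 1.0) * np.clip(r2, 0, 1))
        co *= vignette[..., None]
        cross *= vignette[..., None]

    glare_mask = np.zeros((h, w), dtype=bool)
    for ell in spec.glare:
        m = ell.mask((h, w))
        glare_mask |= m
        co[m] = 0.98 * FULL_SCALE_DN
        cross[m] = np.minimum(cross[m], 0.002 * FULL_SCALE_DN)

    if any(spec.misregistration_px):
        cross = ndimage.shift(cross, (*spec.misregistration_px, 0.0), order=1, mode="nearest")

    if spec.noise:
        e_per_dn = FULL_WELL_ELECTRONS / FULL_SCALE_DN
        co = rng.poisson(np.clip(co, 0, None) * e_per_dn) / e_per_dn
        cross = rng.poisson(np.clip(cross, 0, None) * e_per_dn) / e_per_dn
        co = co + rng.normal(0.0, READ_NOISE_DN, co.shape)
        cross = cross + rng.normal(0.0, READ_NOISE_DN, cross.shape)

    co = np.clip(co, 0.0, FULL_SCALE_DN)
    cross = np.clip(cross, 0.0, FULL_SCALE_DN)
    pair = PolarizedFramePair(co, cross, bit_depth=12)
    truth = {"b_map": b_map, "lesion_mask": lesion_mask, "glare_mask": glare_mask,
             "b_background": b_bg, "b_lesion": b_le}
    return pair, truth


@dataclass
class FiberSpec:
    """Synthetic SHG-like fiber field with von Mises axial orientations."""

    shape: tuple = (256, 256)
    n_fibers: int = 200
    mean_orientation: float = 0.0  # radians
    kappa: float = 2.0  # von Mises concentration of the doubled angles
    length_px: tuple = (40.0, 80.0)
    width_px: float = 1.5
    fiber_intensity: float = 200.0
    background_noise: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")


def render_fibers(spec: FiberSpec):
    """Draw the fiber image; returns (image, true_directional_variance).

    Axial angles are sampled by drawing doubled angles from a von Mises
    distribution centred at twice the mean orientation; the ground truth
    is the circular variance of the *sampled* doubled angles (what a
    perfect orientation estimator would measure on this realization).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    image = np.zeros((h, w))
    if spec.kappa > 1e5:
        doubled = np.full(spec.n_fibers, 2.0 * spec.mean_orientation)
    elif spec.kappa == 0:
        doubled = rng.uniform(0.0, 2.0 * np.pi, spec.n_fibers)
    else:
        doubled = rng.vonmises(2.0 * spec.mean_orientation, spec.kappa, spec.n_fibers)
    theta = np.mod(doubled / 2.0, np.pi)
    true_var = float(1.0 - np.abs(np.exp(1j * doubled).mean()))

    lengths = rng.uniform(*spec.length_px, spec.n_fibers)
    cy = rng.uniform(0, h, spec.n_fibers)
    cx = rng.uniform(0, w, spec.n_fibers)
    yy, xx = np.mgrid[0:h, 0:w]
    for t, L, y0, x0 in zip(theta, lengths, cy, cx):
        dy, dx = np.sin(t), np.cos(t)
        # distance from pixel to the finite segment through (y0, x0)
        py, px = yy - y0, xx - x0
        along = py * dy + px * dx
        along_c = np.clip(along, -L / 2, L / 2)
        dist2 = (py - along_c * dy) ** 2 + (px - along_c * dx) ** 2
        image += spec.fiber_intensity * np.exp(-0.5 * dist2 / spec.width_px**2)
    image = np.clip(image, 0.0, spec.fiber_intensity * 1.5)
    if spec.background_noise > 0:
        image = image + rng.normal(0.0, spec.background_noise, image.shape)
        image = np.clip(image, 0.0, None)
    return image, true_var


def make_fixture_suite(outdir, seed: int = 0) -> dict:
    """Write the canonical synthetic test set to ``outdir``.

    Three phantoms (benign-like, malignant-like, glare-heavy), three
    fiber images (kappa 0.5/2/8), plus a JSON manifest with ground truth.
    Byte-reproducible for a fixed seed.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lut = load_packaged_lut()
    manifest: dict = {"seed": seed, "phantoms": {}, "fibers": {}}

    phantoms = {
        "benign_like": PhantomSpec(lesion_sigma_um2=4.0, noise=True, seed=seed + 1),
        "malignant_like": PhantomSpec(lesion_sigma_um2=1.0, noise=True, seed=seed + 2),
        "glare_heavy": PhantomSpec(
            lesion_sigma_um2=1.0, noise=True, seed=seed + 3,
            glare=(Ellipse(24.0, 70.0, 8.0, 10.0), Ellipse(72.0, 20.0, 6.0, 6.0)),
        ),
    }
    for name, spec in phantoms.items():
        pair, truth = render_phantom(spec, lut)
        tifffile.imwrite(outdir / f"{name}_co.tif", pair.co.astype(np.float32))
        tifffile.imwrite(outdir / f"{name}_cross.tif", pair.cross.astype(np.float32))
        tifffile.imwrite(outdir / f"{name}_lesion_mask.tif", truth["lesion_mask"].astype(np.uint8) * 255)
        manifest["phantoms"][name] = {
            "spec": {k: v for k, v in asdict(spec).items() if not isinstance(v, tuple)},
            "b_background": truth["b_background"],
            "b_lesion": truth["b_lesion"],
            "files": [f"{name}_co.tif", f"{name}_cross.tif", f"{name}_lesion_mask.tif"],
        }

    for kappa in (0.5, 2.0, 8.0):
        spec = FiberSpec(kappa=kappa, seed=seed + int(10 * kappa))
        image, true_var = render_fibers(spec)
        name = f"fibers_kappa_{kappa:g}"
        tifffile.imwrite(outdir / f"{name}.tif", image.astype(np.float32))
        manifest["fibers"][name] = {
            "kappa": kappa, "true_directional_variance": true_var,
            "files": [f"{name}.tif"],
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
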