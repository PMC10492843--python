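"""Wavelength-resolved tissue optical properties and the simulation grid.

A single-layer soft-tissue model: absorption from whole blood (hemoglobin
at 15 g/dL diluted by a blood volume fraction), scattering from a
monodisperse Mie sphere suspension whose cross-section spectrum sets the
scattering power b.  The simulation parameter grid spans the reduced
scattering coefficients, scattering cross sections and blood volume
fractions typical of peritoneal soft tissue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import numpy as np

from .mie import (
    MieError,
    ScatteringSpectrum,
    SphereScatterer,
    fit_scattering_power,
    mie_cross_sections,
    radius_from_cross_section,
)

__all__ = [
    "BloodModel",
    "TissueOpticalProperties",
    "ParameterGrid",
    "load_extinction_table",
    "absorption_coefficient",
    "mus_from_musp",
    "optical_depth",
    "thickness_for_depth",
    "build_parameter_grid",
    "default_wavelengths",
    "HEMOGLOBIN_MOLAR_MASS",
    "HEMOGLOBIN_G_PER_DL",
    "REFERENCE_WAVELENGTH_NM",
    "TISSUE_ANISOTROPY",
]

HEMOGLOBIN_MOLAR_MASS = 64500.0  # g/mol
HEMOGLOBIN_G_PER_DL = 15.0  # whole-blood hemoglobin concentration
REFERENCE_WAVELENGTH_NM = 550.0  # mid-band anchor for sigma_s and mu_s' grids
TISSUE_ANISOTROPY = 0.9  # transport anisotropy g of soft tissue


def default_wavelengths(step: float = 5.0) -> np.ndarray:
    """The 350-750 nm wavelength grid (inclusive)."""
    return np.arange(350.0, 750.0 + step / 2, step)


def load_extinction_table() -> dict[str, np.ndarray]:
    """Load the packaged hemoglobin molar extinction table.

    The table is a synthetic parametric reconstruction of the standard
    oxy/deoxy hemoglobin spectra (see ``scripts/build_hemoglobin_table.py``);
    columns: wavelength_nm, eps_oxy, eps_deoxy in cm^-1/(mol/L).
    """
    ref = resources.files("pelkit.data") / "hemoglobin_extinction_synthetic.csv"
    with ref.open() as fh:
        rows = list(csv.DictReader(fh))
    return {
        "wavelength_nm": np.array([float(r["wavelength_nm"]) for r in rows]),
        "eps_oxy": np.array([float(r["eps_oxy"]) for r in rows]),
        "eps_deoxy": np.array([float(r["eps_deoxy"]) for r in rows]),
    }


@dataclass
class BloodModel:
    """Blood absorption model: hemoglobin diluted by a volume fraction.

    ``oxygen_saturation`` mixes the oxy and deoxy extinction spectra;
    the default (1.0, fully oxygenated) is a modelling choice — only the
    oxygenated curve shape matters for the qualitative band structure.
    """

    blood_volume_fraction: float
    hemoglobin_g_per_dl: float = HEMOGLOBIN_G_PER_DL
    oxygen_saturation: float = 1.0
    extinction_table: dict[str, np.ndarray] = field(default_factory=load_extinction_table)

    def __post_init__(self) -> None:
        if not 0.0 <= self.blood_volume_fraction <= 1.0:
            raise ValueError("blood_volume_fraction must be in [0, 1]")
        if not 0.0 <= self.oxygen_saturation <= 1.0:
            raise ValueError("oxygen_saturation must be in [0, 1]")

    @property
    def molar_concentration(self) -> float:
        """Hemoglobin concentration in blood, mol/L."""
        return self.hemoglobin_g_per_dl * 10.0 / HEMOGLOBIN_MOLAR_MASS

    def extinction(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """Saturation-weighted molar extinction, linearly interpolated."""
        lam = np.asarray(wavelength_nm, dtype=float)
        tab = self.extinction_table
        lo, hi = tab["wavelength_nm"][0], tab["wavelength_nm"][-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(f"wavelength outside extinction table range [{lo}, {hi}] nm")
        eps = (
            self.oxygen_saturation * tab["eps_oxy"]
            + (1.0 - self.oxygen_saturation) * tab["eps_deoxy"]
        )
        return np.interp(lam, tab["wavelength_nm"], eps)


def absorption_coefficient(wavelength_nm, blood: BloodModel) -> np.ndarray:
    """Tissue absorption mu_a in cm^-1.

    mu_a = bvf * ln(10) * eps_Hb(lambda) * C_molar, with C_molar the
    molar hemoglobin concentration of whole blood (15 g/dL / 64500 g/mol).
    """
    eps = blood.extinction(wavelength_nm)
    return blood.blood_volume_fraction * np.log(10.0) * eps * blood.molar_concentration


def mus_from_musp(musp: float | np.ndarray, g: float = TISSUE_ANISOTROPY):
    """mu_s = mu_s' / (1 - g); requires g < 1."""
    if g >= 1.0:
        raise ValueError(f"anisotropy g must be < 1, got {g}")
    return np.asarray(musp) / (1.0 - g) if np.ndim(musp) else musp / (1.0 - g)


def optical_depth(mua: float, mus: float, thickness_cm: float) -> float:
    """tau = (mu_a + mu_s) * D, the dimensionless slab optical depth."""
    return (mua + mus) * thickness_cm


def thickness_for_depth(tau: float, mut: float) -> float:
    """Geometric thickness D (cm) giving optical depth tau at mu_t = mu_a + mu_s."""
    return tau / mut


@dataclass
class TissueOpticalProperties:
    """Full wavelength-resolved optical properties of one tissue condition."""

    wavelengths: np.ndarray  # nm
    mua: np.ndarray  # cm^-1
    mus: np.ndarray  # cm^-1
    musp: np.ndarray  # cm^-1
    g_transport: float
    n_medium: float
    scatterer: SphereScatterer
    b: float

    def at_wavelength(self, lam: float) -> tuple[float, float]:
        """(mu_a, mu_s) at one wavelength by linear interpolation."""
        return (
            float(np.interp(lam, self.wavelengths, self.mua)),
            float(np.interp(lam, self.wavelengths, self.mus)),
        )


def make_tissue(
    musp_ref: float,
    sigma_um2: float,
    bvf: float,
    wavelengths: np.ndarray | None = None,
    n_particle: float = 1.42,
    n_medium: float = 1.35,
    oxygen_saturation: float = 1.0,
) -> TissueOpticalProperties:
    """Tissue properties for one (mu_s'@550, sigma_s@550, bvf) grid point.

    The sphere radius is solved from the target scattering cross section
    at the 550 nm reference.  The suspension is Mie-consistent: with
    number density rho, mu_s(lambda) = rho sigma_sca(lambda) and
    mu_s'(lambda) = mu_s(lambda) (1 - g_Mie(lambda)), and rho is set so
    mu_s'(550) equals the requested grid value.  Matching the *reduced*
    coefficient (rather than mu_s itself) keeps the total white-light
    reflectance nearly invariant across sphere sizes at fixed mu_s'
    (similarity principle), so scattering-power contrast shows up in the
    polarized channels, not the unpolarized sum.  ``g_transport`` is
    recorded as the sphere's Mie anisotropy at the reference wavelength.
    """
    if wavelengths is None:
        wavelengths = default_wavelengths()
    radius = radius_from_cross_section(sigma_um2, REFERENCE_WAVELENGTH_NM, n_particle, n_medium)
    scatterer = SphereScatterer(radius, n_particle, n_medium)
    mie = np.array([mie_cross_sections(scatterer, lam)[:3] for lam in wavelengths])
    sigma_lam, g_lam = mie[:, 0], mie[:, 2]
    sigma_ref, _, g_ref = mie_cross_sections(scatterer, REFERENCE_WAVELENGTH_NM)
    g_transport = g_ref
    rho = musp_ref / (sigma_ref * (1.0 - g_ref))  # per (um^2 cm)
    mus = rho * sigma_lam
    musp = mus * (1.0 - g_lam)
    blood = BloodModel(bvf, oxygen_saturation=oxygen_saturation)
    mua = absorption_coefficient(wavelengths, blood)
    # the scattering-power label b follows the fixed-anisotropy reduced
    # scattering convention, i.e. the shape of the cross-section spectrum;
    # the wavelength-dependent Mie g would otherwise flatten the exponent
    # and compress the contrast the grid is meant to exercise
    power = fit_scattering_power(ScatteringSpectrum(wavelengths, sigma_lam))
    return TissueOpticalProperties(
        wavelengths=np.asarray(wavelengths, dtype=float),
        mua=mua,
        mus=mus,
        musp=musp,
        g_transport=g_transport,
        n_medium=n_medium,
        scatterer=scatterer,
        b=power.b,
    )


@dataclass
class ParameterGrid:
    """The Cartesian simulation grid over (mu_s'@550, sigma_s@550, bvf).

    Defaults: mu_s' from 10 to 35 cm^-1 in 5 equal steps (6 values),
    sigma_s from 0.5 to 8 um^2 in 0.5 um^2 steps (16 values), blood
    volume fraction 0.4-0.9% in 0.1% steps (6 values).
    """

    musp_values: np.ndarray = field(
        default_factory=lambda: np.linspace(10.0, 35.0, 6)
    )
    sigma_values: np.ndarray = field(
        default_factory=lambda: np.arange(0.5, 8.01, 0.5)
    )
    bvf_values: np.ndarray = field(
        default_factory=lambda: np.arange(0.004, 0.00901, 0.001)
    )

    def __post_init__(self) -> None:
        self.musp_values = np.asarray(self.musp_values, dtype=float)
        self.sigma_values = np.asarray(self.sigma_values, dtype=float)
        self.bvf_values = np.asarray(self.bvf_values, dtype=float)
        if self.musp_values.min() < 10.0 - 1e-9 or self.musp_values.max() > 35.0 + 1e-9:
            raise ValueError("musp grid must lie within [10, 35] cm^-1")

    def points(self):
        """Iterate (index, musp, sigma, bvf) over the Cartesian grid."""
        for i, (musp, sigma, bvf) in enumerate(
            product(self.musp_values, self.sigma_values, self.bvf_values)
        ):
            yield i, float(musp), float(sigma), float(bvf)

    def __len__(self) -> int:
        return len(self.musp_values) * len(self.sigma_values) * len(self.bvf_values)


def build_parameter_grid(
    grid: ParameterGrid | None = None,
    wavelengths: np.ndarray | None = None,
    **tissue_kwargs,
) -> list[tuple[int, float, float, float, TissueOpticalProperties]]:
    """Materialize tissue optical properties for every grid point.

    Sphere radii and cross-section spectra depend only on sigma, so they
    are solved once per distinct sigma value and reused.
    """
    if grid is None:
        grid = ParameterGrid()
    if wavelengths is None:
        wavelengths = default_wavelengths()
    cache: dict[float, TissueOpticalProperties] = {}
    out = []
    for i, musp, sigma, bvf in grid.points():
        base = cache.get(sigma)
        if base is None:
            base = make_tissue(1.0, sigma, 0.0, wavelengths, **tissue_kwargs)
            cache[sigma] = base
        blood = BloodModel(bvf, oxygen_saturation=tissue_kwargs.get("oxygen_saturation", 1.0))
        props = TissueOpticalProperties(
            wavelengths=base.wavelengths,
            mua=absorption_coefficient(base.wavelengths, blood),
            mus=base.mus * musp,
            musp=base.musp * musp,
            g_transport=base.g_transport,
            n_medium=base.n_medium,
            scatterer=base.scatterer,
            b=base.b,
        )
        out.append((i, musp, sigma, bvf, props))
    return out
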