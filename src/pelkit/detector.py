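"""RGB detector model: reflectance spectra to camera channel values.

Channel values are the illuminant- and quantum-efficiency-weighted
integrals of the reflectance spectrum over 350-750 nm.  The packaged
default response is a tri-Gaussian model (peaks 460/530/600 nm, 80 nm
FWHM, equal peak height) standing in for an unpublished camera; any
response with the same CSV schema can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectorResponse", "RgbTriple", "default_response", "spectrum_to_rgb"]


@dataclass
class DetectorResponse:
    """Per-channel quantum-efficiency weights on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    qy_red: np.ndarray
    qy_green: np.ndarray
    qy_blue: np.ndarray

    def __post_init__(self) -> None:
        for name in ("qy_red", "qy_green", "qy_blue"):
            q = np.asarray(getattr(self, name), dtype=float)
            if np.any(q < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, q)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.wavelengths, self.qy_red, self.qy_green, self.qy_blue])
        np.savetxt(path, arr, delimiter=",", header="wavelength_nm,qy_r,qy_g,qy_b", comments="")

    @classmethod
    def from_csv(cls, path) -> "DetectorResponse":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


@dataclass
class RgbTriple:
    """Channel-integrated intensities with a polarization tag."""

    r: float
    g: float
    b: float
    tag: str = "co"  # co | cross | differential

    def __post_init__(self) -> None:
        if self.tag not in ("co", "cross", "differential"):
            raise ValueError(f"unknown polarization tag {self.tag!r}")
        if self.tag != "differential" and (self.r < 0 or self.g < 0 or self.b < 0):
            raise ValueError("co/cross channel values must be non-negative")

    def __sub__(self, other: "RgbTriple") -> "RgbTriple":
        return RgbTriple(self.r - other.r, self.g - other.g, self.b - other.b, "differential")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b])


def default_response(step: float = 2.0) -> DetectorResponse:
    """Tri-Gaussian RGB response: peaks 460/530/600 nm, FWHM 80 nm."""
    lam = np.arange(350.0, 750.0 + step / 2, step)
    sigma = 80.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def band(center):
        return np.exp(-0.5 * ((lam - center) / sigma) ** 2)

    return DetectorResponse(lam, band(600.0), band(530.0), band(460.0))


def spectrum_to_rgb(
    wavelengths: np.ndarray,
    spectrum: np.ndarray,
    response: DetectorResponse | None = None,
    illuminant: np.ndarray | None = None,
    tag: str = "co",
) -> RgbTriple:
    """Integrate a reflectance spectrum into RGB channel values.

    value_c = sum_lambda spectrum * illuminant * qy_c * dlambda, with a
    flat white illuminant by default.  The spectrum is resampled onto the
    detector grid by linear interpolation; it must cover the part of the
    grid where the response is non-zero.
    """
    if response is None:
        response = default_response()
    lam_d = response.wavelengths
    lam = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    if lam[0] > lam_d[0] + 50 or lam[-1] < lam_d[-1] - 50:
        raise ValueError(
            f"spectrum grid [{lam[0]}, {lam[-1]}] nm does not cover the "
            f"detector grid [{lam_d[0]}, {lam_d[-1]}] nm"
        )
    spec_d = np.interp(lam_d, lam, spec)
    if illuminant is None:
        illum = np.ones_like(lam_d)
    else:
        illum = np.interp(lam_d, lam, np.asarray(illuminant, dtype=float))
    vals = [
        float(np.trapezoid(spec_d * illum * qy, lam_d))
        for qy in (response.qy_red, response.qy_green, response.qy_blue)
    ]
    if tag == "differential":
        return RgbTriple(*vals, tag=tag)
    # clip tiny negative round-off for the physical channels
    return RgbTriple(*[max(v, 0.0) if abs(v) < 1e-300 else v for v in vals], tag=tag)
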