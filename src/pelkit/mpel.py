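"""WLL / PEL / mPEL computation and the scattering-power regression.

From paired co- and cross-polarized RGB frames:

    WLL  = (R_co + R_cross) + (G_co + G_cross) + (B_co + B_cross)
    PEL  = (R_co - R_cross) + (G_co - G_cross) + (B_co - B_cross)
    mPEL = a0 + a1 (R_co - R_cross) + a2 (G_co - G_cross) + a3 (B_co - B_cross)

WLL is the unpolarized white-light image (surface + deep signal); PEL is
the polarization-gated surface image; mPEL is a linear surrogate for the
tissue scattering power b, with coefficients fitted by ordinary least
squares of b on the three RGB differentials of a simulated reflectance
lookup table.  A published coefficient set from the clinical device is
packaged alongside the fitting route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MpelCoefficients",
    "PolarizedFramePair",
    "DerivedImages",
    "published_coefficients",
    "compute_wll",
    "compute_pel",
    "fit_mpel",
    "apply_mpel",
    "saturate_percentiles",
]


@dataclass
class MpelCoefficients:
    """Affine map from RGB differentials to the scattering-power scale."""

    a0: float
    a1: float
    a2: float
    a3: float
    provenance: str  # "published" | "fitted"
    r2: float | None = None
    stderr: tuple | None = None

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a0, self.a1, self.a2, self.a3])):
            raise ValueError("mPEL coefficients must be finite")
        if self.provenance not in ("published", "fitted"):
            raise ValueError("provenance must be 'published' or 'fitted'")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3])

    def to_json(self, path) -> None:
        payload = {
            "a0": self.a0, "a1": self.a1, "a2": self.a2, "a3": self.a3,
            "provenance": self.provenance,
        }
        if self.r2 is not None:
            payload["r2"] = self.r2
        if self.stderr is not None:
            payload["stderr"] = list(self.stderr)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MpelCoefficients":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["a0"], d["a1"], d["a2"], d["a3"], d["provenance"],
            r2=d.get("r2"), stderr=tuple(d["stderr"]) if "stderr" in d else None,
        )


def published_coefficients() -> MpelCoefficients:
    """The packaged clinical-device coefficient set."""
    ref = resources.files("pelkit.data") / "mpel_coefficients_published.json"
    with ref.open() as fh:
        d = json.load(fh)
    return MpelCoefficients(d["a0"], d["a1"], d["a2"], d["a3"], d["provenance"])


@dataclass
class PolarizedFramePair:
    """Co- and cross-polarized RGB frames sharing geometry.

    Frames are (H, W, 3) arrays of linear intensity.  ``bit_depth``
    records the source quantization (12-bit acquisition); ``normalized``
    frames are on the [0, 1] reflectance-fraction scale the simulation
    coefficients were fitted on.
    """

    co: np.ndarray
    cross: np.ndarray
    valid_mask: np.ndarray | None = None
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.co = np.asarray(self.co, dtype=float)
        self.cross = np.asarray(self.cross, dtype=float)
        if self.co.shape != self.cross.shape:
            raise ValueError(f"co/cross shape mismatch: {self.co.shape} vs {self.cross.shape}")
        if self.co.ndim != 3 or self.co.shape[2] != 3:
            raise ValueError("frames must be (H, W, 3) RGB rasters")
        if np.any(self.co < 0) or np.any(self.cross < 0):
            raise ValueError("co/cross intensities must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.co.shape[:2], dtype=bool)

    def normalized(self) -> "PolarizedFramePair":
        """Rescale digital numbers to the [0, 1] reflectance-fraction scale."""
        full = float(2**self.bit_depth - 1)
        return PolarizedFramePair(self.co / full, self.cross / full, self.valid_mask, self.bit_depth)


@dataclass
class DerivedImages:
    """WLL / PEL / mPEL rasters derived from one frame pair."""

    wll: np.ndarray
    pel: np.ndarray
    mpel: np.ndarray
    valid_mask: np.ndarray
    coefficients: MpelCoefficients | None = None
    # the underlying surface/deep decomposition: I_delta = PEL = I_surface,
    # WLL = I_surface + I_deep
    config: dict = field(default_factory=dict)


def compute_wll(pair: PolarizedFramePair) -> np.ndarray:
    """Unpolarized white-light image: channel sum of co + cross."""
    return (pair.co + pair.cross).sum(axis=2)


def compute_pel(pair: PolarizedFramePair) -> np.ndarray:
    """Polarization-gated surface image: channel sum of co - cross."""
    return (pair.co - pair.cross).sum(axis=2)


def fit_mpel(table, min_rows: int = 5) -> MpelCoefficients:
    """OLS fit of scattering power b on the three RGB differentials.

    ``table`` is a :class:`pelkit.mc.ReflectanceLookupTable` or any
    DataFrame with columns dR, dG, dB, b.  Reports R-squared and
    coefficient standard errors; raises on a rank-deficient design,
    naming the collinear columns.
    """
    import statsmodels.api as sm

    df = getattr(table, "points", table)
    if len(df) < min_rows:
        raise ValueError(f"need >= {min_rows} rows to fit, got {len(df)}")
    X = df[["dR", "dG", "dB"]].to_numpy(dtype=float)
    y = df["b"].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        std = X.std(axis=0)
        degenerate = [c for c, s in zip(("dR", "dG", "dB"), std) if s < 1e-14]
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(("dR", "dG", "dB"))
            for j, b in enumerate(("dR", "dG", "dB"))
            if i < j and abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(
            f"rank-deficient design matrix (constant columns: {degenerate or 'none'}, "
            f"collinear pairs: {pairs or 'none'})"
        )
    fit = sm.OLS(y, Xc).fit()
    a0, a1, a2, a3 = fit.params
    return MpelCoefficients(
        a0, a1, a2, a3, provenance="fitted",
        r2=float(fit.rsquared) if y.std() > 0 else 1.0,
        stderr=tuple(float(s) for s in fit.bse),
    )


def saturate_percentiles(image: np.ndarray, low: float = 1.0, high: float = 1.0) -> np.ndarray:
    """Clip the bottom ``low``% and top ``high``% of pixel values."""
    finite = image[np.isfinite(image)]
    if finite.size == 0:
        return image
    lo, hi = np.percentile(finite, [low, 100.0 - high])
    return np.clip(image, lo, hi)


def apply_mpel(differentials, coeffs: MpelCoefficients, saturate: bool = False):
    """Evaluate mPEL = a0 + a1 dR + a2 dG + a3 dB.

    ``differentials`` is either a length-3 triple (dR, dG, dB) returning
    a scalar, or an (H, W, 3) raster of per-pixel differentials
    returning a raster; rasters are optionally 1%/1% percentile-saturated
    afterwards, matching the clinical contrast adjustment.
    """
    arr = np.asarray(
        differentials.as_array() if hasattr(differentials, "as_array") else differentials,
        dtype=float,
    )
    if not np.all(np.isfinite(arr)):
        raise ValueError("differential inputs must be finite")
    out = coeffs.a0 + coeffs.a1 * arr[..., 0] + coeffs.a2 * arr[..., 1] + coeffs.a3 * arr[..., 2]
    if arr.ndim == 1:
        return float(out)
    if saturate:
        out = saturate_percentiles(out)
    return out
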