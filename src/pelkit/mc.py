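"""Polarization-sensitive Monte Carlo photon transport in a slab.

Photon packets carry a Stokes vector (I,Q,U,V) referenced to a local
orthonormal frame (e1, e2, d) that is rotated at every scattering event.
Scattering angles are sampled from the polarization-dependent density

    p(theta, phi)  proportional to  m11(theta) I + m12(theta) (Q cos 2phi + U sin 2phi)

by composition (theta from the m11 sin(theta) marginal via an inverse-CDF
table, phi uniform) and rejection.  Energy is carried by a survival
weight: absorption multiplies the weight by the single-scattering albedo
at each event and Russian roulette terminates low-weight packets;
the Stokes vector itself is renormalized to I = 1.

Backscattered packets are analyzed into co- and cross-polarized channels
relative to the x-linear illumination polarization, the mechanism behind
polarization gating: singly-scattered superficial light stays co-polarized
while multiply-scattered deep light returns depolarized and splits evenly
between the two channels.

The engine is vectorized over photons (state-of-arrays); the single-photon
operations used in unit tests are the same code paths with batch size 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mie import MieSolution, solve_mie
from .tissue import TissueOpticalProperties, thickness_for_depth

__all__ = [
    "SlabGeometry",
    "PhaseTable",
    "PhotonBatch",
    "ReflectanceResult",
    "ReflectanceLookupTable",
    "launch",
    "sample_step",
    "scatter",
    "fresnel_unpolarized",
    "detect_stokes",
    "simulate_slab",
    "simulate_tissue_slab",
    "build_lookup_table",
]

WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_REJECTION_CAP = 10**6


@dataclass(frozen=True)
class SlabGeometry:
    """A single tissue layer bounded by z = 0 (top) and z = thickness."""

    thickness: float  # cm
    n_inside: float = 1.35
    n_outside: float = 1.0
    matched_boundary: bool = False  # disable Fresnel reflection (oracle mode)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be > 0")


class PhaseTable:
    """Tabulated single-scattering phase matrix with sampling tables."""

    def __init__(self, angles, m11, m12, m33, m34):
        self.angles = np.asarray(angles, dtype=float)
        self.m11 = np.asarray(m11, dtype=float)
        self.m12 = np.asarray(m12, dtype=float)
        self.m33 = np.asarray(m33, dtype=float)
        self.m34 = np.asarray(m34, dtype=float)
        pdf = self.m11 * np.sin(self.angles)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(self.angles))])
        self._cdf = cdf / cdf[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            self._ratio = np.where(self.m11 > 0, self.m12 / np.maximum(self.m11, 1e-300), 0.0)

    @classmethod
    def from_mie(cls, sol: MieSolution) -> "PhaseTable":
        return cls(sol.angles, sol.m11, sol.m12, sol.m33, sol.m34)

    @classmethod
    def isotropic(cls, n_angles: int = 1801) -> "PhaseTable":
        """Unpolarized isotropic scattering (flat m11, no polarization coupling)."""
        ang = np.linspace(0.0, np.pi, n_angles)
        one = np.ones_like(ang)
        return cls(ang, one, 0.0 * one, one, 0.0 * one)

    @classmethod
    def henyey_greenstein(cls, g: float, n_angles: int = 1801) -> "PhaseTable":
        """Scalar Henyey-Greenstein phase function (no polarization coupling)."""
        ang = np.linspace(0.0, np.pi, n_angles)
        mu = np.cos(ang)
        m11 = (1.0 - g**2) / (1.0 + g**2 - 2.0 * g * mu) ** 1.5
        zero = np.zeros_like(ang)
        return cls(ang, m11, zero, m11, zero)

    @classmethod
    def rayleigh(cls, n_angles: int = 1801) -> "PhaseTable":
        """Rayleigh (dipole) scattering phase matrix."""
        ang = np.linspace(0.0, np.pi, n_angles)
        mu = np.cos(ang)
        m11 = 0.75 * (1.0 + mu**2)
        m12 = 0.75 * (mu**2 - 1.0)
        m33 = 1.5 * mu
        return cls(ang, m11, m12, m33, np.zeros_like(ang))

    def sample_theta(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF sampling of theta from the m11 sin(theta) marginal."""
        return np.interp(u, self._cdf, self.angles)

    def ratio_at(self, theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, self.angles, self._ratio)

    def elements_at(self, theta: np.ndarray):
        return (
            np.interp(theta, self.angles, self.m11),
            np.interp(theta, self.angles, self.m12),
            np.interp(theta, self.angles, self.m33),
            np.interp(theta, self.angles, self.m34),
        )


@dataclass
class PhotonBatch:
    """State-of-arrays photon packets inside the slab."""

    z: np.ndarray  # depth (cm)
    d: np.ndarray  # (n,3) unit propagation direction
    e1: np.ndarray  # (n,3) Stokes reference axis (perpendicular to d)
    stokes: np.ndarray  # (n,4), I normalized to 1
    weight: np.ndarray
    n_events: np.ndarray
    max_z: np.ndarray

    def __len__(self) -> int:
        return self.z.size

    @property
    def e2(self) -> np.ndarray:
        return np.cross(self.d, self.e1)

    def select(self, mask: np.ndarray) -> "PhotonBatch":
        return PhotonBatch(
            self.z[mask], self.d[mask], self.e1[mask], self.stokes[mask],
            self.weight[mask], self.n_events[mask], self.max_z[mask],
        )


def launch(geometry: SlabGeometry, n: int = 1, stokes0=(1.0, 1.0, 0.0, 0.0)) -> PhotonBatch:
    """Launch photons at the top surface travelling +z.

    Default illumination is fully x-linearly polarized, Stokes (1,1,0,0),
    with the reference axis e1 along lab x.
    """
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    e1 = np.tile([1.0, 0.0, 0.0], (n, 1))
    stokes = np.tile(np.asarray(stokes0, dtype=float), (n, 1))
    return PhotonBatch(
        z=np.zeros(n), d=d, e1=e1, stokes=stokes,
        weight=np.ones(n), n_events=np.zeros(n, dtype=np.int64), max_z=np.zeros(n),
    )


def sample_step(mu_t: float, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Exponential free path: s = -ln(u)/mu_t."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    u = rng.random(n)
    return -np.log1p(-u) / mu_t


def _rotate_stokes(stokes: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate the Stokes reference frame by phi about the propagation axis."""
    c, s = np.cos(2.0 * phi), np.sin(2.0 * phi)
    out = stokes.copy()
    out[:, 1] = c * stokes[:, 1] + s * stokes[:, 2]
    out[:, 2] = -s * stokes[:, 1] + c * stokes[:, 2]
    return out


def scatter(batch: PhotonBatch, phase: PhaseTable, rng: np.random.Generator) -> PhotonBatch:
    """One polarized scattering event for every photon in the batch.

    Samples (theta, phi) from the polarization-dependent density, rotates
    the Stokes vector into the scattering plane, applies the sphere
    Mueller matrix, renormalizes to I = 1, and rotates the local frame.
    """
    n = len(batch)
    theta = np.empty(n)
    phi = np.empty(n)
    pending = np.arange(n)
    q, u_st = batch.stokes[:, 1], batch.stokes[:, 2]
    i_st = batch.stokes[:, 0]
    tries = 0
    while pending.size:
        tries += 1
        if tries > _REJECTION_CAP:
            raise RuntimeError("scattering rejection loop exceeded cap")
        th = phase.sample_theta(rng.random(pending.size))
        ph = rng.random(pending.size) * 2.0 * np.pi
        r = phase.ratio_at(th)
        lin = (q[pending] * np.cos(2 * ph) + u_st[pending] * np.sin(2 * ph)) / i_st[pending]
        accept = rng.random(pending.size) < 0.5 * (1.0 + r * lin)
        theta[pending[accept]] = th[accept]
        phi[pending[accept]] = ph[accept]
        pending = pending[~accept]

    # Stokes update: rotate into scattering plane, apply Mueller, renormalize
    s_rot = _rotate_stokes(batch.stokes, phi)
    m11, m12, m33, m34 = phase.elements_at(theta)
    s_new = np.empty_like(s_rot)
    s_new[:, 0] = m11 * s_rot[:, 0] + m12 * s_rot[:, 1]
    s_new[:, 1] = m12 * s_rot[:, 0] + m11 * s_rot[:, 1]
    s_new[:, 2] = m33 * s_rot[:, 2] + m34 * s_rot[:, 3]
    s_new[:, 3] = -m34 * s_rot[:, 2] + m33 * s_rot[:, 3]
    s_new /= s_new[:, [0]]

    # frame/direction update in the scattering plane
    cph, sph = np.cos(phi)[:, None], np.sin(phi)[:, None]
    cth, sth = np.cos(theta)[:, None], np.sin(theta)[:, None]
    e2 = batch.e2
    e1p = cph * batch.e1 + sph * e2
    d_new = cth * batch.d + sth * e1p
    e1_new = cth * e1p - sth * batch.d
    # re-orthonormalize against numerical drift
    d_new /= np.linalg.norm(d_new, axis=1, keepdims=True)
    e1_new -= np.sum(e1_new * d_new, axis=1, keepdims=True) * d_new
    e1_new /= np.linalg.norm(e1_new, axis=1, keepdims=True)

    return PhotonBatch(
        z=batch.z, d=d_new, e1=e1_new, stokes=s_new, weight=batch.weight,
        n_events=batch.n_events + 1, max_z=batch.max_z,
    )


def fresnel_unpolarized(cos_i: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Unpolarized-average Fresnel reflectance for incidence cosine cos_i."""
    cos_i = np.clip(np.abs(cos_i), 0.0, 1.0)
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i**2)
    refl = np.ones_like(cos_i)
    ok = sin_t2 < 1.0
    cos_t = np.sqrt(1.0 - sin_t2[ok])
    ci = cos_i[ok]
    rs = (n1 * ci - n2 * cos_t) / (n1 * ci + n2 * cos_t)
    rp = (n1 * cos_t - n2 * ci) / (n1 * cos_t + n2 * ci)
    refl[ok] = 0.5 * (rs**2 + rp**2)
    return refl


def detect_stokes(stokes: np.ndarray, d: np.ndarray, e1: np.ndarray) -> np.ndarray:
    """Q in the lab analyzer frame (x vs y polarization) for exiting photons.

    Projects the lab x axis into the plane transverse to the exit
    direction and rotates the Stokes reference frame onto it.
    """
    xhat = np.array([1.0, 0.0, 0.0])
    f1 = xhat - d * d[:, [0]]
    norm = np.linalg.norm(f1, axis=1, keepdims=True)
    # degenerate exit along x: analyzer orientation undefined, keep frame
    safe = norm[:, 0] > 1e-12
    f1[safe] /= norm[safe]
    f1[~safe] = e1[~safe]
    f2 = np.cross(d, f1)
    cos_a = np.sum(e1 * f1, axis=1)
    sin_a = np.sum(e1 * f2, axis=1)
    c2 = cos_a**2 - sin_a**2
    s2 = 2.0 * sin_a * cos_a
    return c2 * stokes[:, 1] - s2 * stokes[:, 2]


@dataclass
class ExitRecords:
    """Per-photon bookkeeping for packets that left through the top surface."""

    co: np.ndarray
    cross: np.ndarray
    n_events: np.ndarray
    max_depth: np.ndarray


@dataclass
class ReflectanceResult:
    """Tallies of one slab simulation (all values are fractions of input energy)."""

    R_co: float
    R_cross: float
    R_specular: float
    R_total: float
    T_total: float
    A_total: float
    n_photons: int
    seed: int
    records: ExitRecords | None = None

    @property
    def R_diffuse(self) -> float:
        return self.R_co + self.R_cross


def simulate_slab(
    mua: float,
    mus: float,
    phase: PhaseTable,
    geometry: SlabGeometry,
    n_photons: int,
    seed: int,
    stokes0=(1.0, 1.0, 0.0, 0.0),
    keep_records: bool = False,
    batch_size: int = 100_000,
) -> ReflectanceResult:
    """Transport ``n_photons`` packets through the slab and tally reflectance.

    Deterministic for a fixed seed.  Absorption is handled by albedo
    weighting at each scattering event; packets below the 1e-4 weight
    threshold play Russian roulette with survival factor 10.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if mus <= 0:
        raise ValueError("mus must be > 0")
    rng = np.random.default_rng(seed)
    mut = mua + mus
    albedo = mus / mut
    n1, n2 = geometry.n_inside, geometry.n_outside

    r_spec = 0.0 if geometry.matched_boundary else fresnel_unpolarized(
        np.array([1.0]), n2, n1
    )[0]

    co_sum = cross_sum = t_sum = a_sum = 0.0
    rec_co, rec_cross, rec_nev, rec_depth = [], [], [], []

    remaining = n_photons
    while remaining > 0:
        nb = min(batch_size, remaining)
        remaining -= nb
        batch = launch(geometry, nb, stokes0)
        batch.weight *= 1.0 - r_spec

        while len(batch):
            s = sample_step(mut, rng, len(batch))
            z_new = batch.z + batch.d[:, 2] * s
            # fold at boundaries until every photon is inside or has exited
            alive = np.ones(len(batch), dtype=bool)
            while True:
                out_top = alive & (z_new < 0.0)
                out_bot = alive & (z_new > geometry.thickness)
                if not (out_top.any() or out_bot.any()):
                    break
                for mask, top in ((out_top, True), (out_bot, False)):
                    if not mask.any():
                        continue
                    idx = np.where(mask)[0]
                    cos_i = np.abs(batch.d[idx, 2])
                    refl = (
                        np.zeros(idx.size)
                        if geometry.matched_boundary
                        else fresnel_unpolarized(cos_i, n1, n2)
                    )
                    exits = rng.random(idx.size) >= refl
                    exit_idx = idx[exits]
                    if exit_idx.size:
                        w = batch.weight[exit_idx]
                        if top:
                            q_lab = detect_stokes(
                                batch.stokes[exit_idx], batch.d[exit_idx], batch.e1[exit_idx]
                            )
                            i_lab = batch.stokes[exit_idx, 0]
                            co = w * (i_lab + q_lab) / (2.0 * i_lab)
                            cr = w * (i_lab - q_lab) / (2.0 * i_lab)
                            co_sum += co.sum()
                            cross_sum += cr.sum()
                            if keep_records:
                                rec_co.append(co)
                                rec_cross.append(cr)
                                rec_nev.append(batch.n_events[exit_idx])
                                rec_depth.append(batch.max_z[exit_idx])
                        else:
                            t_sum += w.sum()
                        alive[exit_idx] = False
                    refl_idx = idx[~exits]
                    if refl_idx.size:
                        if top:
                            z_new[refl_idx] = -z_new[refl_idx]
                        else:
                            z_new[refl_idx] = 2.0 * geometry.thickness - z_new[refl_idx]
                        batch.d[refl_idx, 2] *= -1.0
                        batch.e1[refl_idx, 2] *= -1.0
            batch.z = z_new
            np.maximum(batch.max_z, batch.z, out=batch.max_z)
            batch = batch.select(alive)
            if not len(batch):
                break

            # interaction: deposit absorbed weight, scatter, roulette
            a_sum = a_sum + (1.0 - albedo) * batch.weight.sum()
            batch.weight *= albedo
            batch = scatter(batch, phase, rng)
            low = batch.weight < WEIGHT_THRESHOLD
            if low.any():
                survive = rng.random(int(low.sum())) < ROULETTE_SURVIVAL
                killed = np.where(low)[0][~survive]
                surv = np.where(low)[0][survive]
                batch.weight[surv] /= ROULETTE_SURVIVAL
                keep = np.ones(len(batch), dtype=bool)
                keep[killed] = False
                batch = batch.select(keep)

    records = None
    if keep_records:
        records = ExitRecords(
            co=np.concatenate(rec_co) if rec_co else np.empty(0),
            cross=np.concatenate(rec_cross) if rec_cross else np.empty(0),
            n_events=np.concatenate(rec_nev) if rec_nev else np.empty(0, dtype=np.int64),
            max_depth=np.concatenate(rec_depth) if rec_depth else np.empty(0),
        )
    return ReflectanceResult(
        R_co=co_sum / n_photons,
        R_cross=cross_sum / n_photons,
        R_specular=float(r_spec),
        R_total=(co_sum + cross_sum) / n_photons + float(r_spec),
        T_total=t_sum / n_photons,
        A_total=a_sum / n_photons,
        n_photons=n_photons,
        seed=seed,
        records=records,
    )


def _slab_thickness(props: TissueOpticalProperties, tau: float, g_convention: float = 0.9) -> float:
    """Slab thickness from tau at 550 nm under the mu_s'/(1-g) convention."""
    mua_ref = float(np.interp(550.0, props.wavelengths, props.mua))
    musp_ref = float(np.interp(550.0, props.wavelengths, props.musp))
    return thickness_for_depth(tau, mua_ref + musp_ref / (1.0 - g_convention))


def simulate_tissue_slab(
    props: TissueOpticalProperties,
    wavelength_nm: float,
    n_photons: int,
    seed: int,
    tau: float = 20.0,
    n_angles: int = 1801,
    **kwargs,
) -> ReflectanceResult:
    """Simulate one tissue condition at one wavelength.

    The slab thickness is set so the optical depth at the 550 nm
    reference equals ``tau`` (default 20).  The scattering coefficient
    entering the depth definition follows the fixed-anisotropy
    convention mu_s = mu_s'/(1 - 0.9), so slabs with equal reduced
    scattering share one geometry regardless of sphere size — the
    white-light signal then depends on mu_s', not on the scatterer.
    """
    thickness = _slab_thickness(props, tau)
    geometry = SlabGeometry(thickness, n_inside=props.n_medium)
    mua, mus = props.at_wavelength(wavelength_nm)
    phase = PhaseTable.from_mie(solve_mie(props.scatterer, wavelength_nm, n_angles))
    return simulate_slab(mua, mus, phase, geometry, n_photons, seed, **kwargs)


@dataclass
class ReflectanceLookupTable:
    """Simulated co/cross reflectance over the tissue parameter grid.

    ``spectra``: one row per (grid point, wavelength) with R_co/R_cross.
    ``points``: one row per grid point with the detector-integrated RGB
    differentials, WLL and PEL scalars, and the scattering power b.
    """

    spectra: pd.DataFrame
    points: pd.DataFrame

    def to_csv(self, path) -> None:
        self.spectra.to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name, df in (("spectra", self.spectra), ("points", self.points)):
                grp = fh.create_group(name)
                for col in df.columns:
                    grp.create_dataset(col, data=df[col].to_numpy())

    @classmethod
    def from_csv(cls, path, detector=None, illuminant=None) -> "ReflectanceLookupTable":
        """Rebuild from the long-format spectra CSV, re-deriving per-point RGB."""
        spectra = pd.read_csv(path)
        points = summarize_points(spectra, detector=detector, illuminant=illuminant)
        return cls(spectra=spectra, points=points)


def summarize_points(spectra: pd.DataFrame, detector=None, illuminant=None) -> pd.DataFrame:
    """Detector-integrate per-point spectra into RGB differentials and WLL/PEL."""
    from .detector import default_response, spectrum_to_rgb

    if detector is None:
        detector = default_response()
    rows = []
    keys = ["point_index", "musp_ref", "sigma_um2", "bvf", "b", "seed"]
    for _, grp in spectra.groupby("point_index"):
        grp = grp.sort_values("wavelength_nm")
        lam = grp["wavelength_nm"].to_numpy()
        rgb_co = spectrum_to_rgb(lam, grp["R_co"].to_numpy(), detector, illuminant)
        rgb_cross = spectrum_to_rgb(lam, grp["R_cross"].to_numpy(), detector, illuminant)
        d_r, d_g, d_b = (rgb_co.r - rgb_cross.r, rgb_co.g - rgb_cross.g, rgb_co.b - rgb_cross.b)
        rec = {k: grp[k].iloc[0] for k in keys}
        rec.update(
            co_r=rgb_co.r, co_g=rgb_co.g, co_b=rgb_co.b,
            cross_r=rgb_cross.r, cross_g=rgb_cross.g, cross_b=rgb_cross.b,
            dR=d_r, dG=d_g, dB=d_b,
            wll=(rgb_co.r + rgb_cross.r) + (rgb_co.g + rgb_cross.g) + (rgb_co.b + rgb_cross.b),
            pel=d_r + d_g + d_b,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def build_lookup_table(
    grid_points,
    wavelengths: np.ndarray,
    n_photons: int,
    seed: int,
    tau: float = 20.0,
    detector=None,
    illuminant=None,
    n_angles: int = 901,
    progress: bool = False,
) -> ReflectanceLookupTable:
    """Run the Monte Carlo over every grid point and wavelength.

    ``grid_points`` is the output of :func:`pelkit.tissue.build_parameter_grid`.
    Each grid point gets its own derived seed (base seed + point index,
    recorded in the table) so results do not depend on execution order.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    rows = []
    iterator = grid_points
    if progress:
        from tqdm import tqdm  # type: ignore

        iterator = tqdm(list(grid_points))
    for i, musp, sigma, bvf, props in iterator:
        point_seed = int(seed + i)
        thickness = _slab_thickness(props, tau)
        geometry = SlabGeometry(thickness, n_inside=props.n_medium)
        for j, lam in enumerate(wavelengths):
            mua, mus = props.at_wavelength(lam)
            phase = PhaseTable.from_mie(solve_mie(props.scatterer, lam, n_angles))
            res = simulate_slab(
                mua, mus, phase, geometry, n_photons, seed=point_seed * 1000 + j
            )
            rows.append(
                dict(
                    point_index=i, musp_ref=musp, sigma_um2=sigma, bvf=bvf,
                    b=props.b, wavelength_nm=lam,
                    R_co=res.R_co, R_cross=res.R_cross, seed=point_seed,
                )
            )
    spectra = pd.DataFrame(rows)
    points = summarize_points(spectra, detector=detector, illuminant=illuminant)
    return ReflectanceLookupTable(spectra=spectra, points=points)
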