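"""Polarized Monte Carlo transport: launch/step/scatter mechanics,
boundary physics, detection algebra, and whole-slab tallies."""

import numpy as np
import pytest
from scipy import stats

from pelkit.mc import (
    PhaseTable,
    SlabGeometry,
    detect_stokes,
    fresnel_unpolarized,
    launch,
    sample_step,
    scatter,
    simulate_slab,
    simulate_tissue_slab,
)


class FakeRng:
    """Scripted uniform source for deterministic scattering tests."""

    def __init__(self, values):
        self._queue = [np.asarray(v, dtype=float) for v in values]

    def random(self, n=None):
        out = self._queue.pop(0)
        assert n is None or out.size == n
        return out


class TestLaunch:
    def test_initial_state(self):
        batch = launch(SlabGeometry(0.1), n=3)
        np.testing.assert_allclose(batch.stokes, [[1, 1, 0, 0]] * 3)
        np.testing.assert_allclose(batch.d, [[0, 0, 1]] * 3)
        np.testing.assert_allclose(np.einsum("ij,ij->i", batch.d, batch.d), 1.0)
        # degree of polarization
        dop = np.linalg.norm(batch.stokes[:, 1:], axis=1) / batch.stokes[:, 0]
        np.testing.assert_allclose(dop, 1.0)


class TestStep:
    def test_closed_form_at_median(self):
        rng = FakeRng([np.array([0.5])])
        assert sample_step(10.0, rng, 1)[0] == pytest.approx(np.log(2) / 10.0)

    def test_mean_and_scaling(self):
        rng = np.random.default_rng(0)
        s = sample_step(7.0, rng, 100_000)
        se = s.std() / np.sqrt(s.size)
        assert abs(s.mean() - 1 / 7.0) < 3 * se
        rng = np.random.default_rng(0)
        s2 = sample_step(14.0, rng, 100_000)
        assert s2.mean() == pytest.approx(s.mean() / 2, rel=1e-12)

    def test_invalid_mut(self):
        with pytest.raises(ValueError):
            sample_step(0.0, np.random.default_rng(0), 1)


class TestScatter:
    def test_isotropic_unpolarized_cos_theta_uniform(self):
        """Isotropic unpolarized scattering gives cos(theta) ~ U(-1,1)."""
        n = 100_000
        batch = launch(SlabGeometry(1.0), n, stokes0=(1, 0, 0, 0))
        out = scatter(batch, PhaseTable.isotropic(), np.random.default_rng(3))
        cos_theta = out.d[:, 2]  # incident along +z
        ks = stats.kstest(cos_theta, stats.uniform(loc=-1, scale=2).cdf)
        assert ks.pvalue > 0.01

    def test_single_rayleigh_scatter_matches_mueller_oracle(self):
        """One forced Rayleigh event at theta=phi=pi/2 reproduces the
        closed-form Mueller algebra (normalized Stokes and geometry)."""
        from oracles import rayleigh_single_scatter_oracle

        phase = PhaseTable.rayleigh()
        phase.sample_theta = lambda u: np.full(u.size, np.pi / 2)
        batch = launch(SlabGeometry(1.0), 1)
        rng = FakeRng([np.array([0.5]), np.array([0.25]), np.array([0.0])])
        out = scatter(batch, phase, rng)  # phi = 0.25 * 2pi = pi/2
        expected = rayleigh_single_scatter_oracle((1, 1, 0, 0), np.pi / 2, np.pi / 2)
        np.testing.assert_allclose(out.stokes[0], expected / expected[0], atol=1e-12)
        # scattered into the y-z plane at 90 degrees: direction is +y
        np.testing.assert_allclose(out.d[0], [0, 1, 0], atol=1e-12)

    def test_stokes_physicality_preserved(self):
        """I^2 >= Q^2+U^2+V^2 and orthonormal frames after many events."""
        rng = np.random.default_rng(7)
        batch = launch(SlabGeometry(1.0), 2000)
        phase = PhaseTable.rayleigh()
        for _ in range(5):
            batch = scatter(batch, phase, rng)
        s = batch.stokes
        assert np.all(s[:, 0] ** 2 >= (s[:, 1:] ** 2).sum(axis=1) - 1e-9)
        np.testing.assert_allclose(np.linalg.norm(batch.d, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            np.einsum("ij,ij->i", batch.d, batch.e1), 0.0, atol=1e-9
        )


class TestBoundary:
    def test_normal_incidence_fresnel(self):
        r = fresnel_unpolarized(np.array([1.0]), 1.35, 1.0)[0]
        assert r == pytest.approx(((1.35 - 1) / (1.35 + 1)) ** 2, rel=1e-12)

    def test_total_internal_reflection(self):
        # beyond the critical angle sin(theta_c) = 1/1.35
        cos_c = np.sqrt(1 - (1 / 1.35) ** 2)
        r = fresnel_unpolarized(np.array([0.5 * cos_c]), 1.35, 1.0)[0]
        assert r == 1.0

    def test_matched_boundary_never_reflects(self):
        geo = SlabGeometry(0.05, matched_boundary=True)
        res = simulate_slab(1e-9, 50.0, PhaseTable.isotropic(), geo, 2000, seed=4)
        assert res.R_specular == 0.0
        assert res.R_total + res.T_total == pytest.approx(1.0, abs=3 / np.sqrt(2000))


class TestDetect:
    def test_depolarized_splits_evenly(self):
        s = np.array([[1.0, 0.0, 0.0, 0.0]])
        d = np.array([[0.0, 0.0, -1.0]])
        e1 = np.array([[1.0, 0.0, 0.0]])
        q = detect_stokes(s, d, e1)
        co, cross = (1 + q) / 2, (1 - q) / 2
        assert co[0] == pytest.approx(0.5) and cross[0] == pytest.approx(0.5)

    def test_preserved_polarization_all_co(self):
        s = np.array([[1.0, 1.0, 0.0, 0.0]])
        d = np.array([[0.0, 0.0, -1.0]])
        e1 = np.array([[1.0, 0.0, 0.0]])
        q = detect_stokes(s, d, e1)
        assert q[0] == pytest.approx(1.0)

    def test_co_plus_cross_conserves_weight(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.normal(size=3)
            d = v / np.linalg.norm(v)
            d[2] = -abs(d[2]) or -1.0
            d /= np.linalg.norm(d)
            e1 = np.cross(d, rng.normal(size=3))
            e1 /= np.linalg.norm(e1)
            q_frac = rng.uniform(-1, 1)
            s = np.array([[1.0, q_frac, 0.0, 0.0]])
            q = detect_stokes(s, d[None], e1[None])
            co, cross = (1 + q) / 2, (1 - q) / 2
            assert co[0] + cross[0] == pytest.approx(1.0, abs=1e-12)


class TestSlabSimulation:
    def test_energy_conservation_no_absorber(self):
        geo = SlabGeometry(0.2)
        n = 20_000
        res = simulate_slab(1e-12, 100.0, PhaseTable.isotropic(), geo, n, seed=5)
        assert res.A_total < 1e-6
        assert res.R_total + res.T_total + res.A_total == pytest.approx(
            1.0, abs=3 / np.sqrt(n)
        )

    def test_energy_conservation_tissue_point(self, tissue_point):
        n = 10_000
        res = simulate_tissue_slab(tissue_point, 550.0, n, seed=6, n_angles=901)
        assert res.R_total + res.T_total + res.A_total == pytest.approx(
            1.0, abs=3 / np.sqrt(n)
        )

    def test_unpolarized_illumination_symmetric_channels(self):
        """Stokes (1,0,0,0) in: co and cross agree within sampling noise."""
        geo = SlabGeometry(0.05)
        n = 20_000
        res = simulate_slab(
            0.1, 200.0, PhaseTable.rayleigh(), geo, n, seed=8, stokes0=(1, 0, 0, 0)
        )
        se = np.sqrt(res.R_diffuse / n)
        assert abs(res.R_co - res.R_cross) < 3 * se

    def test_similarity_relation_forward_vs_isotropic(self):
        """HG g=0.9 at mu_s'/(1-g) vs isotropic at mu_s': total diffuse
        reflectance agrees within 5% for a thick slab."""
        musp = 25.0
        mua = 0.5
        geo = SlabGeometry(20.0 / (mua + musp / 0.1))
        iso = simulate_slab(
            mua, musp, PhaseTable.isotropic(), geo, 20_000, seed=9, stokes0=(1, 0, 0, 0)
        )
        fwd = simulate_slab(
            mua, musp / 0.1, PhaseTable.henyey_greenstein(0.9), geo, 20_000, seed=10,
            stokes0=(1, 0, 0, 0),
        )
        assert fwd.R_diffuse == pytest.approx(iso.R_diffuse, rel=0.05)

    def test_determinism_same_seed(self, tissue_point):
        r1 = simulate_tissue_slab(tissue_point, 550.0, 2000, seed=11, n_angles=301)
        r2 = simulate_tissue_slab(tissue_point, 550.0, 2000, seed=11, n_angles=301)
        assert (r1.R_co, r1.R_cross, r1.T_total, r1.A_total) == (
            r2.R_co, r2.R_cross, r2.T_total, r2.A_total
        )

    def test_depolarization_increases_with_scattering_order(self):
        """Binned by number of scattering events, the co/cross ratio of
        exiting packets decreases over the first 10 bins (probed with the
        backscatter-rich Rayleigh phase, where all orders are populated)."""
        res = simulate_slab(
            0.1, 100.0, PhaseTable.rayleigh(), SlabGeometry(0.2), 60_000,
            seed=12, keep_records=True,
        )
        rec = res.records
        ratios = []
        for k in range(1, 11):
            sel = rec.n_events == k
            assert sel.sum() >= 20
            ratios.append(rec.co[sel].sum() / max(rec.cross[sel].sum(), 1e-12))
        # strictly decreasing while polarization memory dominates; near the
        # depolarized asymptote (ratio -> 1) only the trend is resolvable
        assert all(a > b for a, b in zip(ratios[:6], ratios[1:6]))
        assert stats.spearmanr(np.arange(10), ratios).statistic < -0.8

    def test_polarization_gated_depth_is_shallow(self, tissue_point):
        """(co - cross)-weighted mean maximum depth is smaller than the
        (co + cross)-weighted one: the differential signal is superficial."""
        res = simulate_tissue_slab(
            tissue_point, 550.0, 30_000, seed=13, n_angles=901, keep_records=True
        )
        rec = res.records
        diff_w = rec.co - rec.cross
        sum_w = rec.co + rec.cross
        depth_gated = np.average(rec.max_depth, weights=np.clip(diff_w, 0, None))
        depth_total = np.average(rec.max_depth, weights=sum_w)
        assert depth_gated < depth_total


class TestLookupTable:
    def test_row_count_and_determinism(self):
        from pelkit.mc import build_lookup_table
        from pelkit.tissue import ParameterGrid, build_parameter_grid

        grid = ParameterGrid(musp_values=[20.0], sigma_values=[1.0], bvf_values=[0.005])
        pts = build_parameter_grid(grid)
        wl = np.array([350.0, 550.0, 750.0])
        lut1 = build_lookup_table(pts, wl, n_photons=500, seed=14, n_angles=301)
        lut2 = build_lookup_table(pts, wl, n_photons=500, seed=14, n_angles=301)
        assert len(lut1.spectra) == len(pts) * wl.size
        assert lut1.spectra.equals(lut2.spectra)
        assert set(lut1.spectra.columns) >= {
            "musp_ref", "sigma_um2", "bvf", "b", "wavelength_nm", "R_co", "R_cross", "seed"
        }

    def test_csv_round_trip(self, tmp_path):
        from pelkit.mc import ReflectanceLookupTable, build_lookup_table
        from pelkit.tissue import ParameterGrid, build_parameter_grid

        grid = ParameterGrid(musp_values=[20.0], sigma_values=[1.0], bvf_values=[0.005])
        pts = build_parameter_grid(grid)
        lut = build_lookup_table(pts, np.array([350.0, 550.0, 750.0]), 300, seed=15, n_angles=301)
        path = tmp_path / "lut.csv"
        lut.to_csv(path)
        back = ReflectanceLookupTable.from_csv(path)
        np.testing.assert_allclose(back.points["dB"], lut.points["dB"], rtol=1e-12)

    def test_hdf5_export(self, tmp_path):
        import h5py

        from pelkit.mc import build_lookup_table
        from pelkit.tissue import ParameterGrid, build_parameter_grid

        grid = ParameterGrid(musp_values=[20.0], sigma_values=[1.0], bvf_values=[0.005])
        pts = build_parameter_grid(grid)
        lut = build_lookup_table(pts, np.array([350.0, 550.0, 750.0]), 200, seed=16, n_angles=301)
        path = tmp_path / "lut.h5"
        lut.to_hdf5(path)
        with h5py.File(path) as fh:
            np.testing.assert_allclose(
                fh["spectra/R_co"][...], lut.spectra["R_co"].to_numpy()
            )
            assert "points/dB" in fh
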