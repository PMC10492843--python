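"""Independent oracles used by the test suite.

These deliberately do not share code with the package: the Mie oracle
sums the series in arbitrary-precision arithmetic with its own
Riccati-Bessel recurrences; the Fisher oracle enumerates the
hypergeometric distribution; the regression oracle solves the normal
equations directly.
"""

from __future__ import annotations

from math import comb

import mpmath as mp
import numpy as np


def mie_series_oracle(x, m, angles, dps: int = 40):
    """Arbitrary-precision Mie amplitudes and cross-section factors.

    Returns (S1, S2, Qsca, Qext, g) for size parameter ``x`` and real
    relative index ``m`` at the given scattering angles (radians).
    Riccati-Bessel functions are built by upward recurrence from the
    closed-form n=0,1 seeds in mpmath arithmetic.
    """
    with mp.workdps(dps):
        x = mp.mpf(x)
        m_rel = mp.mpf(m)
        nmax = int(mp.ceil(x + 4 * x ** (mp.mpf(1) / 3) + 2))

        def psi_chain(z, n_top):
            # psi_n = z j_n(z); upward recurrence psi_{n+1} = (2n+1)/z psi_n - psi_{n-1}
            psis = [mp.sin(z), mp.sin(z) / z - mp.cos(z)]
            for n in range(1, n_top):
                psis.append((2 * n + 1) / z * psis[n] - psis[n - 1])
            return psis

        def chi_chain(z, n_top):
            # chi_n = -z y_n(z)
            chis = [mp.cos(z), mp.cos(z) / z + mp.sin(z)]
            for n in range(1, n_top):
                chis.append((2 * n + 1) / z * chis[n] - chis[n - 1])
            return chis

        psi_x = psi_chain(x, nmax + 1)
        chi_x = chi_chain(x, nmax + 1)
        psi_mx = psi_chain(m_rel * x, nmax + 1)

        a_n, b_n = [], []
        for n in range(1, nmax + 1):
            dpsi_x = psi_x[n - 1] - n / x * psi_x[n]
            dchi_x = chi_x[n - 1] - n / x * chi_x[n]
            dpsi_mx = psi_mx[n - 1] - n / (m_rel * x) * psi_mx[n]
            xi = psi_x[n] - 1j * chi_x[n]
            dxi = dpsi_x - 1j * dchi_x
            a = (m_rel * psi_mx[n] * dpsi_x - psi_x[n] * dpsi_mx) / (
                m_rel * psi_mx[n] * dxi - xi * dpsi_mx
            )
            b = (psi_mx[n] * dpsi_x - m_rel * psi_x[n] * dpsi_mx) / (
                psi_mx[n] * dxi - m_rel * xi * dpsi_mx
            )
            a_n.append(a)
            b_n.append(b)

        qsca = mp.mpf(0)
        qext = mp.mpf(0)
        gq = mp.mpf(0)
        for n in range(1, nmax + 1):
            a, b = a_n[n - 1], b_n[n - 1]
            qsca += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
            qext += (2 * n + 1) * (a + b).real
            if n < nmax:
                a1, b1 = a_n[n], b_n[n]
                gq += (n * (n + 2) / mp.mpf(n + 1)) * (
                    a * mp.conj(a1) + b * mp.conj(b1)
                ).real
            gq_term = ((2 * n + 1) / mp.mpf(n * (n + 1))) * (a * mp.conj(b)).real
            gq += gq_term
        qsca *= 2 / x**2
        qext *= 2 / x**2
        g = (4 / x**2) * gq / qsca

        s1_list, s2_list = [], []
        for theta in np.atleast_1d(angles):
            mu = mp.cos(mp.mpf(float(theta)))
            pi_prev, pi_cur = mp.mpf(0), mp.mpf(1)
            s1 = mp.mpc(0)
            s2 = mp.mpc(0)
            for n in range(1, nmax + 1):
                tau_cur = n * mu * pi_cur - (n + 1) * pi_prev
                w = mp.mpf(2 * n + 1) / (n * (n + 1))
                a, b = a_n[n - 1], b_n[n - 1]
                s1 += w * (a * pi_cur + b * tau_cur)
                s2 += w * (a * tau_cur + b * pi_cur)
                pi_next = ((2 * n + 1) * mu * pi_cur - (n + 1) * pi_prev) / n
                pi_prev, pi_cur = pi_cur, pi_next
            s1_list.append(complex(s1))
            s2_list.append(complex(s2))

        return (
            np.array(s1_list),
            np.array(s2_list),
            float(qsca),
            float(qext),
            float(g),
        )


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def ols_normal_equations(X, y):
    """OLS coefficients (with intercept) by solving the normal equations."""
    X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def rayleigh_single_scatter_oracle(stokes_in, theta, phi):
    """Closed-form Mueller algebra for one Rayleigh scattering event.

    Rotates the Stokes vector into the scattering plane (rotation by phi),
    applies the Rayleigh scattering matrix at angle theta, and returns the
    unnormalized outgoing Stokes vector in the scattering-plane frame.
    """
    s = np.asarray(stokes_in, dtype=float)
    c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
    rot = np.array(
        [[1, 0, 0, 0], [0, c2, s2, 0], [0, -s2, c2, 0], [0, 0, 0, 1]]
    )
    mu = np.cos(theta)
    m11 = 0.75 * (1 + mu**2)
    m12 = 0.75 * (mu**2 - 1)
    m33 = 1.5 * mu
    mueller = np.array(
        [[m11, m12, 0, 0], [m12, m11, 0, 0], [0, 0, m33, 0], [0, 0, 0, m33]]
    )
    return mueller @ (rot @ s)
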