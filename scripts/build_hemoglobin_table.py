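"""Regenerate the packaged synthetic hemoglobin extinction table.

Writes ``src/pelkit/data/hemoglobin_extinction_synthetic.csv``: molar
extinction coefficients (cm^-1 / (mol/L)) of oxy- and deoxyhemoglobin on
a 5 nm grid over 350-750 nm.  The curves are a smooth parametric
reconstruction (sums of Gaussian absorption bands plus red-region tails)
anchored at the textbook band positions and magnitudes — Soret band at
414 nm (oxy) / 430 nm (deoxy), oxy Q-bands at 542/577 nm, deoxy Q-band
at 555 nm.  It is a synthetic stand-in for a measured compilation and is
labelled as such; downstream code needs only the band structure and
magnitudes, not spectroscopic-grade accuracy.
"""

from pathlib import Path

import numpy as np


def _band(lam, center, height, width):
    return height * np.exp(-0.5 * ((lam - center) / width) ** 2)


def synthetic_extinction(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam = np.asarray(lam, dtype=float)
    # oxyhemoglobin: Soret 414, Q bands 542 / 577, UV shoulder, low red floor
    eps_oxy = (
        _band(lam, 414.0, 5.24e5, 13.0)
        + _band(lam, 542.0, 5.3e4, 12.0)
        + _band(lam, 577.0, 5.5e4, 10.0)
        + _band(lam, 344.0, 2.6e4, 30.0)
        + 3.0e2
        + _band(lam, 760.0, 6.0e2, 40.0)  # mild near-infrared rise
    )
    # deoxyhemoglobin: Soret 430, single broad Q band 555, raised red tail
    eps_deoxy = (
        _band(lam, 430.0, 5.53e5, 14.0)
        + _band(lam, 555.0, 5.3e4, 18.0)
        + _band(lam, 350.0, 3.0e4, 35.0)
        + 4.0e3 * np.exp(-(lam - 600.0) / 150.0) * (lam > 600.0)
        + 6.0e2
    )
    return eps_oxy, eps_deoxy


def main() -> None:
    lam = np.arange(350.0, 755.0, 5.0)
    eps_oxy, eps_deoxy = synthetic_extinction(lam)
    out = Path(__file__).resolve().parents[1] / "src" / "pelkit" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "hemoglobin_extinction_synthetic.csv"
    with open(path, "w") as fh:
        fh.write("wavelength_nm,eps_oxy,eps_deoxy\n")
        for row in zip(lam, eps_oxy, eps_deoxy):
            fh.write(f"{row[0]:.0f},{row[1]:.6g},{row[2]:.6g}\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
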