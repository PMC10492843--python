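"""Build the packaged reflectance lookup table.

Runs the package's polarized Monte Carlo over a condensed tissue grid
(3 reduced scattering coefficients x 7 scattering cross sections x 3
blood volume fractions, 13 wavelengths, 10k photons per condition; seeds
recorded per row) and writes the long-format spectra CSV shipped as
``src/pelkit/data/lookup_table_small.csv``.  Rows are appended per grid
point and completed points are skipped on restart, so an interrupted
build resumes where it stopped.  Regenerating takes a few CPU-hours;
the packaged copy lets phantom fixtures and coefficient fits run in
milliseconds.

Usage: python scripts/build_packaged_lut.py [--photons N] [--seed S] [--out PATH]
"""

import argparse
import time
from pathlib import Path

import numpy as np

COLUMNS = [
    "point_index", "musp_ref", "sigma_um2", "bvf", "b",
    "wavelength_nm", "R_co", "R_cross", "seed",
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--photons", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument(
        "--out",
        default=Path(__file__).resolve().parents[1]
        / "src" / "pelkit" / "data" / "lookup_table_small.csv",
    )
    args = ap.parse_args()
    out = Path(args.out)

    import pandas as pd

    from pelkit.mc import build_lookup_table
    from pelkit.tissue import ParameterGrid, build_parameter_grid

    grid = ParameterGrid(
        musp_values=[15.0, 25.0, 35.0],
        sigma_values=[0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0],
        bvf_values=[0.004, 0.0065, 0.009],
    )
    points = build_parameter_grid(grid)
    wavelengths = np.linspace(350.0, 750.0, 13)

    done: set[int] = set()
    if out.exists():
        existing = pd.read_csv(out)
        counts = existing.groupby("point_index").size()
        done = set(counts[counts == len(wavelengths)].index)
        existing[existing.point_index.isin(done)].to_csv(
            out, index=False, float_format="%.6g"
        )
        print(f"resuming: {len(done)}/{len(points)} points already complete")
    else:
        out.write_text(",".join(COLUMNS) + "\n")

    t0 = time.time()
    for n_done, point in enumerate(points):
        i = point[0]
        if i in done:
            continue
        part = build_lookup_table([point], wavelengths, args.photons, args.seed)
        part.spectra[COLUMNS].to_csv(
            out, mode="a", header=False, index=False, float_format="%.6g"
        )
        print(
            f"point {i + 1}/{len(points)} done ({time.time() - t0:.0f} s elapsed)",
            flush=True,
        )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
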