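import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle helpers importable from any test module
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def packaged_lut():
    """The small pre-built Monte Carlo lookup table shipped with the package."""
    from pelkit.synthetic import load_packaged_lut

    return load_packaged_lut()


@pytest.fixture(scope="session")
def reduced_lut():
    """A reduced lookup table computed live by the polarized Monte Carlo.

    One reduced scattering coefficient and blood volume fraction, three
    well-separated scattering cross sections (b = 1.93, 1.78, 1.48):
    monodisperse-sphere Mie resonances ripple the polarized signal
    between closely spaced sizes, so strict scattering-power ordering is
    probed across well-separated b.
    """
    from pelkit.mc import build_lookup_table
    from pelkit.tissue import ParameterGrid, build_parameter_grid

    grid = ParameterGrid(
        musp_values=[25.0], sigma_values=[0.5, 2.0, 8.0], bvf_values=[0.004]
    )
    points = build_parameter_grid(grid)
    # 21 wavelengths average the per-sphere resonance ripple; 12k photons
    # put the channel-differential sampling noise well below the ~0.3
    # separations between these conditions
    wavelengths = np.linspace(350.0, 750.0, 21)
    return build_lookup_table(points, wavelengths, n_photons=12_000, seed=20)


@pytest.fixture(scope="session")
def tissue_point():
    """One mid-grid tissue condition used by several transport tests."""
    from pelkit.tissue import make_tissue

    return make_tissue(25.0, 1.0, 0.004)
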