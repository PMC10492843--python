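"""One polarized Monte Carlo run: co/cross reflectance of a tissue slab.

Simulates x-polarized illumination of a single tissue layer (optical
depth 20) and prints the energy budget and the polarization split of the
backscattered light.  The co channel exceeds the cross channel because
superficially scattered photons keep their incident polarization; deep
photons return depolarized and split evenly.
"""

import numpy as np

from pelkit import make_tissue, simulate_tissue_slab

props = make_tissue(musp_ref=25.0, sigma_um2=1.0, bvf=0.004)
res = simulate_tissue_slab(props, wavelength_nm=550.0, n_photons=20_000, seed=1,
                           keep_records=True)

print(f"tissue: mu_s'(550)=25 cm^-1, sigma_s=1 um^2, bvf=0.4%  (b={props.b:.2f})")
print(f"R_co      = {res.R_co:.4f}")
print(f"R_cross   = {res.R_cross:.4f}")
print(f"R_specular= {res.R_specular:.4f}")
print(f"T         = {res.T_total:.4f}")
print(f"A         = {res.A_total:.4f}")
print(f"sum       = {res.R_total + res.T_total + res.A_total:.4f}  (energy check)")

rec = res.records
diff = rec.co - rec.cross
depth_gated = np.average(rec.max_depth, weights=np.clip(diff, 0, None))
depth_total = np.average(rec.max_depth, weights=rec.co + rec.cross)
print(
    f"\nmean max depth, (co-cross)-weighted: {depth_gated*1e4:.0f} um vs "
    f"(co+cross)-weighted: {depth_total*1e4:.0f} um"
)
print("the differential (PEL) signal samples a much shallower layer.")
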