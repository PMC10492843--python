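# Default constants of the analysis pipeline.  Every stated physical or
# processing constant lives here so runs can record the exact configuration.

[optics]
n_tissue = 1.35
n_scatterer = 1.42
anisotropy_g = 0.9
optical_depth_tau = 20.0
reference_wavelength_nm = 550.0
wavelength_min_nm = 350.0
wavelength_max_nm = 750.0

[blood]
hemoglobin_g_per_dl = 15.0
hemoglobin_molar_mass = 64500.0
oxygen_saturation = 1.0

[grid]
# "10 to 35 cm^-1 with 5 equal steps" read as 6 values spanning the closed
# interval; set musp_n_values = 5 for the 5-value reading.
musp_min = 10.0
musp_max = 35.0
musp_n_values = 6
sigma_min_um2 = 0.5
sigma_max_um2 = 8.0
sigma_step_um2 = 0.5
bvf_min = 0.004
bvf_max = 0.009
bvf_step = 0.001

[monte_carlo]
n_photons = 100000
n_wavelengths = 27
weight_threshold = 1e-4
roulette_survival = 0.1

[pipeline]
denoise_sigma = 0.5
homomorphic_sigma = 15.0
saturation_low_percent = 1.0
saturation_high_percent = 1.0
glare_co_percentile = 99.5
glare_cross_percentile = 0.5
glare_dilation_radius = 2

[collagen]
window_px = 33

[phantom]
full_scale_dn = 4095
read_noise_dn = 2.0
full_well_electrons = 10000
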