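"""SHG collagen analysis on synthetic fiber fields.

Renders fiber images with von Mises-distributed axial orientations of
known concentration kappa and recovers the 2D directional variance
(0 = perfectly aligned, 1 = random) and collagen area fraction.  In
peritoneal lesions, malignant tissue shows *lower* variance (more
aligned) and lower collagen fraction than benign tissue.
"""

from pelkit import FiberSpec, analyze_fiber_image, area_fraction, render_fibers
from pelkit.collagen import directional_variance

print("kappa   true-variance   measured   area-fraction")
for kappa in (0.5, 2.0, 8.0):
    image, true_var = render_fibers(FiberSpec(kappa=kappa, seed=0))
    field = analyze_fiber_image(image)
    measured = directional_variance(field.orientation[field.fiber_mask])
    frac = area_fraction(field.fiber_mask)
    print(f"{kappa:5.1f}   {true_var:10.3f}     {measured:8.3f}   {frac:10.3f}")

print(
    "\nhigher kappa = more aligned fibers = lower directional variance; "
    "the estimator tracks the analytic circular variance of the sampled "
    "angles to within a few hundredths."
)
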