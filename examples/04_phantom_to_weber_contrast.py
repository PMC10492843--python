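"""End-to-end phantom analysis: frames -> WLL/PEL/mPEL -> Weber contrast.

Renders a synthetic phantom whose lesion has a higher scattering power
than the background (the malignant-like condition), runs the frame
pre-processing chain with glare exclusion, and quantifies the lesion by
Weber contrast under each modality.  The polarization-gated modalities
suppress the depolarized deep background, so their contrast exceeds the
white-light (WLL) contrast.
"""

import numpy as np

from pelkit import PhantomSpec, fit_mpel, render_phantom, run_frame
from pelkit.roi import contrast_table
from pelkit.synthetic import Ellipse, load_packaged_lut

lut = load_packaged_lut()
spec = PhantomSpec(
    noise=True,
    vignette_ratio=2.0,
    glare=(Ellipse(20.0, 75.0, 5.0, 7.0),),
    seed=7,
)
pair, truth = render_phantom(spec, lut)
derived = run_frame(pair.normalized(), coefficients=fit_mpel(lut))

rois = truth["lesion_mask"].astype(int)
table = contrast_table(
    {"WLL": derived.wll, "PEL": derived.pel, "mPEL": derived.mpel},
    rois,
    excluded_mask=~derived.valid_mask,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
print(
    "\nC_W = (I_lesion - I_background) / I_background; PEL contrast "
    "exceeds WLL because the uniform deep signal cancels in the "
    "polarization difference.  mPEL contrast is positive but small on the "
    "Weber scale: mPEL is an affine map with a large intercept, so its "
    "class separation shows in the mean values rather than the ratio."
)
print(f"glare pixels excluded: {(~derived.valid_mask).sum()}")
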