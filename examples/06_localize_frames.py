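"""Render camera frames from known emitters and localize them back.

Each emitter becomes a pixel-integrated 2D Gaussian (130 nm PSF sigma on
100 nm pixels); the localizer band-passes every frame, picks local maxima
above a noise-scaled threshold, and fits each candidate with an elliptical
2D Gaussian. The round-trip error measures the localization accuracy.
"""

import numpy as np
import pandas as pd

from smdmap import localize_stack, render_frames

rng = np.random.default_rng(6)
truth = pd.DataFrame(
    [(f, x, y) for f in (1, 2)
     for x, y in rng.uniform(2000, 18_000, size=(10, 2))],
    columns=["frame", "x_nm", "y_nm"])

stack = render_frames(truth, psf_sigma_nm=130.0, photons_per_spot=1000.0,
                      fov_nm=20_000.0, offset=100.0, shot_noise=True,
                      read_noise=2.0, rng=rng)
locs = localize_stack(stack, threshold_sd=4.0)

errors = [np.min(np.hypot(truth.x_nm - r.x_nm, truth.y_nm - r.y_nm))
          for _, r in locs.iterrows()]
print(f"emitters: {len(truth)}, localized: {len(locs)}")
print(f"median error {np.median(errors):.1f} nm, max {max(errors):.1f} nm")
print("With 1000 photons on a 100 nm-pixel camera the fit reaches ~5-10 nm")
print("precision; detections near other emitters or frame edges are")
print("dropped rather than risk biased fits.")
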