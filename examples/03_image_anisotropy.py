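"""Image-route anisotropy: render filaments, then measure them back.

Rasterizes a parallel filament array into a synthetic fluorescence
image (Gaussian PSF + Poisson noise) and quantifies it with the
intensity-gradient nematic tensor, comparing against the segment-route
order parameter.
"""

import numpy as np

from mtconfine.quantify import (nematic_tensor_image, parallel_array,
                                render_image, s2_order)

rng = np.random.default_rng(3)
segs = parallel_array(25.0, 40, length=12.0, rng=rng)
seg_res = s2_order(segs)

clean = render_image(segments=segs)
noisy = render_image(segments=segs, noise=2000.0, rng=rng)

for label, img in (("noise-free", clean), ("with shot noise", noisy)):
    r = nematic_tensor_image(img)
    print(f"{label:16s} image angle = {r.angle:+.2f} deg, "
          f"anisotropy = {r.anisotropy:.3f}")
print(f"{'segment route':16s} ThetaS2    = {seg_res.theta_s2:+.2f} deg, "
      f"S2         = {seg_res.s2:.3f}")
print("Both routes should agree on the angle to within a couple of "
      "degrees; the PSF damps image anisotropy slightly and shot noise "
      "damps it further (gradients of noise point in all directions).")
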