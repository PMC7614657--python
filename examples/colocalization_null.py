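"""Pearson colocalization with the 4-direction pixel-shift null.

Compares a pair of colocalized punctate channels against an independent
pair, inside a nuclear mask, using the randomization null obtained by
shifting the channels 40 px in each cardinal direction.
"""

import numpy as np
from scipy import ndimage

from rtqibc import shift_randomized_null

rng = np.random.default_rng(0)
yy, xx = np.mgrid[0:160, 0:160]
mask = (yy - 80) ** 2 + (xx - 80) ** 2 <= 70**2

foci = ndimage.gaussian_filter((rng.random((160, 160)) < 0.004).astype(float), 1.5)
partner = foci + 0.05 * rng.normal(size=foci.shape)          # colocalized
independent = ndimage.gaussian_filter((rng.random((160, 160)) < 0.004).astype(float), 1.5)

co = shift_randomized_null(foci, partner, mask, shift_px=40)
indep = shift_randomized_null(foci, independent, mask, shift_px=40)

print(f"colocalized pair:  r = {co.pearson_r:+.3f}, shift null = {co.null_r_mean:+.3f}")
print(f"independent pair:  r = {indep.pearson_r:+.3f}, shift null = {indep.null_r_mean:+.3f}")
print("A genuine spatial association shows r far above its own shift null;")
print("independent channels give r and null both near zero.")
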