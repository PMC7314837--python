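"""Measure a known displacement field by subset image correlation.

Renders a fluorescent-particle image pair deformed by a smooth 2-pixel warp
and recovers the field with 32 px subsets at 8 px spacing (the particle-image
parameters used for traction microscopy).
"""
import numpy as np

import islandmech as im
from islandmech.fields import GriddedVectorField
from islandmech.synthetic import render_speckle_pair

n, px = 256, 0.65
x = np.arange(n) * px
X, Y = np.meshgrid(x, x)
L = n * px
amp = 2 * px                      # 2-pixel amplitude
truth = GriddedVectorField(x, x, amp * np.sin(2 * np.pi * X / L),
                           amp * np.cos(2 * np.pi * Y / L), units="um")

reference, deformed = render_speckle_pair(truth, seed=8)
field = im.correlate_pair(reference.data, deformed.data,
                          subset_size=32, spacing=8, pixel_size=px,
                          n_passes=2)

gu, gv = truth.sample(*np.meshgrid(field.x, field.y))
rms_px = np.sqrt(np.nanmean((field.u - gu) ** 2 + (field.v - gv) ** 2)) / px
print(f"measured {field.u.size} displacement vectors on an 8 px grid")
print(f"RMS error vs ground truth: {rms_px:.3f} px "
      "(subset matching resolves a few hundredths of a pixel)")
print(f"worst correlation quality: {np.nanmin(field.quality):.3f} "
      "(1 = perfect match)")
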