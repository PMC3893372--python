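"""Pattern spectrum of a cell mask by morphological granulometry.

Opens a binary mask with growing disk structuring elements; the area
removed at each size is the mask's morphological size distribution. Two
fields with grain radius 6 vs 5 px show the downward mode shift that a
population of smaller cells produces.
"""

import numpy as np

from fcdmap import DiskGrainSpec, granulometry, simulate_boolean_field

sizes = np.arange(0.0, 13.0)  # disk radii, px
for label, radius in (("radius-6 grains", 6.0), ("radius-5 grains", 5.0)):
    _, truth = simulate_boolean_field(
        0.003, DiskGrainSpec(radius), (600, 600), noise_sd=0.0, seed=2
    )
    mask = truth.render_mask()
    ps = granulometry(mask, sizes)
    bars = " ".join(f"{a:7.0f}" for a in ps.areas)
    print(f"{label}: mode at size {ps.mode_size:.0f}")
    print(f"  spectrum (px^2 per size bin): {bars}")
    assert ps.total_area == mask.sum()  # the spectrum is complete
# The radius-5 field's spectrum peaks one bin lower: a downward shift of
# the mode of the size distribution, with total area conserved.
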