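"""Detect an implanted focal thinning against a matched control section.

Builds a case/control pair of gyral ribbon phantoms (sinusoidal spine,
~1.5 mm cortex); the case carries a 6 mm focus where the cortex is
thinned to 70%. The control slide's thickness distribution defines
skew-adjusted (medcouple) fences; case midline runs below the lower
fence are flagged as candidate dysplasias.
"""

import numpy as np

from fcdmap import (
    adjusted_fences,
    flag_thin_regions,
    make_thickness_pair,
    midline_profile,
    rasterize_ribbon,
    solve_laplace,
)

case, control = make_thickness_pair(seed=4, focus_multiplier=0.7, focus_length=6000.0)
print("implanted focus (um):", [f"{s0:.0f}..{s1:.0f} x{m}" for s0, s1, m in case.foci])


def profile(phantom):
    field = solve_laplace(rasterize_ribbon(phantom.contour_pair))
    return midline_profile(field, sample_step=200.0, trim=1000.0)


p_case, p_ctrl = profile(case), profile(control)
fences = adjusted_fences(p_ctrl.t)
print(f"control: median t {fences.q2:.0f} um, medcouple {fences.medcouple:+.3f}, "
      f"lower fence {fences.lower_fence:.0f} um")

regions = flag_thin_regions(p_case, fences, min_len=1000.0)
truth = case.in_focus(p_case.points)
flagged = np.zeros(len(p_case), bool)
for r in regions:
    sel = (p_case.arc_s >= r.s_start) & (p_case.arc_s <= r.s_end)
    flagged |= sel
    # midline arc runs in its own direction; report in spine coordinates
    spine_s = case.project_to_spine(p_case.points[sel])
    print(f"flagged: spine {spine_s.min():.0f}..{spine_s.max():.0f} um "
          f"(mean t {r.mean_t:.0f} um, mean curvature {r.mean_kappa:+.2f}/mm)")
jac = (truth & flagged).sum() / max((truth | flagged).sum(), 1)
print(f"overlap with implanted focus (Jaccard): {jac:.2f}")
# A Jaccard near 1 means the flagged interval coincides with the thinning
# that was actually implanted in the phantom.
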