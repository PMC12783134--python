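"""Scattered-light orientation analysis: peaks → pairs → orientation map.

Per pixel, the azimuthal intensity profile is searched for circular peaks
(prominence ≥ 8% of the profile amplitude).  Peaks roughly 180° apart are
paired; the pair mid-position, plus 90°, would be the scattering direction
— equivalently the mid-position itself gives the fibre orientation because
scattering is perpendicular to the fibre.  A lone unpaired peak also maps
to a fibre orientation via the +90° rule.  Out-of-plane tilt shows up as a
peak-pair separation below 180°.
"""

import numpy as np

from fibremap import (
    PhantomSpec,
    compute_fom,
    generate_phantom,
    make_schedule,
    peak_distance_map,
    simulate_comsli_stack,
    smallest_resolved_crossing,
)

# A fold phantom: 20° band, 110° band, crossing in the middle; the lower
# half of both bands is tilted out of plane by 40°.
spec = PhantomSpec(24, 24)
spec.add_band((2, 12, 2, 16), delta_deg=20.0)
spec.add_band((2, 12, 8, 22), delta_deg=110.0)
spec.add_band((12, 22, 2, 16), delta_deg=20.0, alpha_deg=40.0)
spec.add_band((12, 22, 8, 22), delta_deg=110.0, alpha_deg=40.0)
gt = generate_phantom(spec, seed=0)

stack = simulate_comsli_stack(gt, make_schedule(15.0))
fom = compute_fom(stack)

print("orientation counts per region:")
print(f"  left band    : {sorted(set(fom.n_orientations()[4, 2:8]))}")
print(f"  overlap      : {sorted(set(fom.n_orientations()[4, 8:16]))}")
print(f"  background   : {sorted(set(fom.n_orientations()[0, :]))}")

# With a 15° azimuth grid and 8°-wide peaks, off-grid orientations carry a
# sub-grid interpolation bias of up to ~2.5°.
print("\nrecovered orientations (truth 20° and 110°):")
print(f"  left band pixel (4, 5)  : {fom.orientations[4, 5, 0]:.2f}°")
ov = np.sort(fom.orientations[4, 12, :2])
print(f"  overlap pixel  (4, 12)  : {ov[0]:.2f}°, {ov[1]:.2f}°")

# Tilt signature: the peak-pair distance drops from 180° by half the tilt.
dist = peak_distance_map(fom)
print("\npeak-pair distances (tilt reduces them below 180°):")
print(f"  flat rows   : {np.nanmean(dist[2:12]):.2f}°  (expected 180°)")
print(f"  tilted rows : {np.nanmean(dist[12:22]):.2f}°  (expected 180 − 0.5·40 = 160°)")

# How close can two bundles cross and still be separated at 15° sampling?
chi = smallest_resolved_crossing()
print(f"\nsmallest resolved crossing angle in the pinned sweep: {chi:.0f}°")
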