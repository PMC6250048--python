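"""Why the cube-minus-sphere compensator flattens the residual range.

For any ray parallel to the beam axis inside the sphere silhouette, the
compensator thickness plus the sphere chord is the constant cube side,
so every proton leaves the object with (ideally) the same residual
range.  This narrows the telescope depth the scan has to cover.
"""

import numpy as np

from protonct import MATERIALS, wepl_line_integral
from protonct.phantom import PhantomModel, SphereBody, default_compensator

sphere = PhantomModel(SphereBody(np.zeros(3), 75.0, MATERIALS["pmma"]))
comp = default_compensator()

print("lateral offset [mm]   sphere-only WEPL   compensated WEPL")
for offset in [0.0, 10.0, 20.0, 30.0, 36.0]:
    alone = wepl_line_integral([offset, 0, -400], [offset, 0, 400], sphere)
    both = wepl_line_integral([offset, 0, -400], [offset, 0, 400], sphere, comp)
    print(f"{offset:8.0f} {alone:18.1f} {both:18.1f}")

print("\nWithout the compensator the WEPL varies by tens of mm across the")
print("field; with it every ray sees 87.0 mm (75 mm of PMMA), so all")
print("protons stop within a few layers of each other in the telescope.")
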