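"""Segment nuclei and quantify deformation: minor diameter and NII.

Confinement squeezes nuclei: the fitted-ellipse minor diameter drops and
the nuclear irregularity index NII = (1-circularity) + (1-solidity)
rises with elongation and contour concavity.
"""

import numpy as np
from skimage.draw import disk, ellipse

from trackmech import segment_nuclei

PS = 0.32  # µm/px

img = np.zeros((256, 256))
rr, cc = disk((60, 60), 5.0 / PS, shape=img.shape)       # round nucleus
img[rr, cc] = 1.0
rr, cc = ellipse(60, 170, 4.0 / PS, 9.0 / PS, shape=img.shape)  # confined
img[rr, cc] = 1.0
rr, cc = ellipse(180, 110, 2.5 / PS, 12.0 / PS, shape=img.shape)  # squeezed
img[rr, cc] = 1.0

# wider watershed-seed separation: strongly elongated nuclei would
# otherwise be split into two objects
result = segment_nuclei(img, pixel_size=PS, min_separation_um=12.0)
print(f"{result.count} nuclei segmented, {len(result.excluded)} excluded")
for s in sorted(result.shapes, key=lambda s: -s.minor_um):
    print(f"  label {s.label}: minor {s.minor_um:5.2f} µm, "
          f"major {s.major_um:5.2f} µm, circularity {s.circularity:.3f}, "
          f"NII {s.nii:.3f}")
print("-> the round nucleus scores NII ~ 0; narrowing the minor axis from")
print("   10 to 5 µm (and the aspect to ~5:1) raises NII several-fold,")
print("   the signature of nuclear deformation in confining tracks.")
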