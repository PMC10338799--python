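"""Build the synthetic pelvis phantom and inspect its organs.

The phantom is a 96x96x40 CT-like volume (1 x 1 x 2.5 mm voxels) holding a
high-contrast bladder-like ellipsoid, a low-contrast prostate-like
ellipsoid and a bent rectum-like tube, each with an exact ground-truth
mask.  Mean Sobel gradient on each organ's surface shows the contrast
ordering the generator exploits: low-contrast surfaces are where simulated
delineation uncertainty will concentrate.
"""

import numpy as np

import ducsim as ds
from ducsim.generator import sobel_gradient

ct, masks = ds.make_phantom(ds.pelvis_spec(seed=1))
print(f"volume shape {ct.shape}, spacing {ct.spacing} mm")
for roi, mask in masks.items():
    vol_ml = mask.voxels.sum() * np.prod(ct.spacing) / 1000.0
    grads = []
    for surf in ds.surfaces_for_roi(mask, on_too_small="skip"):
        g = sobel_gradient(ct.axial_slice(surf.z), ct.spacing[:2])
        grads.extend(g[surf.L[:, 0], surf.L[:, 1]])
    print(
        f"{roi:>9}: {mask.voxels.sum():6d} voxels ({vol_ml:5.1f} ml), "
        f"mean surface gradient {np.mean(grads):6.1f} HU/mm, "
        f"contrast response {ds.contrast_response(float(np.mean(grads))):.2f}"
    )
print("Higher surface gradient -> lower contrast response -> smaller "
      "simulated delineation uncertainty on that organ.")
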