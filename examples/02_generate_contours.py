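"""Generate alternative prostate contours at two variation levels.

The generator displaces each boundary voxel by D = W * TG * F~ct along its
outward normal: Gaussian variation W scaled by C, a truncated-Gaussian
localization TG anchored at the lowest-gradient surface region, and the
contrast response F~ct.  Larger C means larger deformations; the surface
DSC (3 mm tolerance) and 95th-percentile Hausdorff distance against the
input contour quantify how far each generated contour strays.
"""

import ducsim as ds
from ducsim.phantom import WORKING_SMOOTHING_SIGMA

ct, masks = ds.make_phantom(ds.pelvis_spec(seed=1))
prostate = masks["prostate"]

for C in (50, 200):
    for seed in (0, 1):
        params = ds.DUParams(C=C, seed=seed,
                             smoothing_sigma=WORKING_SMOOTHING_SIGMA)
        generated = ds.generate_du_contour(ct, prostate, params)
        cmp_ = ds.compare_masks(prostate, generated, tolerance_mm=3.0)
        print(
            f"C={C:3d} seed={seed}: surface DSC(3mm)={cmp_.surface_dsc:.3f}  "
            f"HD95={cmp_.hd95:.2f} mm  volumetric DSC={cmp_.volumetric_dsc:.3f}"
        )
print("Surface DSC 1.0 means every boundary point stayed within 3 mm of "
      "the clinical contour; rising HD95 tracks the growing deformation.")
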