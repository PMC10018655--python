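"""Contrast-to-noise ratio and vessel line profiles across reconstructions.

Simulates the same anatomy under a sharp-kernel/high-noise reconstruction
and a smooth-kernel/low-noise one, places the aorta and mediastinal-fat
ROIs, and prints per-patient CNR with the paired-difference analysis, plus
the peak height of a profile over a 2 mm vessel (a resolution probe).
"""

import numpy as np

from ctiq import (NoiseModel, ROISpec, apply_noise, cnr,
                  cnr_difference_analysis, default_chest_phantom,
                  generate_phantom_stack, line_profile, roi_stats)
from ctiq.noise import apply_resolution_blur


def main():
    phantom = generate_phantom_stack(default_chest_phantom(n_slices=1))
    sp = phantom.pixel_spacing
    roi_aorta = ROISpec(center=(0.0, 10.0), diameter=15.0)
    roi_fat = ROISpec(center=(0.0, -30.0), diameter=15.0)

    arms = {
        "sharp_high_noise": (NoiseModel("sharp_kernel", sigma_ref=40.0), 0.4),
        "smooth_low_noise": (NoiseModel("smooth_kernel", sigma_ref=15.0), 0.8),
    }
    cnrs = {}
    for name, (noise, blur_mm) in arms.items():
        anatomy = apply_resolution_blur(phantom, blur_mm)
        values = []
        for patient in range(10):
            img = apply_noise(anatomy, noise, seed=100 + patient).voxels[0]
            values.append(cnr(roi_stats(img, roi_aorta, sp),
                              roi_stats(img, roi_fat, sp)))
        cnrs[name] = np.array(values)
        prof = line_profile(anatomy.voxels[0], (-76.0, -40.0), (-64.0, -40.0),
                            sp / 2.0, sp)
        print(f"{name}: mean CNR {cnrs[name].mean():5.2f} "
              f"(per-patient SD {cnrs[name].std(ddof=1):.2f}), "
              f"vessel profile peak {prof.values.max():7.1f} HU")

    comp = cnr_difference_analysis(cnrs["smooth_low_noise"],
                                   cnrs["sharp_high_noise"])
    print(f"\npaired difference (smooth - sharp): mean {comp.mean_diff:.2f}, "
          f"SEM {comp.sem:.2f}, t = {comp.t_statistic:.2f}, p = {comp.p_value:.2e}")
    print("Lower noise lifts the CNR for every patient (positive difference,"
          "\nsmall p); the sharper kernel keeps a higher vessel peak.")


if __name__ == "__main__":
    main()
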