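"""Generate a chest phantom at two dose levels and compare power spectra.

Builds the built-in chest phantom, adds sharp-kernel noise at full dose and
at quarter dose, and prints the radially averaged power spectrum in three
frequency bands next to the spectrum of the noiseless anatomy.  The curves
are anatomy + noise: the anatomy contribution is dose-independent, while
the noise contribution (the excess over the anatomy line) scales with
1/dose — quarter dose means double the noise SD and four times the noise
power.
"""

from ctiq import (NoiseModel, apply_noise, default_chest_phantom,
                  examination_ps, generate_phantom_stack, radial_average)

BANDS = ((0.05, 0.15), (0.15, 0.35), (0.35, 0.55))


def band_means(curve):
    out = []
    for lo, hi in BANDS:
        band = (curve.bin_freq >= lo) & (curve.bin_freq < hi)
        out.append(curve.ps[band].mean())
    return out


def main():
    phantom = generate_phantom_stack(default_chest_phantom(n_slices=5))
    print(f"phantom stack: {phantom.shape}, pixel spacing {phantom.pixel_spacing} mm")

    anatomy = band_means(radial_average(examination_ps(phantom)))
    print("\n                      " + "".join(f"{lo:.2f}-{hi:.2f}    " for lo, hi in BANDS)
          + "mm^-1")
    print("anatomy only        " + "".join(f"{v:12.0f}" for v in anatomy) + "  HU^2 mm^2")

    for dose_factor in (1.0, 0.25):
        noise = NoiseModel(radial_shape="sharp_kernel", sigma_ref=40.0,
                           dose_factor=dose_factor)
        stack = apply_noise(phantom, noise, seed=1)
        total = band_means(radial_average(examination_ps(stack)))
        excess = [t - a for t, a in zip(total, anatomy)]
        print(f"dose factor {dose_factor:<4}      "
              + "".join(f"{v:12.0f}" for v in total)
              + f"  (noise SD {noise.target_sd:.0f} HU)")
        print("  excess over anatomy" + "".join(f"{v:11.0f}" for v in excess))

    print("\nThe anatomy line does not move with dose; the excess (the noise"
          "\npower) is ~4x larger at quarter dose in every band, shaped by the"
          "\nband-pass kernel.")


if __name__ == "__main__":
    main()
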