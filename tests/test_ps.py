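import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctiq import (ImageStack, NoiseModel, PS2D, PSCurve1D, apply_noise,
                  cohort_ps, examination_ps, extract_central_rois, mirror_roi,
                  radial_average, roi_power_spectrum)


# ------------------------------------------------------------- ROI tiling

def test_default_tiling_four_central_rois():
    img = np.arange(512 * 512, dtype=float).reshape(512, 512)
    rois = extract_central_rois(img)
    assert len(rois) == 4 and all(r.shape == (64, 64) for r in rois)
    # corners of the central 128x128 window of a 512 image: rows/cols 192..320
    assert rois[0][0, 0] == img[192, 192]
    assert rois[1][0, 0] == img[192, 256]
    assert rois[2][0, 0] == img[256, 192]
    assert rois[3][-1, -1] == img[319, 319]


def test_tiling_window_equal_to_image_and_degenerate():
    img = np.random.default_rng(0).normal(size=(128, 128))
    rois = extract_central_rois(img)
    assert len(rois) == 4
    assert np.array_equal(np.block([[rois[0], rois[1]], [rois[2], rois[3]]]), img)
    assert len(extract_central_rois(img, roi_size=128, central_size=128)) == 1
    with pytest.raises(ValueError):
        extract_central_rois(img[:64], roi_size=64, central_size=128)


# ------------------------------------------------------------- mirroring

def test_mirror_roi_reflection_definition():
    roi = np.array([[1.0, 2.0], [3.0, 4.0]])
    expected = np.array([[1, 2, 2, 1], [3, 4, 4, 3], [3, 4, 4, 3], [1, 2, 2, 1]],
                        dtype=float)
    assert np.array_equal(mirror_roi(roi), expected)


@settings(max_examples=25, derandomize=True)
@given(arrays(np.float64, (6, 6), elements=st.floats(-1000, 1000)))
def test_mirror_roi_even_symmetry(roi):
    block = mirror_roi(roi)
    assert block.shape == (12, 12)
    assert np.array_equal(block, block[:, ::-1])
    assert np.array_equal(block, block[::-1, :])


def test_mirror_constant_roi():
    assert np.array_equal(mirror_roi(np.full((3, 3), 7.0)), np.full((6, 6), 7.0))


# ------------------------------------------------------- per-block spectrum

def test_constant_block_has_zero_spectrum():
    ps = roi_power_spectrum(np.full((8, 8), 123.0), pixel_spacing=0.75)
    assert np.allclose(ps.values, 0.0)


def test_white_noise_ps_level_matches_sigma2_delta2():
    """Averaged over many blocks, the PS of white noise is flat at
    sigma^2 * spacing^2 (checked via the direct summation oracle)."""
    rng = np.random.default_rng(4)
    sigma, spacing = 5.0, 0.8
    acc = None
    for _ in range(100):
        block = rng.normal(0.0, sigma, (32, 32))
        ps = roi_power_spectrum(block, spacing)
        acc = ps.values if acc is None else acc + ps.values
    mean_ps = acc / 100
    grid = mean_ps[mean_ps > 0]  # all non-DC bins
    assert abs(grid.mean() - sigma ** 2 * spacing ** 2) / (sigma ** 2 * spacing ** 2) < 0.05


def test_mirrored_block_dft_is_cosine_up_to_half_sample_phase():
    """Edge-duplicating (half-sample symmetric) mirroring makes the DFT a
    cosine transform times the linear phase exp(i*pi*(kx+ky)/N); removing
    that phase leaves a real transform, and the Nyquist row/column
    coefficients vanish identically."""
    rng = np.random.default_rng(5)
    block = mirror_roi(rng.normal(size=(16, 16)))
    n = block.shape[0]
    dft = np.fft.fft2(block - block.mean())
    k = np.fft.fftfreq(n) * n
    phase = np.exp(-1j * np.pi * (k[:, None] + k[None, :]) / n)
    dephased = dft * phase
    assert np.max(np.abs(dephased.imag)) < 1e-9 * np.max(np.abs(dephased.real))
    assert np.allclose(dft[n // 2, :], 0.0, atol=1e-9)
    assert np.allclose(dft[:, n // 2], 0.0, atol=1e-9)


def test_parseval_identity_per_block_exact():
    rng = np.random.default_rng(6)
    block = mirror_roi(rng.normal(0.0, 30.0, (64, 64)))
    ps = roi_power_spectrum(block, 0.75)
    assert np.isclose(ps.integral(), block.var(), rtol=1e-12)


# ------------------------------------------------------- examination level

def test_single_slice_exam_is_mean_of_roi_spectra(flat_stack):
    noisy = apply_noise(flat_stack, NoiseModel(sigma_ref=10.0), seed=1)
    single = ImageStack(noisy.voxels[:1], pixel_spacing=noisy.pixel_spacing)
    exam = examination_ps(single)
    manual = np.mean([roi_power_spectrum(mirror_roi(r), 0.75).values
                      for r in extract_central_rois(single.voxels[0])], axis=0)
    assert np.allclose(exam.values, manual)
    assert exam.n_rois_averaged == 4 and exam.n_slices_averaged == 1


def test_exam_ps_invariant_under_slice_duplication_and_order(flat_stack):
    noisy = apply_noise(flat_stack, NoiseModel(sigma_ref=10.0), seed=2)
    base = examination_ps(noisy)
    doubled = ImageStack(np.concatenate([noisy.voxels, noisy.voxels]),
                         pixel_spacing=noisy.pixel_spacing)
    permuted = ImageStack(noisy.voxels[::-1].copy(),
                          pixel_spacing=noisy.pixel_spacing)
    assert np.allclose(examination_ps(doubled).values, base.values)
    assert np.allclose(examination_ps(permuted).values, base.values)


def test_ps_scales_with_noise_variance():
    """Doubling the noise SD quadruples the PS at non-DC bins."""
    flat = ImageStack(np.zeros((20, 128, 128)), pixel_spacing=0.75)
    ps1 = examination_ps(apply_noise(flat, NoiseModel(radial_shape="smooth_kernel",
                                                      sigma_ref=10.0), seed=3))
    ps2 = examination_ps(apply_noise(flat, NoiseModel(radial_shape="smooth_kernel",
                                                      sigma_ref=20.0), seed=4))
    c1, c2 = radial_average(ps1), radial_average(ps2)
    band = (c1.bin_freq > 0.05) & (c1.bin_freq < 0.4)
    ratio = c2.ps[band] / c1.ps[band]
    assert abs(np.median(ratio) - 4.0) < 0.4


def test_monotone_dose_ordering():
    """Lower dose -> pointwise larger PS above 0.1 mm^-1."""
    flat = ImageStack(np.zeros((20, 128, 128)), pixel_spacing=0.75)
    model = dict(radial_shape="smooth_kernel", sigma_ref=15.0)
    hi = examination_ps(apply_noise(flat, NoiseModel(dose_factor=1.0, **model), seed=5))
    lo = examination_ps(apply_noise(flat, NoiseModel(dose_factor=0.25, **model), seed=6))
    ch, cl = radial_average(hi), radial_average(lo)
    # up to the axis Nyquist; the lone corner-diagonal bin is structurally
    # zero for half-sample-symmetric blocks and carries no noise power
    band = (ch.bin_freq > 0.1) & (ch.bin_freq <= 1.0 / (2 * 0.75))
    assert np.all(cl.ps[band] > ch.ps[band])


def test_empty_stack_rejected():
    with pytest.raises(ValueError):
        examination_ps(ImageStack(np.zeros((0, 128, 128)), pixel_spacing=1.0))


# ----------------------------------------------------------- radial average

def _radial_average_oracle(values, freq, df):
    """Exhaustive enumeration over grid samples, independent binning loop."""
    bins = {}
    n = len(freq)
    for i in range(n):
        for j in range(n):
            fr = np.hypot(freq[i], freq[j])
            if fr == 0:
                continue
            k = int(np.floor(fr / df + 1e-9))
            bins.setdefault(k, []).append((fr, values[i, j]))
    out_f, out_p = [], []
    for k in sorted(bins):
        fs, vs = zip(*bins[k])
        out_f.append(np.mean(fs))
        out_p.append(np.mean(vs))
    return np.array(out_f), np.array(out_p)


@pytest.mark.parametrize("side", [8, 16])
def test_radial_average_matches_enumeration_oracle(side):
    rng = np.random.default_rng(side)
    freq = np.fft.fftshift(np.fft.fftfreq(side, d=1.0))
    u = freq[None, :] * np.ones((side, side))
    values = u ** 2 + 0.1 * rng.random((side, side))  # anisotropic
    ps2d = PS2D(values=values, freq=freq, freq_spacing=1.0 / side)
    curve = radial_average(ps2d)
    of, op = _radial_average_oracle(values, freq, 1.0 / side)
    assert np.allclose(curve.bin_freq, of)
    assert np.allclose(curve.ps, op)


def test_radial_average_of_uniform_grid_is_one():
    side = 16
    freq = np.fft.fftshift(np.fft.fftfreq(side, d=1.0))
    ps2d = PS2D(values=np.ones((side, side)), freq=freq, freq_spacing=1.0 / side)
    curve = radial_average(ps2d)
    assert np.allclose(curve.ps, 1.0)


def test_radial_average_reproduces_isotropic_bin_constants():
    side = 16
    df = 1.0 / side
    freq = np.fft.fftshift(np.fft.fftfreq(side, d=1.0))
    fr = np.hypot(freq[:, None], freq[None, :])
    bin_idx = np.floor(fr / df + 1e-9).astype(int)
    values = (bin_idx + 1).astype(float)  # piecewise constant per bin
    curve = radial_average(PS2D(values=values, freq=freq, freq_spacing=df))
    expected = np.array(sorted(set(bin_idx[fr > 0] + 1)), dtype=float)
    assert np.allclose(curve.ps, expected)


# ----------------------------------------------------------------- cohort

def test_cohort_identical_curves_zero_se():
    curve = PSCurve1D(bin_freq=np.array([0.1, 0.2]), ps=np.array([4.0, 2.0]))
    pooled = cohort_ps([curve, curve, curve])
    assert np.allclose(pooled.ps, curve.ps)
    assert np.allclose(pooled.relative_se, 0.0)
    assert pooled.n_patients == 3


def test_cohort_two_curves_hand_computed_se():
    c = 3.0
    a = PSCurve1D(bin_freq=np.array([0.1, 0.2]), ps=np.array([c, c]))
    b = PSCurve1D(bin_freq=np.array([0.1, 0.2]), ps=np.array([3 * c, 3 * c]))
    pooled = cohort_ps([a, b])
    # mean 2c, SD sqrt(2)c, SE = SD/sqrt(2) = c, relative SE = c/2c = 50%
    assert np.allclose(pooled.ps, 2 * c)
    assert np.allclose(pooled.relative_se, 50.0)


def test_cohort_rejects_mismatched_bins():
    a = PSCurve1D(bin_freq=np.array([0.1, 0.2]), ps=np.array([1.0, 1.0]))
    b = PSCurve1D(bin_freq=np.array([0.1, 0.3]), ps=np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        cohort_ps([a, b])
    with pytest.raises(ValueError):
        cohort_ps([a])


def test_cohort_relative_se_order_of_magnitude():
    """25 matched-noise patients give a relative SE of a few percent."""
    flat = ImageStack(np.zeros((10, 128, 128)), pixel_spacing=0.75)
    model = NoiseModel(radial_shape="smooth_kernel", sigma_ref=20.0)
    curves = [radial_average(examination_ps(apply_noise(flat, model, seed=100 + i)))
              for i in range(25)]
    pooled = cohort_ps(curves)
    band = (pooled.bin_freq > 0.05) & (pooled.bin_freq < 0.5)
    assert np.median(pooled.relative_se[band]) < 10.0
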