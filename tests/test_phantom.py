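"""Tests for the digital flow phantom: curves, rendering, noise."""

import numpy as np
import pytest

from coapvc.exceptions import GeometryError, InvalidParameterError
from coapvc.phantom import (
    InjectionModel,
    NoiseModel,
    PhantomSpec,
    TubeSpec,
    add_noise,
    generate_input_function,
    generate_vein_curve,
    render_dynamic_image,
)


def fine_auc(tac):
    return float(np.sum(tac.values * tac.frame_duration))


# ----------------------------------------------------------------------
# input function
# ----------------------------------------------------------------------
def test_mass_balance_flow_times_auc_equals_delivered_activity(arterial, injection):
    delivered_kbq = injection.injected_activity_mbq * 1000.0
    assert fine_auc(arterial) * 10.0 == pytest.approx(delivered_kbq, rel=1e-3)


def test_chamber_to_zero_limit_is_boxcar():
    inj = InjectionModel(chamber_volume_ml=0.0)
    tac = generate_input_function(inj, 10.0)
    plateau = 22000.0 / (50.0 * 10.0)
    inside = tac.midpoints < 50.0
    np.testing.assert_allclose(tac.values[inside], plateau)
    np.testing.assert_allclose(tac.values[~inside], 0.0)


def test_peak_height_matches_closed_form():
    # chamber 100 mL, flow 10 mL/s: peak = A/(T*Q) * (1 - exp(-Q*T/V))
    inj = InjectionModel(chamber_volume_ml=100.0)
    tac = generate_input_function(inj, 10.0)
    expected = 22000.0 / (50.0 * 10.0) * (1.0 - np.exp(-10.0 * 50.0 / 100.0))
    assert tac.values.max() == pytest.approx(expected, rel=1e-3)


def test_input_function_parameter_validation():
    with pytest.raises(InvalidParameterError):
        generate_input_function(InjectionModel(), flow_rate_ml_s=0.0)
    with pytest.raises(InvalidParameterError):
        InjectionModel(injected_activity_mbq=-1.0)


# ----------------------------------------------------------------------
# vein curve
# ----------------------------------------------------------------------
def test_vein_zero_buffer_is_identity(arterial):
    vein = generate_vein_curve(arterial, 0.0, 10.0)
    np.testing.assert_array_equal(vein.values, arterial.values)


def test_vein_preserves_auc_and_lowers_peak(arterial):
    vein = generate_vein_curve(arterial, 500.0, 10.0)
    assert fine_auc(vein) == pytest.approx(fine_auc(arterial), rel=1e-3)
    assert vein.values.max() < arterial.values.max()


def test_vein_matches_discrete_convolution_oracle(arterial):
    """Exact-for-linear filter vs brute-force fine-step convolution."""
    v, q = 500.0, 10.0
    vein = generate_vein_curve(arterial, v, q)
    dt = arterial.frame_duration[0]
    t = np.arange(0, 6 * v / q, dt)
    kernel = (q / v) * np.exp(-q * t / v) * dt
    oracle = np.convolve(arterial.values, kernel)[: arterial.n_frames]
    peak_i, peak_o = np.argmax(vein.values), np.argmax(oracle)
    assert abs(int(peak_i) - int(peak_o)) <= 1
    assert vein.values.max() == pytest.approx(oracle.max(), rel=0.01)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------
def test_no_blur_no_noise_conservation_identity():
    """psf -> 0: total tube activity over rasterized volume equals truth
    exactly; the plain ROI mean converges to truth as voxels shrink."""
    from coapvc.rois import disc_occupancy

    def run(voxel):
        spec = PhantomSpec(
            tube_bank=(TubeSpec(25.4, (40.0, 40.0), "artery"),),
            fov_mm=(80.0, 80.0, 8 * voxel), voxel_size_mm=voxel,
            psf_fwhm_mm=0.0, background_activity=0.0)
        image, truth = render_dynamic_image(spec)
        occ = disc_occupancy((40.0, 40.0), 12.7, image.data.shape[:2],
                             (voxel, voxel))
        frame = np.argmax(truth["artery_25.4mm"].values)
        plane = image.data[:, :, 0, frame]
        total_over_volume = plane.sum() / occ.sum()
        mean = (plane * occ).sum() / occ.sum()
        return total_over_volume, mean, truth["artery_25.4mm"].values[frame]

    tot, mean1, true = run(1.0)
    assert tot == pytest.approx(true, rel=1e-6)  # conservation readout exact
    _, mean025, _ = run(0.25)
    # sub-voxel edge bias of the mean readout shrinks with voxel size
    assert abs(mean025 - true) < abs(mean1 - true)
    assert mean025 == pytest.approx(true, rel=0.01)


def test_blur_conserves_total_activity(single_tube_rendered, single_tube_spec):
    """Kernel is normalized and the tube is far from the edge: per-frame
    totals match the unblurred totals within 0.1%."""
    image, truth = single_tube_rendered
    spec = single_tube_spec
    from coapvc.rois import disc_occupancy

    occ = disc_occupancy((50.0, 50.0), 4.75, image.data.shape[:2], (1.0, 1.0))
    nvox_plane = image.data.shape[0] * image.data.shape[1]
    for f in (5, 10):
        expected = (spec.background_activity * (nvox_plane - occ.sum())
                    + truth["artery_9.5mm"].values[f] * occ.sum())
        got = image.data[:, :, 0, f].sum()
        assert got == pytest.approx(expected, rel=1e-3)


def test_small_tube_peak_depressed_by_more_than_half(default_rendered):
    """At 6 mm FWHM the 6.35 mm tube's uncorrected mean peak falls below
    50% of ground truth."""
    from coapvc.rois import extract_tac, rasterize_roi, CylinderROI

    spec, image, truth = default_rendered
    tube = next(t for t in spec.tube_bank if t.label == "artery_6.35mm")
    roi = CylinderROI((*tube.center_xy_mm, 30.0), tube.radius_mm, 20.0)
    tac = extract_tac(image, rasterize_roi(roi, image.grid))
    assert tac.values.max() < 0.5 * truth["artery_6.35mm"].values.max()


def test_uncorrected_peak_recovery_monotone_in_diameter(default_rendered):
    from coapvc.rois import extract_tac, rasterize_roi, CylinderROI

    spec, image, truth = default_rendered
    recoveries = []
    for t in spec.tube_bank:
        if t.role != "artery":
            continue
        roi = CylinderROI((*t.center_xy_mm, 30.0), t.radius_mm, 20.0)
        tac = extract_tac(image, rasterize_roi(roi, image.grid))
        recoveries.append((t.inner_diameter_mm,
                           tac.values.max() / truth[t.label].values.max()))
    recoveries.sort()
    ratios = [r for _, r in recoveries]
    assert all(np.diff(ratios) > 0), f"PVE must worsen as diameter shrinks: {ratios}"


def test_artery_tubes_share_ground_truth(default_rendered):
    spec, _, truth = default_rendered
    curves = [truth[t.label] for t in spec.tube_bank if t.role == "artery"]
    for c in curves[1:]:
        np.testing.assert_array_equal(c.values, curves[0].values)


def test_render_is_pure_function_of_spec():
    spec = PhantomSpec(tube_bank=(TubeSpec(9.5, (50.0, 50.0), "artery"),),
                       fov_mm=(100.0, 100.0, 30.0),
                       noise=NoiseModel(kind="gaussian", scale=0.5), seed=7)
    img1, _ = render_dynamic_image(spec)
    img2, _ = render_dynamic_image(spec)
    np.testing.assert_array_equal(img1.data, img2.data)


def test_tube_margin_and_overlap_validation():
    with pytest.raises(GeometryError):
        PhantomSpec(tube_bank=(TubeSpec(25.4, (14.0, 50.0), "artery"),),
                    fov_mm=(100.0, 100.0, 30.0))
    with pytest.raises(GeometryError):
        PhantomSpec(tube_bank=(TubeSpec(25.4, (50.0, 50.0), "artery"),
                               TubeSpec(25.4, (60.0, 50.0), "artery")),
                    fov_mm=(120.0, 100.0, 30.0))


# ----------------------------------------------------------------------
# noise
# ----------------------------------------------------------------------
def test_noise_none_is_bit_identical_passthrough(single_tube_rendered):
    image, _ = single_tube_rendered
    out = add_noise(image, NoiseModel(kind="none"), seed=1)
    assert out.data is image.data


def test_noise_seeded_determinism(single_tube_rendered):
    image, _ = single_tube_rendered
    a = add_noise(image, NoiseModel(kind="gaussian"), seed=3)
    b = add_noise(image, NoiseModel(kind="gaussian"), seed=3)
    c = add_noise(image, NoiseModel(kind="gaussian"), seed=4)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_noise_sigma_follows_configured_law(single_tube_rendered):
    """Empirical sigma in a uniform background region matches
    scale * sqrt(max(value, floor)/duration) within 5% at n = 1e4."""
    image, _ = single_tube_rendered
    model = NoiseModel(kind="gaussian", scale=2.0, floor=0.1)
    noisy = add_noise(image, model, seed=11)
    # corner region far from the tube: uniform background 1.4
    frame = 5
    region = slice(0, 25)
    resid = (noisy.data[region, region, :, frame]
             - image.data[region, region, :, frame]).ravel()
    assert resid.size >= 10_000
    expected = model.scale * np.sqrt(
        max(image.data[5, 5, 0, frame], model.floor) / image.frame_duration[frame])
    assert np.std(resid) == pytest.approx(expected, rel=0.05)


def test_unknown_noise_model_rejected():
    with pytest.raises(InvalidParameterError):
        NoiseModel(kind="poissonish")


def test_resample_to_scanner_slices(single_tube_rendered):
    """Slab averaging to 3 mm slices preserves z-invariant values and
    scales the z spacing."""
    from coapvc.phantom import resample_slices

    image, _ = single_tube_rendered
    coarse = resample_slices(image, 3.0)
    assert coarse.voxel_size[2] == pytest.approx(3.0)
    assert coarse.data.shape[2] == image.data.shape[2] // 3
    # tubes are z-invariant: slab means equal the source values
    np.testing.assert_allclose(coarse.data[:, :, 0, 5], image.data[:, :, 0, 5],
                               rtol=1e-12)
    assert resample_slices(image, 1.0) is image
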