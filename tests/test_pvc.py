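"""Unit and property tests for the conservation-of-activity corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from coapvc.exceptions import ConfigurationError, GeometryError, InvalidParameterError
from coapvc.pvc import (
    RegionMeasurement,
    coa_correct_artery_vein,
    coa_correct_background,
    coa_correct_simple,
    rc_correct,
    recovery_coefficient_cylinder,
)
from coapvc.tac import TimeActivityCurve

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


def tac(values):
    values = np.atleast_1d(np.asarray(values, float))
    return TimeActivityCurve(np.arange(len(values)) * 20.0,
                             np.full(len(values), 20.0), values)


# ----------------------------------------------------------------------
# algebraic identities
# ----------------------------------------------------------------------
def test_simple_recovers_total_over_true_volume():
    # c_so = A / v_so for any v_so -> corrected = A / v_a
    total = 37.5  # kBq
    for v_so in (2.0, 5.0, 11.0):
        out = coa_correct_simple(total / v_so, v_so, v_a=1.5)
        assert out == pytest.approx(total / 1.5)


def test_simple_identity_when_no_spill_region():
    assert coa_correct_simple(4.2, v_so=1.3, v_a=1.3) == pytest.approx(4.2)


@given(b=st.floats(0, 100), v_a=st.floats(0.1, 10), extra=st.floats(0.01, 50))
@settings(max_examples=200, deadline=None)
def test_background_fixed_point_exact(b, v_a, extra):
    """A pure background field is left untouched, to machine precision."""
    v_so = v_a + extra
    assert coa_correct_background(b, v_so, v_a, b) == pytest.approx(b, abs=1e-9, rel=1e-12)


@given(c=st.floats(-10, 100), v_a=st.floats(0.1, 10), extra=st.floats(0.0, 50))
@settings(max_examples=200, deadline=None)
def test_background_reduces_to_simple_at_zero_background(c, v_a, extra):
    v_so = v_a + extra
    assert coa_correct_background(c, v_so, v_a, 0.0) == pytest.approx(
        coa_correct_simple(c, v_so, v_a), rel=1e-13, abs=1e-13)


def test_artery_vein_reduces_to_background_when_vein_carries_nothing():
    c_so, c_a, c_bkg = tac([5.0, 8.0, 2.0]), tac([4.0, 7.0, 1.5]), tac([1.4, 1.4, 1.4])
    v_a, v_v, v_so = 0.6, 1e-9, 60.0
    m = RegionMeasurement(c_so=c_so, v_so=v_so, v_a=v_a, c_a=c_a, c_bkg=c_bkg,
                          c_v=tac([0.0, 0.0, 0.0]), v_v=v_v)
    res = coa_correct_artery_vein(m)
    expected = coa_correct_background(c_so.values, v_so - v_v, v_a, c_bkg.values)
    np.testing.assert_allclose(res.c_a_corr.values, expected, rtol=1e-9)


def test_artery_vein_symmetry_splits_spill_equally():
    c = tac([6.0, 3.0])
    v_a = v_v = 0.8
    v_so, bkg = 50.0, 1.4
    m = RegionMeasurement(c_so=tac([5.0, 2.5]), v_so=v_so, v_a=v_a, c_a=c,
                          c_bkg=tac([bkg, bkg]), c_v=c, v_v=v_v)
    res = coa_correct_artery_vein(m)
    expected = (np.array([5.0, 2.5]) * v_so - bkg * (v_so - 2 * v_a)) / (2 * v_a)
    np.testing.assert_allclose(res.c_a_corr.values, expected, rtol=1e-12)
    np.testing.assert_allclose(res.c_v_corr.values, expected, rtol=1e-12)


def test_artery_vein_zero_signal_frames_return_zero():
    m = RegionMeasurement(c_so=tac([1.0, 1.0]), v_so=50.0, v_a=0.5,
                          c_a=tac([0.0, 2.0]), c_bkg=tac([0.0, 0.0]),
                          c_v=tac([0.0, 1.0]), v_v=0.5)
    res = coa_correct_artery_vein(m)
    assert res.c_a_corr.values[0] == 0.0
    assert res.c_v_corr.values[0] == 0.0
    assert res.c_a_corr.values[1] > 0


@given(k=st.floats(0.1, 10), c_so=st.floats(0, 50), c_a=st.floats(0, 50),
       c_v=st.floats(0, 50), bkg=st.floats(0, 5))
@settings(max_examples=100, deadline=None)
def test_corrections_linear_in_concentrations(k, c_so, c_a, c_v, bkg):
    """Scaling all measured concentrations by k scales every output by k."""
    v_a, v_v, v_so = 0.7, 0.5, 40.0
    assert coa_correct_simple(k * c_so, v_so, v_a) == pytest.approx(
        k * coa_correct_simple(c_so, v_so, v_a), rel=1e-9, abs=1e-9)
    assert coa_correct_background(k * c_so, v_so, v_a, k * bkg) == pytest.approx(
        k * coa_correct_background(c_so, v_so, v_a, bkg), rel=1e-9, abs=1e-9)
    m = RegionMeasurement(c_so=tac(c_so), v_so=v_so, v_a=v_a, c_a=tac(c_a),
                          c_bkg=tac(bkg), c_v=tac(c_v), v_v=v_v)
    mk = RegionMeasurement(c_so=tac(k * c_so), v_so=v_so, v_a=v_a, c_a=tac(k * c_a),
                           c_bkg=tac(k * bkg), c_v=tac(k * c_v), v_v=v_v)
    a, ak = coa_correct_artery_vein(m), coa_correct_artery_vein(mk)
    np.testing.assert_allclose(ak.c_a_corr.values, k * a.c_a_corr.values,
                               rtol=1e-9, atol=1e-9)


def test_geometry_and_configuration_errors():
    with pytest.raises(GeometryError):
        coa_correct_simple(1.0, v_so=1.0, v_a=0.0)
    with pytest.raises(GeometryError):
        coa_correct_simple(1.0, v_so=0.5, v_a=1.0)
    with pytest.raises(InvalidParameterError):
        coa_correct_background(1.0, 2.0, 1.0, -0.5)
    # permissive flag lets noisy negative backgrounds through
    coa_correct_background(1.0, 2.0, 1.0, -0.5, allow_negative_background=True)
    with pytest.raises(ConfigurationError):
        coa_correct_artery_vein(RegionMeasurement(c_so=tac(1.0), v_so=2.0, v_a=1.0))
    with pytest.raises(GeometryError):
        RegionMeasurement(c_so=tac(1.0), v_so=1.5, v_a=1.0, c_a=tac(1.0),
                          c_v=tac(1.0), v_v=0.6)


# ----------------------------------------------------------------------
# image-space conservation oracle (independent of the phantom module)
# ----------------------------------------------------------------------
def _blurred_cylinder_2d(radius_mm, value, bkg, fwhm_mm, dx=1.0, half=70):
    """Brute-force 2-D oracle: rasterize a disc by 8x8 subpixel sampling,
    fill background, blur with a Gaussian; return field and occupancy."""
    n = 2 * half
    sub = (np.arange(8) + 0.5) / 8
    occ = np.zeros((n, n))
    for ox in sub:
        for oy in sub:
            x = (np.arange(n) + ox) * dx - half * dx
            y = (np.arange(n) + oy) * dx - half * dx
            occ += (x[:, None] ** 2 + y[None, :] ** 2) <= radius_mm**2
    occ /= 64.0
    field = bkg * (1 - occ) + value * occ
    sigma = fwhm_mm * FWHM_TO_SIGMA / dx
    return gaussian_filter(field, sigma, mode="nearest"), occ, dx


@pytest.mark.parametrize("bkg,correct", [
    (0.0, lambda c_so, v_so, v_a, b: coa_correct_simple(c_so, v_so, v_a)),
    (1.4, coa_correct_background),
])
def test_blurred_cylinder_oracle_recovers_true_activity(bkg, correct):
    """9.5 mm cylinder at 10 kBq/cc, 6 mm FWHM blur, +1.5 cm spill-out
    region: the CoA correction recovers the true value within 2%."""
    radius, value, length = 4.75, 10.0, 1.0
    field, occ, dx = _blurred_cylinder_2d(radius, value, bkg, 6.0)
    n = field.shape[0]
    x = (np.arange(n) + 0.5) * dx - (n / 2) * dx
    r = np.hypot(x[:, None], x[None, :])
    so = r <= radius + 15.0
    ring = (r > radius + 15.0) & (r <= radius + 25.0)
    c_so = field[so].mean()
    v_so = so.sum() * dx * dx * length / 1000.0
    v_a = np.pi * radius**2 * length / 1000.0
    c_bkg = field[ring].mean()
    got = correct(c_so, v_so, v_a, c_bkg)
    assert got == pytest.approx(value, rel=0.02)


def test_blurred_artery_vein_pair_oracle():
    """Two 6.35 mm tubes 2 cm apart with a shared spill-out cylinder:
    the apportioned correction recovers both concentrations within 5%."""
    radius, fwhm, dx = 3.175, 6.0, 0.5
    c_art, c_ven, bkg = 30.0, 18.0, 1.4
    half = 140
    n = 2 * half
    sub = (np.arange(4) + 0.5) / 4
    x0 = half * dx

    def disc(cx):
        occ = np.zeros((n, n))
        for ox in sub:
            for oy in sub:
                x = (np.arange(n) + ox) * dx - x0 - cx
                y = (np.arange(n) + oy) * dx - x0
                occ += (x[:, None] ** 2 + y[None, :] ** 2) <= radius**2
        return occ / 16.0

    occ_a, occ_v = disc(-10.0), disc(+10.0)
    field = bkg * (1 - occ_a - occ_v) + c_art * occ_a + c_ven * occ_v
    field = gaussian_filter(field, fwhm * FWHM_TO_SIGMA / dx, mode="nearest")
    x = (np.arange(n) + 0.5) * dx - x0
    r = np.hypot(x[:, None], x[None, :])
    so = r <= 25.0
    ring = (r > 25.0) & (r <= 35.0)
    px_cc = dx * dx * 1.0 / 1000.0  # 1 mm of tube length
    v_a = v_v = np.pi * radius**2 * 1.0 / 1000.0
    m = RegionMeasurement(
        c_so=tac(field[so].mean()), v_so=so.sum() * px_cc, v_a=v_a,
        c_a=tac((field * occ_a).sum() / occ_a.sum()),
        c_bkg=tac(field[ring].mean()),
        c_v=tac((field * occ_v).sum() / occ_v.sum()), v_v=v_v)
    res = coa_correct_artery_vein(m)
    assert res.c_a_corr.values[0] == pytest.approx(c_art, rel=0.05)
    assert res.c_v_corr.values[0] == pytest.approx(c_ven, rel=0.05)


# ----------------------------------------------------------------------
# recovery-coefficient comparator
# ----------------------------------------------------------------------
def test_rc_limits_and_monotonicity():
    assert recovery_coefficient_cylinder(600.0, 6.0) > 0.99
    diameters = [1.0, 2.0, 4.0, 6.35, 9.5, 12.7, 25.4]
    rcs = [recovery_coefficient_cylinder(d, 6.0) for d in diameters]
    assert all(np.diff(rcs) > 0), "RC must increase with diameter"
    assert rcs[0] < 0.05  # d -> 0 limit
    fwhms = [2.0, 4.0, 6.0, 8.0]
    rcs_f = [recovery_coefficient_cylinder(9.5, f) for f in fwhms]
    assert all(np.diff(rcs_f) < 0), "RC must decrease with FWHM"


def test_rc_against_dense_quadrature_oracle():
    base = recovery_coefficient_cylinder(9.5, 6.0)
    dense = recovery_coefficient_cylinder(9.5, 6.0, resolution=600)
    assert abs(base - dense) < 1e-3


def test_rc_correct_identity_and_overcorrection():
    c = np.array([10.0, 0.5])
    np.testing.assert_array_equal(rc_correct(c, 1.0), c)
    bkg = 1.4
    measured_tail = 0.9 * bkg  # below-background measurement, spill-in dominated
    out = rc_correct(measured_tail, 0.5)
    assert out > measured_tail and out > bkg  # the documented inflation
    with pytest.raises(InvalidParameterError):
        rc_correct(c, 0.0)
    with pytest.raises(InvalidParameterError):
        rc_correct(c, 1.2)
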