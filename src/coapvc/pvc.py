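"""Conservation-of-activity (CoA) partial volume corrections.

The partial volume effect (PVE) in PET spills activity out of small hot
objects (arteries, flow tubes) into their surroundings.  Because a
calibrated scanner conserves total activity in the field of view, the true
mean concentration of a small region can be recovered by summing all the
activity inside an enlarged "spill-out" region V_SO that encloses the true
region V_A plus its blurred signal, and re-assigning it to the true volume:

* simple (zero background):        C_corr = C_SO * V_SO / V_A
* with background subtraction:     C_corr = (C_SO*V_SO - C_BKG*(V_SO - V_A)) / V_A
* artery + vein sharing one V_SO:  the summed activity (after background
  subtraction over V_SO - V_A - V_V) is apportioned between artery and vein
  proportionally to their image-derived signals C_A*V_A and C_V*V_V.

A classical recovery-coefficient (RC) comparator is provided as a baseline:
it divides the measured mean by a size-dependent constant and is
deliberately background-blind, which reproduces its documented failure mode
(inflated values once the true activity drops below background).

All corrections are applied frame-by-frame and are linear in the measured
concentrations at fixed geometry; no temporal smoothing is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, GeometryError, InvalidParameterError
from .tac import TimeActivityCurve

__all__ = [
    "RegionMeasurement",
    "CorrectedAif",
    "coa_correct_simple",
    "coa_correct_background",
    "coa_correct_artery_vein",
    "recovery_coefficient_cylinder",
    "rc_correct",
    "correct_aif",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RegionMeasurement:
    """Per-frame mean activities and true volumes of the nested region scheme.

    ``c_a``/``v_a`` are the true artery region, ``c_so``/``v_so`` the
    enlarged spill-out region that encloses it, ``c_bkg`` the background
    ring, and ``c_v``/``v_v`` an optional companion vein sharing the same
    spill-out region.  All curves must share one frame schedule; volumes
    are in cc and constant across frames.
    """

    c_so: TimeActivityCurve
    v_so: float
    v_a: float
    c_a: TimeActivityCurve | None = None
    c_bkg: TimeActivityCurve | None = None
    c_v: TimeActivityCurve | None = None
    v_v: float | None = None

    def __post_init__(self) -> None:
        if self.v_a <= 0:
            raise GeometryError(f"true artery volume must be positive, got {self.v_a}")
        if self.v_so < self.v_a:
            raise GeometryError(
                f"spill-out volume ({self.v_so} cc) must be >= artery volume ({self.v_a} cc)"
            )
        if (self.c_v is None) != (self.v_v is None):
            raise ConfigurationError("vein curve and vein volume must be given together")
        if self.v_v is not None:
            if self.v_v <= 0:
                raise GeometryError(f"vein volume must be positive, got {self.v_v}")
            if self.v_so <= self.v_a + self.v_v:
                raise GeometryError(
                    "combined spill-out volume must exceed artery + vein volumes "
                    f"({self.v_so} <= {self.v_a} + {self.v_v})"
                )
        for name in ("c_a", "c_bkg", "c_v"):
            curve = getattr(self, name)
            if curve is not None and not curve.same_schedule(self.c_so):
                raise ConfigurationError(f"{name} is not on the same frame schedule as c_so")

    @property
    def has_vein(self) -> bool:
        return self.c_v is not None


@dataclass(frozen=True)
class CorrectedAif:
    """Corrected arterial (and optionally venous) input function.

    ``method`` is one of ``coa_simple``, ``coa_background``,
    ``coa_artery_vein`` or ``rc``; ``diagnostics`` carries per-frame
    intermediate terms (spill-out totals, background subtraction, the
    artery/vein apportioning fraction) for inspection.
    """

    c_a_corr: TimeActivityCurve
    method: str
    c_v_corr: TimeActivityCurve | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method == "coa_artery_vein" and self.c_v_corr is None:
            raise ConfigurationError("artery/vein correction must produce a vein curve")
        if self.method in ("coa_simple", "coa_background", "rc") and self.c_v_corr is not None:
            raise ConfigurationError(f"method {self.method!r} does not produce a vein curve")


# ----------------------------------------------------------------------
# CoA corrections
# ----------------------------------------------------------------------
def _check_geometry(v_so: float, v_a: float) -> None:
    if v_a <= 0:
        raise GeometryError(f"true volume must be positive, got v_a={v_a}")
    if v_so < v_a:
        raise GeometryError(f"spill-out volume v_so={v_so} smaller than true volume v_a={v_a}")


def coa_correct_simple(c_so, v_so: float, v_a: float):
    """Zero-background CoA correction: ``c_so * v_so / v_a``, elementwise.

    Valid only when the surroundings of the spill-out region carry no
    activity; the total activity in V_SO is re-assigned to the true volume.
    """
    _check_geometry(v_so, v_a)
    return np.asarray(c_so, dtype=float) * (v_so / v_a)


def coa_correct_background(c_so, v_so: float, v_a: float, c_bkg,
                           allow_negative_background: bool = False):
    """CoA correction with background subtraction over the annulus.

    ``(c_so*v_so - c_bkg*(v_so - v_a)) / v_a`` per frame.  ``c_bkg`` is the
    mean of a ring far enough from the object to carry pure background.
    Negative background values (possible in very noisy frames) are rejected
    unless ``allow_negative_background`` is set.
    """
    _check_geometry(v_so, v_a)
    c_so = np.asarray(c_so, dtype=float)
    c_bkg = np.asarray(c_bkg, dtype=float)
    if not allow_negative_background and np.any(c_bkg < 0):
        raise InvalidParameterError(
            "negative background concentration; pass allow_negative_background=True "
            "to accept noise-driven negative ring means"
        )
    return (c_so * v_so - c_bkg * (v_so - v_a)) / v_a


def coa_correct_artery_vein(measurement: RegionMeasurement,
                            clamp_negative: bool = False) -> CorrectedAif:
    """CoA correction when artery and vein share one spill-out region.

    The summed activity in V_SO (after subtracting background over
    ``v_so - v_a - v_v``) is apportioned between artery and vein in
    proportion to the image-derived signals ``c_a*v_a`` and ``c_v*v_v``;
    the artery share is divided by ``v_a`` and the vein share, using the
    complementary fraction, by ``v_v``.  Frames with zero combined signal
    (before tracer arrival) return 0 for both corrected values.

    Apportioning uses the signed products as measured; ``clamp_negative``
    clamps negative corrected values to zero.
    """
    if not measurement.has_vein or measurement.c_a is None:
        raise ConfigurationError(
            "artery/vein correction needs c_a, c_v and v_v on the measurement"
        )
    m = measurement
    c_so = m.c_so.values
    c_a = m.c_a.values
    c_v = m.c_v.values
    c_bkg = m.c_bkg.values if m.c_bkg is not None else np.zeros_like(c_so)
    v_free = m.v_so - m.v_a - m.v_v

    total = c_so * m.v_so - c_bkg * v_free
    signal = c_a * m.v_a + c_v * m.v_v
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_a = np.where(signal != 0.0, c_a * m.v_a / np.where(signal == 0, 1.0, signal), 0.0)
    a_corr = np.where(signal != 0.0, total * frac_a / m.v_a, 0.0)
    v_corr = np.where(signal != 0.0, total * (1.0 - frac_a) / m.v_v, 0.0)
    if clamp_negative:
        a_corr = np.clip(a_corr, 0.0, None)
        v_corr = np.clip(v_corr, 0.0, None)
    diagnostics = {
        "spill_out_total_kbq": c_so * m.v_so,
        "background_subtracted_kbq": c_bkg * v_free,
        "artery_fraction": frac_a,
        "note": "vein uses the complementary apportioning fraction over v_v",
    }
    return CorrectedAif(
        c_a_corr=m.c_so.with_values(a_corr),
        c_v_corr=m.c_so.with_values(v_corr),
        method="coa_artery_vein",
        diagnostics=diagnostics,
    )


# ----------------------------------------------------------------------
# Recovery-coefficient comparator
# ----------------------------------------------------------------------
def recovery_coefficient_cylinder(diameter_mm: float, psf_fwhm_mm: float,
                                  resolution: int = 60) -> float:
    """Recovery coefficient of an infinite cylinder under Gaussian blur.

    Fraction of a unit-intensity infinite cylinder's in-plane (2-D disc)
    profile, convolved with an isotropic 2-D Gaussian of the given FWHM,
    that falls inside the true cross-section.  Evaluated by numerical
    integration on a fine grid; ``resolution`` is the number of grid cells
    across ``min(diameter, fwhm)``.
    """
    if diameter_mm <= 0:
        raise InvalidParameterError(f"diameter must be positive, got {diameter_mm}")
    if psf_fwhm_mm <= 0:
        raise InvalidParameterError(f"PSF FWHM must be positive, got {psf_fwhm_mm}")
    radius = 0.5 * diameter_mm
    sigma = psf_fwhm_mm * FWHM_TO_SIGMA
    dx = min(diameter_mm, psf_fwhm_mm) / resolution
    half = radius + 5.0 * sigma
    n = int(np.ceil(half / dx))
    coords = (np.arange(-n, n + 1)) * dx
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(xx, yy)
    # linear anti-aliased disc edge, one cell wide
    disc = np.clip((radius - r) / dx + 0.5, 0.0, 1.0)
    blurred = gaussian_filter(disc, sigma / dx, mode="constant", cval=0.0)
    return float(np.sum(blurred * disc) / np.sum(disc))


def rc_correct(c_a, rc: float):
    """Recovery-coefficient correction: ``c_a / rc`` per frame.

    Deliberately background-blind (the classical linear correction), so
    that once true activity drops below background the spill-in dominates
    and the corrected curve is artificially inflated — the comparator's
    documented failure mode.
    """
    if not (0.0 < rc <= 1.0):
        raise InvalidParameterError(f"recovery coefficient must be in (0, 1], got {rc}")
    return np.asarray(c_a, dtype=float) / rc


# ----------------------------------------------------------------------
# Dispatcher
# ----------------------------------------------------------------------
def correct_aif(measurement: RegionMeasurement, method: str,
                rc: float | None = None, clamp_negative: bool = False,
                allow_negative_background: bool = False) -> CorrectedAif:
    """Apply a named correction to a :class:`RegionMeasurement`.

    ``method`` is ``"simple"``, ``"background"``, ``"artery-vein"`` or
    ``"rc"`` (the latter needs the precomputed recovery coefficient).
    """
    m = measurement
    if method == "simple":
        vals = coa_correct_simple(m.c_so.values, m.v_so, m.v_a)
        diag = {"spill_out_total_kbq": m.c_so.values * m.v_so}
        tag = "coa_simple"
    elif method == "background":
        if m.c_bkg is None:
            raise ConfigurationError("background correction needs a background-ring curve")
        vals = coa_correct_background(m.c_so.values, m.v_so, m.v_a, m.c_bkg.values,
                                      allow_negative_background=allow_negative_background)
        diag = {
            "spill_out_total_kbq": m.c_so.values * m.v_so,
            "background_subtracted_kbq": m.c_bkg.values * (m.v_so - m.v_a),
        }
        tag = "coa_background"
    elif method == "artery-vein":
        return coa_correct_artery_vein(m, clamp_negative=clamp_negative)
    elif method == "rc":
        if rc is None:
            raise ConfigurationError("rc correction needs a recovery coefficient")
        if m.c_a is None:
            raise ConfigurationError("rc correction divides the true-region mean c_a")
        vals = rc_correct(m.c_a.values, rc)
        diag = {"recovery_coefficient": rc}
        tag = "rc"
    else:
        raise ConfigurationError(f"unknown correction method {method!r}")
    if clamp_negative:
        vals = np.clip(vals, 0.0, None)
    return CorrectedAif(c_a_corr=m.c_so.with_values(vals), method=tag, diagnostics=diag)
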