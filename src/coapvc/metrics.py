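"""Validation arithmetic: AUC, temporal binning, decay correction, scaling.

Conventions follow the phantom validation protocol:

* AUC is the rectangle rule, ``sum(frame mean * frame duration)`` in
  kBq*s/cc — not trapezoidal — so framed and bin-averaged curves compare
  consistently.
* Fine reference curves are averaged to the dynamic-PET bin scheme before
  comparison (the binned curve is what a 20 s acquisition can see; sharp
  peaks alias down).
* Percent improvement is the difference of absolute percent errors, in
  percentage points: ``|err_uncorrected| - |err_corrected|``.
* Decay correction uses frame midpoints.
"""

from __future__ import annotations

import numpy as np

from .exceptions import CoverageError, InvalidParameterError
from .phantom import F18_HALF_LIFE_MIN, frame_average
from .tac import TimeActivityCurve

__all__ = [
    "auc",
    "peak",
    "temporal_average",
    "ground_truth_auc",
    "decay_correct",
    "hu_activity_scaling",
    "percent_error",
    "percent_improvement",
]


def auc(tac: TimeActivityCurve) -> float:
    """Area under the curve: ``sum(value_i * duration_i)``, kBq*s/cc."""
    if tac.n_frames == 0:
        raise InvalidParameterError("cannot integrate an empty TAC")
    return float(np.sum(tac.values * tac.frame_duration))


def peak(tac: TimeActivityCurve) -> float:
    """Peak frame value."""
    return float(np.max(tac.values))


def temporal_average(fine: TimeActivityCurve, frame_start, frame_duration
                     ) -> TimeActivityCurve:
    """Average a fine curve onto a frame schedule.

    Each output frame is the mean of the fine samples whose midpoints fall
    in ``[start, start + duration)``; raises :class:`CoverageError` if the
    fine curve does not cover the schedule.
    """
    frame_start = np.asarray(frame_start, float)
    frame_duration = np.asarray(frame_duration, float)
    vals = frame_average(fine, frame_start, frame_duration)
    return TimeActivityCurve(frame_start, frame_duration, vals, unit=fine.unit)


def ground_truth_auc(delivered_activity_kbq: float, flow_rate_ml_s: float,
                     half_life_min: float | None = None,
                     decay_interval_s: float = 0.0) -> float:
    """Model AUC from the known delivered activity.

    The activity delivered through the tubes, decay-corrected to the
    experiment reference time, divided by the volumetric flow rate:
    every tracer atom passes the tube cross-section exactly once, so
    ``AUC = A / Q`` regardless of curve shape.  Units kBq*s/cc.
    """
    if delivered_activity_kbq <= 0:
        raise InvalidParameterError("delivered activity must be positive")
    if flow_rate_ml_s <= 0:
        raise InvalidParameterError("flow rate must be positive")
    a = delivered_activity_kbq
    if half_life_min is not None and decay_interval_s != 0.0:
        a = a * 2.0 ** (-(decay_interval_s / 60.0) / half_life_min)
    return a / flow_rate_ml_s


def decay_correct(tac: TimeActivityCurve, half_life_min: float = F18_HALF_LIFE_MIN,
                  reference_time_s: float = 0.0) -> TimeActivityCurve:
    """Decay-correct a TAC to a reference time.

    Each frame is scaled by ``2**((t_mid - reference)/half_life)`` with
    ``t_mid`` the frame midpoint; correcting by an interval and then by
    its negative is an exact round trip.
    """
    if half_life_min <= 0:
        raise InvalidParameterError("half-life must be positive")
    factor = 2.0 ** ((tac.midpoints - reference_time_s) / 60.0 / half_life_min)
    return tac.with_values(tac.values * factor)


def hu_activity_scaling(contrast_enhancement_hu_per_mgi_ml: float,
                        iodine_mass_mg: float, activity_mbq: float) -> float:
    """HU-per-(kBq/cc) factor linking DCE-CT and PET curves.

    Assuming contrast agent and tracer share the same dilution volume, the
    enhancement per unit iodine concentration times the iodine-to-activity
    mass ratio gives HU per kBq/cc:
    ``CE [HU/(mgI/mL)] * iodine [mg] / activity [kBq]``.
    """
    if min(contrast_enhancement_hu_per_mgi_ml, iodine_mass_mg, activity_mbq) <= 0:
        raise InvalidParameterError("all scaling inputs must be positive")
    return contrast_enhancement_hu_per_mgi_ml * iodine_mass_mg / (activity_mbq * 1000.0)


def percent_error(measured: float, truth: float) -> float:
    """Signed percent error, ``100 * (measured - truth) / truth``."""
    if truth == 0:
        raise InvalidParameterError("percent error undefined for zero truth")
    return 100.0 * (measured - truth) / truth


def percent_improvement(err_uncorrected_pct: float, err_corrected_pct: float) -> float:
    """Improvement in percentage points: ``|err_u| - |err_c|``."""
    return abs(err_uncorrected_pct) - abs(err_corrected_pct)
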