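"""Time-activity curves.

A :class:`TimeActivityCurve` is the package's framed concentration series:
frame start times and durations in seconds, mean activity values in kBq/cc
(or HU for CT-derived reference curves).  Frames are half-open intervals
``[start, start + duration)`` and must be non-overlapping and increasing.

Two sampling regimes share the container:

* scanner-like frames (e.g. the 15 x 20 s dynamic PET schedule), and
* "fine" curves sampled on a regular sub-second grid, where each sample is
  the value at the bin midpoint (so that frame averaging and rectangle-rule
  integration behave like midpoint quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParseError

__all__ = ["TimeActivityCurve"]

_OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framed mean-activity series.

    Parameters
    ----------
    frame_start : array-like
        Frame start times, seconds, strictly increasing.
    frame_duration : array-like
        Frame durations, seconds, all positive.
    values : array-like
        Mean activity per frame; units given by ``unit``.
    unit : str
        Value units, default ``"kBq/cc"``.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray
    values: np.ndarray
    unit: str = "kBq/cc"

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        object.__setattr__(self, "values", val)
        if start.ndim != 1 or start.shape != dur.shape or start.shape != val.shape:
            raise ParseError(
                f"frame_start, frame_duration and values must be 1-D and equal "
                f"length, got shapes {start.shape}, {dur.shape}, {val.shape}"
            )
        if start.size == 0:
            raise ParseError("a TimeActivityCurve needs at least one frame")
        if np.any(dur <= 0):
            row = int(np.argmax(dur <= 0))
            raise ParseError(f"non-positive frame duration at row {row}")
        ends = start + dur
        overlap = start[1:] < ends[:-1] - _OVERLAP_TOL
        if np.any(overlap):
            row = int(np.argmax(overlap)) + 1
            raise ParseError(f"frame at row {row} overlaps the previous frame")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def midpoints(self) -> np.ndarray:
        """Frame midpoint times (s), used for decay correction and plotting."""
        return self.frame_start + 0.5 * self.frame_duration

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeActivityCurve":
        """Return a copy on the same frame schedule with new values."""
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)

    def same_schedule(self, other: "TimeActivityCurve", tol: float = 1e-9) -> bool:
        return (
            self.n_frames == other.n_frames
            and np.allclose(self.frame_start, other.frame_start, atol=tol)
            and np.allclose(self.frame_duration, other.frame_duration, atol=tol)
        )

    # ------------------------------------------------------------------
    @classmethod
    def fine(cls, t_end: float, dt: float, values: np.ndarray | None = None,
             unit: str = "kBq/cc") -> "TimeActivityCurve":
        """Regular fine grid on [0, t_end) with bin width ``dt``.

        Values, when given, are interpreted as samples at bin midpoints.
        """
        n = int(round(t_end / dt))
        start = np.arange(n) * dt
        dur = np.full(n, dt)
        if values is None:
            values = np.zeros(n)
        return cls(start, dur, values, unit=unit)
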