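"""Digital flow phantom for input-function correction studies.

Emulates a flow phantom in which four tubes of decreasing inner diameter
(1" = 25.4 mm down to 1/4" = 6.35 mm) carry the same arterial input
function through a uniform background compartment, with a companion 1/4"
venous tube fed through a dilution buffer.  Tracer is injected through a
well-mixed chamber at constant rate, the system is flushed at constant
volumetric flow, and the resulting concentration curves are imaged as a
4-D dynamic PET series: frames are averaged over the acquisition windows,
tube cross-sections rasterized with fractional occupancy, the volume
blurred with an isotropic Gaussian point-spread function (the image-space
surrogate for the 4-7 mm PET resolution), and optionally degraded with
frame-duration-dependent Gaussian noise.

The whole simulation is a pure function of (PhantomSpec, seed); ground
truth (the unblurred, frame-averaged tube concentrations) is returned next
to the image so corrections can be validated without scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .exceptions import CoverageError, GeometryError, InvalidParameterError
from .rois import disc_occupancy
from .tac import TimeActivityCurve

__all__ = [
    "InjectionModel",
    "TubeSpec",
    "NoiseModel",
    "PhantomSpec",
    "DynamicImage",
    "generate_input_function",
    "generate_vein_curve",
    "render_dynamic_image",
    "resample_slices",
    "add_noise",
    "exp_compartment_filter",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
F18_HALF_LIFE_MIN = 109.77

#: inner diameters (mm) of the default artery tube bank, largest first
DEFAULT_ARTERY_DIAMETERS = (25.4, 12.7, 9.5, 6.35)


# ----------------------------------------------------------------------
# Specs
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class InjectionModel:
    """Tracer delivery through a well-mixed chamber.

    ``injected_activity_mbq`` is the activity delivered over the injection
    (default 22 MBq: a 60 cc syringe loaded with 53 MBq of which 25 mL is
    pushed at 0.5 mL/s for 50 s).  ``chamber_volume_ml`` sets the
    mixing-chamber dispersion; ``buffer_volume_ml`` the venous dilution
    compartment.  ``sample_dt_s`` is the fine ground-truth sampling step.
    """

    injected_activity_mbq: float = 22.0
    injection_rate_ml_s: float = 0.5
    injection_duration_s: float = 50.0
    chamber_volume_ml: float = 150.0
    buffer_volume_ml: float = 500.0
    sample_dt_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("injected_activity_mbq", "injection_rate_ml_s",
                     "injection_duration_s", "sample_dt_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.chamber_volume_ml < 0 or self.buffer_volume_ml < 0:
            raise InvalidParameterError("compartment volumes cannot be negative")


@dataclass(frozen=True)
class TubeSpec:
    """One flow tube: inner diameter (mm), in-plane centre (mm), role."""

    inner_diameter_mm: float
    center_xy_mm: tuple[float, float]
    role: str = "artery"  # artery | vein | buffer

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0:
            raise InvalidParameterError("tube diameter must be positive")
        if self.role not in ("artery", "vein", "buffer"):
            raise InvalidParameterError(f"unknown tube role {self.role!r}")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.inner_diameter_mm

    @property
    def label(self) -> str:
        return f"{self.role}_{self.inner_diameter_mm:g}mm"


@dataclass(frozen=True)
class NoiseModel:
    """Image-space noise: ``none`` or frame-duration-dependent ``gaussian``.

    The gaussian model adds zero-mean noise with standard deviation
    ``sigma = scale * sqrt(max(value, floor) / frame_duration)`` per voxel,
    mimicking the count-statistics scaling of short dynamic frames.
    """

    kind: str = "none"  # none | gaussian
    scale: float = 1.0
    floor: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian"):
            raise InvalidParameterError(f"unknown noise model {self.kind!r}")


def default_tube_bank(spacing_mm: float = 63.5, first_x_mm: float = 50.0,
                      y_mm: float = 50.0, vein_offset_mm: float = 20.0) -> tuple[TubeSpec, ...]:
    """Four artery tubes 63.5 mm apart plus a 6.35 mm vein 2 cm beyond the last."""
    tubes = [
        TubeSpec(d, (first_x_mm + i * spacing_mm, y_mm), "artery")
        for i, d in enumerate(DEFAULT_ARTERY_DIAMETERS)
    ]
    last_x = first_x_mm + (len(DEFAULT_ARTERY_DIAMETERS) - 1) * spacing_mm
    tubes.append(TubeSpec(6.35, (last_x + vein_offset_mm, y_mm), "vein"))
    return tuple(tubes)


def default_frame_schedule(n_frames: int = 15, duration_s: float = 20.0
                           ) -> tuple[tuple[float, float], ...]:
    """15 x 20 s dynamic acquisition."""
    return tuple((i * duration_s, duration_s) for i in range(n_frames))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom experiment."""

    tube_bank: tuple[TubeSpec, ...] = field(default_factory=default_tube_bank)
    background_activity: float = 1.4  # kBq/cc
    psf_fwhm_mm: float = 6.0
    voxel_size_mm: float = 1.0
    fov_mm: tuple[float, float, float] = (310.0, 100.0, 60.0)
    frame_schedule: tuple[tuple[float, float], ...] = field(
        default_factory=default_frame_schedule)
    injection: InjectionModel = field(default_factory=InjectionModel)
    flow_rate_ml_s: float = 10.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    tracer_half_life_min: float = F18_HALF_LIFE_MIN
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if self.background_activity < 0:
            raise InvalidParameterError("background activity cannot be negative")
        if self.flow_rate_ml_s <= 0 or self.voxel_size_mm <= 0:
            raise InvalidParameterError("flow rate and voxel size must be positive")
        starts = np.array([s for s, _ in self.frame_schedule])
        durs = np.array([d for _, d in self.frame_schedule])
        if np.any(durs <= 0) or np.any(np.diff(starts) <= 0):
            raise InvalidParameterError("frame schedule must be increasing, positive")
        if np.any(starts[1:] < (starts + durs)[:-1] - 1e-9):
            raise InvalidParameterError("frame schedule has overlapping frames")
        margin = 3.0 * self.psf_fwhm_mm if self.psf_fwhm_mm > 0 else 0.0
        for tube in self.tube_bank:
            x, y = tube.center_xy_mm
            r = tube.radius_mm
            if (x - r < margin or y - r < margin
                    or x + r > self.fov_mm[0] - margin
                    or y + r > self.fov_mm[1] - margin):
                raise GeometryError(
                    f"tube {tube.label} within {margin:g} mm of the FOV edge"
                )
        for i, a in enumerate(self.tube_bank):
            for b in self.tube_bank[i + 1:]:
                sep = np.hypot(a.center_xy_mm[0] - b.center_xy_mm[0],
                               a.center_xy_mm[1] - b.center_xy_mm[1])
                if sep < a.radius_mm + b.radius_mm:
                    raise GeometryError(f"tubes {a.label} and {b.label} overlap")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.voxel_size_mm)) for e in self.fov_mm)

    @property
    def frame_start(self) -> np.ndarray:
        return np.array([s for s, _ in self.frame_schedule], float)

    @property
    def frame_duration(self) -> np.ndarray:
        return np.array([d for _, d in self.frame_schedule], float)

    @property
    def scan_end_s(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1])


@dataclass
class DynamicImage:
    """4-D voxel grid (x, y, z, frame) of activity with spacing and schedule."""

    data: np.ndarray  # (nx, ny, nz, nt), kBq/cc
    voxel_size: tuple[float, float, float]  # mm
    frame_start: np.ndarray  # s
    frame_duration: np.ndarray  # s
    unit: str = "kBq/cc"

    def __post_init__(self) -> None:
        self.frame_start = np.asarray(self.frame_start, float)
        self.frame_duration = np.asarray(self.frame_duration, float)
        if self.data.ndim != 4:
            raise InvalidParameterError("dynamic image data must be 4-D (x, y, z, t)")
        if self.data.shape[3] != self.frame_start.size:
            raise InvalidParameterError(
                f"frame count mismatch: image has {self.data.shape[3]} frames, "
                f"schedule has {self.frame_start.size}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def grid(self):
        from .rois import ImageGrid
        return ImageGrid(self.data.shape[:3], self.voxel_size)


# ----------------------------------------------------------------------
# Input-function generation
# ----------------------------------------------------------------------
def generate_input_function(injection: InjectionModel, flow_rate_ml_s: float,
                            t_end_s: float = 320.0, apply_decay: bool = False,
                            half_life_min: float = F18_HALF_LIFE_MIN) -> TimeActivityCurve:
    """Arterial ground-truth curve from a single well-mixed chamber.

    During the injection, activity flows into a chamber of volume V at
    constant rate A/T while the chamber is flushed at flow Q, giving a
    mono-exponential rise ``C(t) = A/(T*Q) * (1 - exp(-Q*t/V))``; after
    the injection the chamber washes out as ``C(T) * exp(-Q*(t-T)/V)``.
    Mass balance ``Q * integral(C) = A`` holds by construction.  Samples
    are taken at fine-bin midpoints in kBq/cc.  With ``apply_decay`` the
    curve carries physical decay (otherwise it is decay-corrected to
    injection time, as scanner output would be).
    """
    if flow_rate_ml_s <= 0:
        raise InvalidParameterError("flow rate must be positive")
    a_kbq = injection.injected_activity_mbq * 1000.0
    big_t = injection.injection_duration_s
    q = flow_rate_ml_s
    v = injection.chamber_volume_ml
    dt = injection.sample_dt_s
    if t_end_s <= big_t:
        raise InvalidParameterError("t_end must exceed the injection duration")

    n = int(round(t_end_s / dt))
    t = (np.arange(n) + 0.5) * dt
    plateau = a_kbq / (big_t * q)  # kBq/mL == kBq/cc
    if v <= 0:
        c = np.where(t < big_t, plateau, 0.0)
    else:
        tau = v / q
        rising = plateau * (1.0 - np.exp(-t / tau))
        peak = plateau * (1.0 - np.exp(-big_t / tau))
        c = np.where(t < big_t, rising, peak * np.exp(-(t - big_t) / tau))
    if apply_decay:
        c = c * 2.0 ** (-(t / 60.0) / half_life_min)
    return TimeActivityCurve.fine(t_end_s, dt, c)


def exp_compartment_filter(values: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Response of a well-mixed compartment, ``y' = (x - y)/tau``, to input x.

    Exact discretization for piecewise-linear input on a regular grid;
    ``tau -> 0`` returns the input unchanged.
    """
    x = np.asarray(values, float)
    if tau <= 0:
        return x.copy()
    e = np.exp(-dt / tau)
    # y[i] = e*y[i-1] + b0*x[i] + b1*x[i-1]: first-order IIR, run via lfilter
    b0 = (dt - tau * (1.0 - e)) / dt
    b1 = (1.0 - e) - b0
    return lfilter([b0, b1], [1.0, -e], x)


def generate_vein_curve(arterial: TimeActivityCurve, buffer_volume_ml: float,
                        flow_rate_ml_s: float) -> TimeActivityCurve:
    """Venous curve: arterial curve dispersed by a well-mixed buffer.

    Convolution with the single-compartment impulse response
    ``(Q/V) * exp(-Q*t/V)``; preserves AUC (a linear dispersive system) and
    strictly lowers the peak for V > 0.
    """
    if flow_rate_ml_s <= 0:
        raise InvalidParameterError("flow rate must be positive")
    if buffer_volume_ml < 0:
        raise InvalidParameterError("buffer volume cannot be negative")
    dt = float(arterial.frame_duration[0])
    if not np.allclose(arterial.frame_duration, dt):
        raise InvalidParameterError("vein dispersion expects a regular fine grid")
    tau = buffer_volume_ml / flow_rate_ml_s
    return arterial.with_values(exp_compartment_filter(arterial.values, dt, tau))


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------
def frame_average(fine: TimeActivityCurve, frame_start: np.ndarray,
                  frame_duration: np.ndarray) -> np.ndarray:
    """Mean of fine samples (midpoint convention) within each frame window."""
    mids = fine.midpoints
    out = np.empty(len(frame_start))
    for i, (s, d) in enumerate(zip(frame_start, frame_duration)):
        sel = (mids >= s) & (mids < s + d)
        if (not np.any(sel) or fine.frame_start[0] > s + 1e-9
                or fine.frame_end[-1] < s + d - 1e-9):
            raise CoverageError(
                f"fine curve (0..{fine.frame_end[-1]:g} s) does not cover frame "
                f"[{s:g}, {s + d:g}) s"
            )
        out[i] = fine.values[sel].mean()
    return out


def render_dynamic_image(spec: PhantomSpec,
                         arterial: TimeActivityCurve | None = None,
                         venous: TimeActivityCurve | None = None,
                         ) -> tuple[DynamicImage, dict[str, TimeActivityCurve]]:
    """Render the phantom into a 4-D dynamic image plus ground-truth TACs.

    Per frame: average the fine curves over the frame window, rasterize
    each tube cross-section with fractional occupancy, fill the background
    compartment uniformly, blur with the isotropic Gaussian PSF and apply
    the configured noise model.  Tubes are z-invariant (they span the full
    FOV along z), so the isotropic 3-D blur equals the in-plane 2-D blur
    broadcast along z, which is how it is computed.

    Returns the image and a dict label -> unblurred frame-averaged
    ground-truth TAC (one entry per tube, plus ``"background"``).
    """
    inj = spec.injection
    t_need = spec.scan_end_s
    if arterial is None:
        arterial = generate_input_function(
            inj, spec.flow_rate_ml_s, t_end_s=max(320.0, t_need + inj.sample_dt_s),
            apply_decay=not spec.decay_corrected,
            half_life_min=spec.tracer_half_life_min)
    if venous is None:
        venous = generate_vein_curve(arterial, inj.buffer_volume_ml, spec.flow_rate_ml_s)

    fs, fd = spec.frame_start, spec.frame_duration
    art_binned = frame_average(arterial, fs, fd)
    ven_binned = frame_average(venous, fs, fd)
    per_role = {"artery": art_binned, "vein": ven_binned,
                "buffer": np.zeros_like(art_binned)}

    nx, ny, nz = spec.grid_shape
    dxy = (spec.voxel_size_mm, spec.voxel_size_mm)
    occs = [disc_occupancy(t.center_xy_mm, t.radius_mm, (nx, ny), dxy) for t in spec.tube_bank]
    occ_total = np.sum(occs, axis=0)

    sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    nt = len(fs)
    data = np.empty((nx, ny, nz, nt), dtype=np.float64)
    for f in range(nt):
        field2d = spec.background_activity * (1.0 - occ_total)
        for tube, occ in zip(spec.tube_bank, occs):
            field2d = field2d + occ * per_role[tube.role][f]
        if sigma_vox > 0:
            # nearest-edge handling: exact for the uniform background at the
            # borders, mass-conserving for tubes kept >= 3 FWHM from the edge
            field2d = gaussian_filter(field2d, sigma_vox, mode="nearest")
        data[:, :, :, f] = field2d[:, :, None]

    image = DynamicImage(data, (spec.voxel_size_mm,) * 3, fs, fd)
    image = add_noise(image, spec.noise, seed=spec.seed)

    truth: dict[str, TimeActivityCurve] = {}
    for tube in spec.tube_bank:
        truth[tube.label] = TimeActivityCurve(fs, fd, per_role[tube.role].copy())
    truth["background"] = TimeActivityCurve(
        fs, fd, np.full(nt, spec.background_activity))
    return image, truth


def resample_slices(image: DynamicImage, slice_thickness_mm: float) -> DynamicImage:
    """Resample the z axis to scanner-like slices by slab averaging.

    The requested thickness is rounded to an integer number of source
    voxels (e.g. 3 mm slabs from a 1 mm grid approximate 3.27 mm scanner
    slices); x/y sampling is unchanged.
    """
    factor = int(round(slice_thickness_mm / image.voxel_size[2]))
    if factor < 1:
        raise InvalidParameterError("slice thickness below the source spacing")
    if factor == 1:
        return image
    nz = (image.data.shape[2] // factor) * factor
    if nz == 0:
        raise InvalidParameterError("image too thin for the requested slices")
    nx, ny, _, nt = image.data.shape
    slabs = image.data[:, :, :nz, :].reshape(nx, ny, nz // factor, factor, nt)
    data = slabs.mean(axis=3)
    vx, vy, vz = image.voxel_size
    return DynamicImage(data, (vx, vy, vz * factor), image.frame_start,
                        image.frame_duration, unit=image.unit)


def add_noise(image: DynamicImage, model: NoiseModel, seed: int | None = None) -> DynamicImage:
    """Apply the noise model; ``none`` is a bit-identical passthrough.

    The gaussian model is seeded and reproducible: identical seed, model
    and image give identical output.
    """
    if model.kind == "none":
        return image
    rng = np.random.default_rng(seed)
    sigma = model.scale * np.sqrt(
        np.maximum(image.data, model.floor) / image.frame_duration[None, None, None, :]
    )
    noisy = image.data + rng.standard_normal(image.data.shape) * sigma
    return replace(image, data=noisy)
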