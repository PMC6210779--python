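"""Spatiotemporal gait parameters from initial contacts and vertical acceleration.

Five parameters are computed: step time, stride time, step length, stride
length and walking speed. Temporal parameters come straight from the
initial-contact sequence; spatial ones from an extended inverted-pendulum
model in which the vertical excursion D of the knee-worn sensor during one
step maps to step length as

    step_length = KG * 2 * sqrt(2 * Wp * D - D**2)

with Wp the sensor height above ground (0.34 m) and KG a generic multiplying
factor (4) mapping the sensor position to the body's centre of mass. D is
obtained by double integration of the vertical acceleration between
consecutive initial contacts, with per-step linear drift removal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .errors import DomainError, InputError, InsufficientDataError, ParameterError
from .events import InitialContactSeries
from .signal_core import STANDARD_GRAVITY, lowpass_filter

log = logging.getLogger(__name__)


@dataclass
class PendulumConfig:
    """Inverted-pendulum geometry: sensor height Wp (m) and gain KG."""

    Wp: float = 0.34
    KG: float = 4.0

    def __post_init__(self):
        if self.Wp <= 0:
            raise ParameterError("Wp (sensor height) must be positive")
        if self.KG <= 0:
            raise ParameterError("KG must be positive")


@dataclass
class GaitOptions:
    """Conditioning applied to the vertical signal before displacement integration.

    repair_halfwidth
        Samples replaced on each side of every initial contact by cubic-spline
        interpolation, to excise the heel-strike impact transient which would
        otherwise corrupt the double integral. 0 disables the repair.
    excursion_cutoff_hz
        Zero-phase Butterworth low-pass cutoff isolating the centre-of-mass
        band (< ~3 Hz at pathological cadences) before integration. ``None``
        disables the filter.
    """

    repair_halfwidth: int = 1
    excursion_cutoff_hz: float | None = 4.0
    excursion_filter_order: int = 4


@dataclass
class StepRecord:
    """One step: bounding initial contacts, vertical excursion and length."""

    ic_start: float
    ic_end: float
    D: float
    step_length_m: float

    def __post_init__(self):
        if self.ic_end <= self.ic_start:
            raise InputError("ic_end must be after ic_start")
        if self.D < 0 or self.step_length_m < 0:
            raise DomainError("D and step length must be non-negative")

    @property
    def step_time(self) -> float:
        return self.ic_end - self.ic_start


@dataclass
class GaitSummary:
    """Per-subject (per-side) averages of the five gait parameters."""

    avg_step_time: float
    avg_stride_time: float
    avg_step_length: float
    avg_stride_length: float
    walking_speed: float
    n_steps: int
    side: str = "left"
    subject_id: str = "anonymous"

    def as_dict(self) -> dict:
        return {
            "avg_step_time_s": self.avg_step_time,
            "avg_stride_time_s": self.avg_stride_time,
            "avg_step_length_m": self.avg_step_length,
            "avg_stride_length_m": self.avg_stride_length,
            "walking_speed_mps": self.walking_speed,
            "n_steps": self.n_steps,
        }


def step_times(ics: InitialContactSeries | np.ndarray) -> np.ndarray:
    """Step times: IC(i+1) - IC(i). Fewer than 2 ICs gives an empty series."""
    t = ics.ic_times if isinstance(ics, InitialContactSeries) else np.asarray(ics, float)
    if len(t) < 2:
        return np.empty(0)
    return np.diff(t)


def stride_times(ics: InitialContactSeries | np.ndarray) -> np.ndarray:
    """Stride times: IC(i+2) - IC(i). Fewer than 3 ICs gives an empty series.

    Satisfies stride_time(i) = step_time(i) + step_time(i+1) exactly.
    """
    t = ics.ic_times if isinstance(ics, InitialContactSeries) else np.asarray(ics, float)
    if len(t) < 3:
        return np.empty(0)
    st = np.diff(t)
    # summing adjacent step times (rather than differencing t[i+2] - t[i])
    # makes stride(i) = step(i) + step(i+1) exact in floating point
    return st[:-1] + st[1:]


def _remove_boundary_trend(x: np.ndarray) -> np.ndarray:
    """Subtract the straight line through the first and last samples.

    This is the per-step drift correction of the pendulum model: the sensor
    state is assumed equal at successive initial contacts, so any net change
    across the step is integration drift. Unlike a least-squares detrend it
    leaves a full-period sinusoid exactly intact while still annihilating the
    ramp (in velocity) and quadratic growth (in displacement) that a constant
    acceleration bias produces.
    """
    line = x[0] + (x[-1] - x[0]) * np.linspace(0.0, 1.0, len(x))
    return x - line


def vertical_excursion(segment_g: np.ndarray, sampling_rate: float) -> float:
    """Vertical excursion D (m) of one step from its acceleration segment.

    The segment (units g, gravity removed) spans one step, IC to next IC.
    Acceleration is converted to m/s^2 and trapezoid-integrated to velocity;
    the velocity's boundary-to-boundary linear drift is removed (per-step
    drift correction), it is integrated again to displacement, the
    displacement drift is removed the same way, and D is the max - min of
    the result.
    """
    seg = np.asarray(segment_g, dtype=float)
    if len(seg) < 4:
        raise InputError(f"step segment of {len(seg)} samples is too short (need >= 4)")
    if not np.all(np.isfinite(seg)):
        raise InputError("segment contains non-finite values")
    dt = 1.0 / sampling_rate
    vel = cumulative_trapezoid(seg * STANDARD_GRAVITY, dx=dt, initial=0.0)
    vel = _remove_boundary_trend(vel)
    disp = cumulative_trapezoid(vel, dx=dt, initial=0.0)
    disp = _remove_boundary_trend(disp)
    return float(disp.max() - disp.min())


def step_length(D: float, config: PendulumConfig | None = None) -> float:
    """Inverted-pendulum step length KG * 2 * sqrt(2*Wp*D - D^2), meters."""
    config = config or PendulumConfig()
    if D < 0 or D > 2.0 * config.Wp:
        raise DomainError(
            f"vertical excursion D={D} outside [0, {2.0 * config.Wp}] m (negative radicand)"
        )
    return config.KG * 2.0 * math.sqrt(2.0 * config.Wp * D - D * D)


def stride_length(step_length_m: float) -> float:
    """Stride length = exactly 2 x step length."""
    if step_length_m < 0:
        raise DomainError("step length must be non-negative")
    return 2.0 * step_length_m


def walking_speed(avg_step_length: float, avg_step_time: float) -> float:
    """Walking speed = mean step length / mean step time (m/s)."""
    if avg_step_time <= 0:
        raise DomainError("average step time must be positive")
    return avg_step_length / avg_step_time


def _repair_transients(vertical: np.ndarray, ic_indices: np.ndarray, halfwidth: int) -> np.ndarray:
    """Replace +/-halfwidth samples around each IC by cubic-spline interpolation.

    Heel-strike impact transients are high-amplitude, near-impulsive artefacts
    with no counterpart in the centre-of-mass trajectory; left in place they
    dominate the doubly-integrated displacement. The pendulum arc is smooth at
    the contact, so local spline interpolation from the surrounding samples
    restores it with negligible error.
    """
    if halfwidth <= 0 or len(ic_indices) == 0:
        return vertical
    mask = np.zeros(len(vertical), dtype=bool)
    for i in ic_indices:
        lo = max(0, int(i) - halfwidth)
        hi = min(len(vertical), int(i) + halfwidth + 1)
        mask[lo:hi] = True
    keep = np.flatnonzero(~mask)
    if len(keep) < 4:
        return vertical
    out = vertical.copy()
    spline = CubicSpline(keep, vertical[keep])
    gaps = np.flatnonzero(mask)
    out[gaps] = spline(gaps)
    return out


def condition_vertical_for_excursion(
    vertical: np.ndarray,
    sampling_rate: float,
    ic_indices: np.ndarray,
    options: GaitOptions | None = None,
) -> np.ndarray:
    """Impact-transient repair + centre-of-mass band low-pass, for integration."""
    options = options or GaitOptions()
    v = np.asarray(vertical, dtype=float)
    v = _repair_transients(v, np.asarray(ic_indices, int), options.repair_halfwidth)
    if options.excursion_cutoff_hz is not None:
        v = lowpass_filter(
            v,
            sampling_rate,
            order=options.excursion_filter_order,
            cutoff=options.excursion_cutoff_hz,
        )
    return v


def summarize_gait(
    ics: InitialContactSeries,
    vertical: np.ndarray,
    sampling_rate: float,
    config: PendulumConfig | None = None,
    options: GaitOptions | None = None,
) -> tuple[GaitSummary, list[StepRecord]]:
    """Per-step records and the five-parameter summary for one leg.

    ``vertical`` is the orientation-corrected (gravity-removed, unfiltered)
    vertical acceleration in g; it is conditioned internally (impact-transient
    repair, centre-of-mass low-pass) before displacement integration. Steps
    whose excursion falls outside the pendulum domain [0, 2*Wp] are dropped
    with a logged warning; the summary reports the retained count.
    """
    config = config or PendulumConfig()
    options = options or GaitOptions()
    if len(ics) < 3:
        raise InsufficientDataError(
            f"subject {ics.source_id!r} side {ics.side!r}: "
            f"{len(ics)} initial contacts, need >= 3"
        )
    v = condition_vertical_for_excursion(vertical, sampling_rate, ics.ic_indices, options)

    records: list[StepRecord] = []
    times = ics.ic_times
    for i0, i1, t0, t1 in zip(ics.ic_indices[:-1], ics.ic_indices[1:], times[:-1], times[1:]):
        seg = v[i0 : i1 + 1]
        d = vertical_excursion(seg, sampling_rate)
        if d > 2.0 * config.Wp:
            log.warning(
                "subject %s side %s: step at %.2f s has D=%.3f m outside [0, %.2f]; dropped",
                ics.source_id,
                ics.side,
                t0,
                d,
                2.0 * config.Wp,
            )
            continue
        records.append(StepRecord(ic_start=t0, ic_end=t1, D=d, step_length_m=step_length(d, config)))

    if not records:
        raise InsufficientDataError(
            f"subject {ics.source_id!r} side {ics.side!r}: no valid steps after domain filtering"
        )
    avg_step_time = float(np.mean(step_times(ics)))
    avg_stride_time = float(np.mean(stride_times(ics)))
    avg_step_length = float(np.mean([r.step_length_m for r in records]))
    summary = GaitSummary(
        avg_step_time=avg_step_time,
        avg_stride_time=avg_stride_time,
        avg_step_length=avg_step_length,
        avg_stride_length=stride_length(avg_step_length),
        walking_speed=walking_speed(avg_step_length, avg_step_time),
        n_steps=len(records),
        side=ics.side,
        subject_id=ics.source_id,
    )
    return summary, records


def combine_summaries(left: GaitSummary, right: GaitSummary) -> GaitSummary:
    """Unweighted mean of the left- and right-leg summaries."""
    if left.subject_id != right.subject_id:
        raise InputError("cannot combine summaries of different subjects")
    avg_step_length = 0.5 * (left.avg_step_length + right.avg_step_length)
    return GaitSummary(
        avg_step_time=0.5 * (left.avg_step_time + right.avg_step_time),
        avg_stride_time=0.5 * (left.avg_stride_time + right.avg_stride_time),
        avg_step_length=avg_step_length,
        avg_stride_length=stride_length(avg_step_length),
        walking_speed=0.5 * (left.walking_speed + right.walking_speed),
        n_steps=left.n_steps + right.n_steps,
        side="combined",
        subject_id=left.subject_id,
    )
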