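"""Raw-signal data model, file I/O, orientation correction and low-pass filtering.

The sensor is a knee-worn triaxial accelerometer (32 Hz, +/-8 g, mounted
0.34 m above the ground). Recordings arrive in device coordinates; a
quasi-static estimate of the gravity direction (the recording-mean
acceleration vector) is used to rotate the axes into an anatomically
meaningful horizontal-vertical frame before gait events are detected.

All stored series are in g; conversion to m/s^2 happens only at the single
point where acceleration is integrated to displacement (see
:mod:`kneegait.parameters`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    FormatError,
    InputError,
    OrientationError,
    ParameterError,
    ParseError,
)

STANDARD_GRAVITY = 9.80665  # m/s^2 per g

SIDES = ("left", "right")
LABELS = ("FoG", "noFoG", "unknown")

AXIS_COLUMNS = ("ax", "ay", "az")


@dataclass
class AccelerometerRecording:
    """A triaxial accelerometer recording for one subject and one knee.

    Parameters
    ----------
    samples
        Array of shape (n, 3) with columns (ax, ay, az), units g.
    sampling_rate
        Samples per second (the study device records at 32 Hz).
    sensor_height
        Height of the sensor above the ground in meters (0.34 m at the knee).
    side
        Which knee the sensor was strapped to: "left" or "right".
    subject_id
        Free-form subject identifier.
    label
        Clinical class: "FoG", "noFoG" or "unknown".
    sensor_sourced
        When True, samples are checked against the device's +/-8 g range.
    """

    samples: np.ndarray
    sampling_rate: float = 32.0
    sensor_height: float = 0.34
    side: str = "left"
    subject_id: str = "anonymous"
    label: str = "unknown"
    sensor_sourced: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InputError("samples must be an (n, 3) array of (ax, ay, az) in g")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if len(self.samples) < 2:
            raise InputError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("recording contains non-finite values")
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sensor_sourced and np.any(np.abs(self.samples) > 8.0):
            raise InputError("sensor-sourced samples must lie within [-8, +8] g")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n / sampling_rate)."""
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Uniform time base, index / sampling_rate."""
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class OrientationCorrectedSignal:
    """Gravity-aligned acceleration components of one recording.

    ``vertical`` has gravity removed (zero mean); ``horizontal_ap`` and
    ``horizontal_ml`` are the two horizontal components. The rotation matrix
    and the estimated gravity magnitude are retained so the correction is
    exactly invertible.
    """

    vertical: np.ndarray
    horizontal_ap: np.ndarray
    horizontal_ml: np.ndarray
    sampling_rate: float
    source_id: str = "anonymous"
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    gravity_g: float = 1.0

    def inverse(self) -> np.ndarray:
        """Reconstruct the raw (n, 3) device-frame samples."""
        rotated = np.column_stack(
            [self.horizontal_ap, self.horizontal_ml, self.vertical + self.gravity_g]
        )
        return rotated @ self.rotation


def read_recording(
    path,
    sampling_rate: float = 32.0,
    sensor_height: float = 0.34,
    side: str = "left",
    subject_id: str | None = None,
    label: str = "unknown",
    sensor_sourced: bool = False,
) -> AccelerometerRecording:
    """Read a delimited text file with columns [time], ax, ay, az (units g).

    The delimiter (comma or tab) is sniffed. A ``time`` column, when present,
    is validated for uniform spacing (tolerance 10% of the sample period
    implied by ``sampling_rate``) and then discarded: the package's time base
    is always index / sampling_rate.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
        # round_trip parsing so write -> read is bit-identical
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise InputError(f"could not open {path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc

    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in AXIS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing axis column(s) {missing}")
    if len(df) < 2:
        raise InputError(f"{path}: fewer than 2 data rows")

    axes = np.empty((len(df), 3), dtype=float)
    for j, col in enumerate(AXIS_COLUMNS):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy() & df[col].notna().to_numpy())
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0]) if bad.size == 0 else int(bad[0])
            raise ParseError(f"{path}: non-numeric value in column {col!r} at data row {row}", row=row)
        axes[:, j] = converted.to_numpy()

    if "time" in df.columns:
        t = pd.to_numeric(df["time"], errors="coerce").to_numpy()
        if np.isnan(t).any():
            row = int(np.flatnonzero(np.isnan(t))[0])
            raise ParseError(f"{path}: non-numeric value in column 'time' at data row {row}", row=row)
        dt = np.diff(t)
        period = 1.0 / sampling_rate
        if np.any(np.abs(dt - period) > 0.1 * period):
            raise FormatError(
                f"{path}: time column is not uniform at {sampling_rate} Hz "
                f"(max deviation {np.max(np.abs(dt - period)):.4g} s)"
            )

    return AccelerometerRecording(
        samples=axes,
        sampling_rate=sampling_rate,
        sensor_height=sensor_height,
        side=side,
        subject_id=subject_id if subject_id is not None else path.stem,
        label=label,
        sensor_sourced=sensor_sourced,
    )


def write_recording(rec: AccelerometerRecording, path) -> None:
    """Write a recording back to delimited text (columns time, ax, ay, az).

    Values round-trip at full float precision.
    """
    df = pd.DataFrame(rec.samples, columns=list(AXIS_COLUMNS))
    df.insert(0, "time", rec.times)
    df.to_csv(path, index=False, float_format="%.17g")


def write_corrected(sig: OrientationCorrectedSignal, path) -> None:
    """Write an orientation-corrected signal (columns time, vertical, ap, ml)."""
    n = len(sig.vertical)
    df = pd.DataFrame(
        {
            "time": np.arange(n) / sig.sampling_rate,
            "vertical": sig.vertical,
            "ap": sig.horizontal_ap,
            "ml": sig.horizontal_ml,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _gravity_rotation(mean_vec: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ mean_vec = (0, 0, |mean_vec|).

    Two elementary rotations: about y to null the x component, then about x
    to null the y component. Both are orthonormal, so per-sample vector norms
    are preserved exactly.
    """
    mx, my, mz = mean_vec
    theta = np.arctan2(mx, mz)  # tilt in the x-z plane
    ry = np.array(
        [
            [np.cos(theta), 0.0, -np.sin(theta)],
            [0.0, 1.0, 0.0],
            [np.sin(theta), 0.0, np.cos(theta)],
        ]
    )
    v = ry @ mean_vec
    phi = np.arctan2(v[1], v[2])  # remaining tilt in the y-z plane
    rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(phi), -np.sin(phi)],
            [0.0, np.sin(phi), np.cos(phi)],
        ]
    )
    return rx @ ry


def realign_to_horizontal_vertical(rec: AccelerometerRecording) -> OrientationCorrectedSignal:
    """Rotate device axes so the recording-mean acceleration points vertically.

    During quasi-stationary wear the mean acceleration is dominated by
    gravity; aligning it with the vertical axis corrects sensor tilt. The
    gravity magnitude (the mean norm) is then subtracted from the vertical
    component, so all three returned series are zero-mean.

    Raises
    ------
    OrientationError
        If the mean acceleration norm is outside [0.5, 1.5] g — such a signal
        cannot serve as a quasi-static gravity reference.
    InputError
        If the recording is shorter than 2 s (tilt is estimated from the
        full-recording mean).
    """
    if rec.duration < 2.0:
        raise InputError(
            f"recording of {rec.duration:.2f} s is too short to estimate tilt (need >= 2 s)"
        )
    mean_vec = rec.samples.mean(axis=0)
    norm = float(np.linalg.norm(mean_vec))
    if not 0.5 <= norm <= 1.5:
        raise OrientationError(
            f"mean acceleration norm {norm:.3f} g outside [0.5, 1.5] g; "
            "signal is not a quasi-static gravity reference"
        )
    rot = _gravity_rotation(mean_vec)
    rotated = rec.samples @ rot.T
    vertical = rotated[:, 2]
    return OrientationCorrectedSignal(
        vertical=vertical - vertical.mean(),
        horizontal_ap=rotated[:, 0] - rotated[:, 0].mean(),
        horizontal_ml=rotated[:, 1] - rotated[:, 1].mean(),
        sampling_rate=rec.sampling_rate,
        source_id=rec.subject_id,
        rotation=rot,
        gravity_g=float(vertical.mean()),
    )


def lowpass_filter(
    x: np.ndarray, sampling_rate: float, order: int = 4, cutoff: float = 15.0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Forward-backward (``sosfiltfilt``) application keeps event timing
    unshifted, at the cost of squaring the magnitude response. DC gain is 1.

    At the study's 32 Hz sampling rate the 15 Hz default cutoff sits just
    below Nyquist; that is allowed but a warning is emitted because the
    transition band is effectively empty.
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(
            f"cutoff must be in (0, {nyquist}) Hz at {sampling_rate} Hz sampling; got {cutoff}"
        )
    if cutoff > 0.9 * nyquist:
        warnings.warn(
            f"cutoff {cutoff} Hz is within 10% of Nyquist ({nyquist} Hz); "
            "the filter has almost no stop band",
            UserWarning,
            stacklevel=2,
        )
    if x.ndim != 1:
        raise InputError("lowpass_filter expects a 1-D series")
    if len(x) <= 3 * order:
        raise InputError(f"series of length {len(x)} too short for order {order}")
    if not np.all(np.isfinite(x)):
        raise InputError("series contains non-finite values")
    sos = sps.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, x)
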