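"""Ground-truthed synthetic inputs: pendulum-kinematic walks and labeled cohorts.

Two generators are provided.

``simulate_walk`` builds a triaxial accelerometer recording from an explicit
vertical centre-of-mass trajectory: each step is a full-cosine arc of
peak-to-trough height D, so the vertical acceleration is its analytic second
derivative and the double-integration oracle is closed-form. A sharp
heel-strike transient is injected at every initial contact, gravity is added,
the whole triple is rotated by a sensor tilt and white noise is added. The
returned ground truth records the exact contact times, per-step excursions
and the summary the pipeline should recover.

``simulate_feature_cohort`` draws a labeled two-class 14-feature table from a
correlated multivariate normal, with a controllable standardized mean shift
on designated features, for classifier benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .parameters import (
    GaitSummary,
    PendulumConfig,
    step_length,
    stride_length,
    walking_speed,
)
from .signal_core import STANDARD_GRAVITY, AccelerometerRecording

#: Heel-strike transient shape: a symmetric 2nd-difference pattern (negative
#: centre, half-amplitude positive side lobes). Its 0th and 1st moments
#: vanish, so it carries no net impulse and only a one-sample-scale blip in
#: the doubly integrated displacement, while remaining clearly visible to the
#: Gaussian smoothing of the event detector.
_TRANSIENT_STENCIL = np.array([0.5, -1.0, 0.5])


@dataclass
class WalkSimulationSpec:
    """Conditions for one synthetic walk.

    Defaults emulate the study's recording setup: 32 Hz sampling, sensor
    0.34 m above ground, step times in the 0.5-0.6 s band, vertical
    excursions of a few millimetres, a modest mounting tilt, and the
    accelerometer noise floor.
    """

    n_steps: int = 30
    step_time_mean: float = 0.55
    step_time_sd: float = 0.02
    D_mean: float = 0.008
    D_sd: float = 0.002
    tilt_deg: float = 5.0
    noise_sd: float = 0.01
    sampling_rate: float = 32.0
    sensor_height: float = 0.34
    seed: int = 0
    ic_spike_g: float = 0.5
    lead_s: float = 1.5
    side: str = "left"
    subject_id: str = "synthetic"
    label: str = "unknown"

    def __post_init__(self):
        if self.n_steps < 3:
            raise ParameterError("n_steps must be >= 3")
        if self.step_time_mean <= 0:
            raise ParameterError("step_time_mean must be positive")
        if not 0 <= self.D_mean < 2 * self.sensor_height:
            raise ParameterError("D_mean must lie in [0, 2 * sensor_height)")
        if self.noise_sd < 0 or self.D_sd < 0 or self.step_time_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")


@dataclass
class WalkGroundTruth:
    """Exact contact times, per-step excursions/lengths and the true summary."""

    ic_times: np.ndarray
    step_times: np.ndarray
    D_values: np.ndarray
    step_lengths: np.ndarray
    summary: GaitSummary


def simulate_walk(
    spec: WalkSimulationSpec, pendulum: PendulumConfig | None = None
) -> tuple[AccelerometerRecording, WalkGroundTruth]:
    """Generate one walk and its ground truth. Same seed, same bits."""
    pendulum = pendulum or PendulumConfig(Wp=spec.sensor_height)
    rng = np.random.default_rng(spec.seed)

    step_t = rng.normal(spec.step_time_mean, spec.step_time_sd, spec.n_steps)
    step_t = np.clip(step_t, 0.3, None)  # keep steps physical and well separated
    d_vals = rng.normal(spec.D_mean, spec.D_sd, spec.n_steps)
    d_vals = np.clip(d_vals, 0.0, 1.9 * spec.sensor_height)

    ic_times = spec.lead_s + np.concatenate([[0.0], np.cumsum(step_t)])
    duration = ic_times[-1] + spec.lead_s
    fs = spec.sampling_rate
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    # analytic vertical acceleration of the per-step cosine arc, in m/s^2:
    # z(t) = (D/2) * (1 + cos(2*pi*(t - ic)/T))  =>  z'' = -(D/2)*(2*pi/T)^2*cos(...)
    # The sensor is lowest mid-step and the acceleration minimum sits exactly
    # at each initial contact, where the detector looks for it. Velocity is
    # continuous at the contacts (z' = 0 there), so the per-step excursion is
    # exactly D regardless of step-to-step variation.
    acc = np.zeros(n)
    k = np.searchsorted(ic_times, t, side="right") - 1
    walking = (k >= 0) & (k < spec.n_steps)
    kw = k[walking]
    omega = 2.0 * np.pi / step_t[kw]
    phase = omega * (t[walking] - ic_times[kw])
    acc[walking] = -0.5 * d_vals[kw] * omega**2 * np.cos(phase)
    vertical_g = acc / STANDARD_GRAVITY

    # heel-strike transient at the sample nearest each contact
    for ti in ic_times:
        c = int(round(ti * fs))
        if 1 <= c < n - 1:
            vertical_g[c - 1 : c + 2] += spec.ic_spike_g * _TRANSIENT_STENCIL

    body = np.zeros((n, 3))
    body[:, 2] = 1.0 + vertical_g  # gravity in g

    tilt = np.deg2rad(spec.tilt_deg)
    rot = np.array(
        [
            [np.cos(tilt), 0.0, np.sin(tilt)],
            [0.0, 1.0, 0.0],
            [-np.sin(tilt), 0.0, np.cos(tilt)],
        ]
    )
    samples = body @ rot.T
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, samples.shape)

    rec = AccelerometerRecording(
        samples=samples,
        sampling_rate=fs,
        sensor_height=spec.sensor_height,
        side=spec.side,
        subject_id=spec.subject_id,
        label=spec.label,
    )

    lengths = np.array([step_length(d, pendulum) for d in d_vals])
    avg_step_t = float(np.mean(step_t))
    avg_len = float(np.mean(lengths))
    truth = WalkGroundTruth(
        ic_times=ic_times,
        step_times=step_t,
        D_values=d_vals,
        step_lengths=lengths,
        summary=GaitSummary(
            avg_step_time=avg_step_t,
            avg_stride_time=float(np.mean(step_t[:-1] + step_t[1:])),
            avg_step_length=avg_len,
            avg_stride_length=stride_length(avg_len),
            walking_speed=walking_speed(avg_len, avg_step_t),
            n_steps=spec.n_steps,
            side=spec.side,
            subject_id=spec.subject_id,
        ),
    )
    return rec, truth


def simulate_walk_cohort(
    n_subjects: int = 51,
    n_fog: int = 36,
    n_steps: int = 30,
    noise_sd: float = 0.01,
    seed: int = 0,
    sampling_rate: float = 32.0,
    sensor_height: float = 0.34,
):
    """A cohort of subjects, each with left- and right-knee recordings.

    Subjects differ in their walking characteristics: per subject the mean
    step time is drawn uniformly from the 0.5-0.6 s band and the mean
    vertical excursion from 5-11 mm, then both knees are simulated at those
    conditions. Returns (recordings, reference, truths) where ``recordings``
    maps subject_id to its two recordings, ``reference`` is the ground-truth
    five-parameter table (side-averaged, the quantity a reference motion
    capture system would report), and ``truths`` maps subject_id to the two
    per-side ground truths.
    """
    import pandas as pd  # local to keep module import light

    rng = np.random.default_rng(seed)
    recordings, truths, ref_rows = {}, {}, []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        label = "FoG" if i < n_fog else "noFoG"
        subj_T = float(rng.uniform(0.50, 0.60))
        subj_D = float(rng.uniform(0.005, 0.011))
        recs, sides = [], []
        for side in ("left", "right"):
            spec = WalkSimulationSpec(
                n_steps=n_steps,
                step_time_mean=subj_T,
                D_mean=subj_D,
                noise_sd=noise_sd,
                sampling_rate=sampling_rate,
                sensor_height=sensor_height,
                seed=int(rng.integers(0, 2**31 - 1)),
                side=side,
                subject_id=sid,
                label=label,
            )
            rec, truth = simulate_walk(spec)
            recs.append(rec)
            sides.append(truth)
        recordings[sid] = recs
        truths[sid] = sides
        s0, s1 = sides[0].summary, sides[1].summary
        ref_rows.append(
            {
                "subject_id": sid,
                "label": label,
                "avg_step_time_s": 0.5 * (s0.avg_step_time + s1.avg_step_time),
                "avg_stride_time_s": 0.5 * (s0.avg_stride_time + s1.avg_stride_time),
                "avg_step_length_m": 0.5 * (s0.avg_step_length + s1.avg_step_length),
                "avg_stride_length_m": 0.5 * (s0.avg_stride_length + s1.avg_stride_length),
                "walking_speed_mps": 0.5 * (s0.walking_speed + s1.walking_speed),
            }
        )
    return recordings, pd.DataFrame(ref_rows), truths


#: Baseline (class 0 / no-FoG) feature means. The five gait features sit at
#: the cohort-mean scale reported for PD walking; signal features at values
#: typical of knee-worn accelerometry.
COHORT_BASELINE = {
    "avg_step_time": 0.53,
    "avg_stride_time": 1.17,
    "avg_step_length": 0.38,
    "avg_stride_length": 0.73,
    "walking_speed": 0.68,
    "sigma_x": 0.25,
    "sigma_y": 0.20,
    "sigma_z": 0.35,
    "S_xy": 0.10,
    "S_xz": 0.20,
    "S_yz": 0.15,
    "harmonic_x": 2.0,
    "harmonic_y": 2.0,
    "harmonic_z": 2.5,
}

#: Coefficient of variation used to derive feature standard deviations.
_COHORT_CV = 0.12

#: Features shifted by the class effect (the five spatiotemporal parameters).
DEFAULT_SHIFTED = (
    "avg_step_time",
    "avg_stride_time",
    "avg_step_length",
    "avg_stride_length",
    "walking_speed",
)

FEATURE_NAMES = tuple(COHORT_BASELINE)


def simulate_feature_cohort(
    n_per_class: tuple[int, int] = (36, 15),
    effect_size: float = 1.5,
    correlation: float = 0.3,
    seed: int = 0,
    shifted_features: tuple[str, ...] = DEFAULT_SHIFTED,
) -> pd.DataFrame:
    """Labeled two-class 14-feature cohort.

    Parameters
    ----------
    n_per_class
        (n_FoG, n_noFoG); defaults mirror the 36/15 study composition.
    effect_size
        Standardized mean shift applied to ``shifted_features`` for the FoG
        class (sign chosen so FoG walks slower: times up, lengths/speed down).
    correlation
        Exchangeable correlation among all 14 features, in [0, 0.9].
    seed
        Reproducibility seed; same seed, identical table.

    Returns
    -------
    DataFrame with columns ``subject_id``, the 14 features and ``label``
    ("FoG" / "noFoG").
    """
    n_fog, n_nofog = n_per_class
    if n_fog < 2 or n_nofog < 2:
        raise ParameterError("need at least 2 subjects per class")
    if not 0 <= correlation <= 0.9:
        raise ParameterError("correlation must lie in [0, 0.9]")
    unknown = set(shifted_features) - set(FEATURE_NAMES)
    if unknown:
        raise ParameterError(f"unknown shifted features: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    names = list(FEATURE_NAMES)
    means = np.array([COHORT_BASELINE[f] for f in names])
    sds = np.abs(means) * _COHORT_CV + 1e-3
    corr = np.full((14, 14), correlation)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)

    shift = np.zeros(14)
    for f in shifted_features:
        j = names.index(f)
        sign = 1.0 if "time" in f else -1.0  # slower gait: longer times, shorter/slower pace
        shift[j] = sign * effect_size * sds[j]

    x_fog = rng.multivariate_normal(means + shift, cov, size=n_fog, method="cholesky")
    x_nofog = rng.multivariate_normal(means, cov, size=n_nofog, method="cholesky")

    df = pd.DataFrame(np.vstack([x_fog, x_nofog]), columns=names)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n_fog + n_nofog)])
    df["label"] = ["FoG"] * n_fog + ["noFoG"] * n_nofog
    return df
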