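"""The 14-feature gait vector and its PCA augmentation to 28 dimensions.

Per subject the feature vector holds, in fixed order: the five spatiotemporal
gait parameters (average step/stride time, average step/stride length,
walking speed), the per-axis standard deviations of the raw acceleration,
the three pairwise zeroth-lag cross-correlation coefficients between raw
axes, and the three per-axis harmonic ratios (even-to-odd harmonic amplitude
composition at multiples of the stride frequency, a gait smoothness/symmetry
measure).

For classification the 14 features are augmented with all 14 principal
component scores, giving a 28-dimensional vector. The PCA transform
(standardization statistics and loadings) is fitted on training subjects
only and applied frozen elsewhere — no leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSignalError,
    InputError,
    ParameterError,
    UndefinedCorrelationError,
)
from .events import InitialContactSeries
from .parameters import GaitSummary
from .signal_core import AccelerometerRecording

#: Fixed feature order of the 14-dimensional vector.
FEATURE_ORDER = (
    "avg_step_time",
    "avg_stride_time",
    "avg_step_length",
    "avg_stride_length",
    "walking_speed",
    "sigma_x",
    "sigma_y",
    "sigma_z",
    "S_xy",
    "S_xz",
    "S_yz",
    "harmonic_x",
    "harmonic_y",
    "harmonic_z",
)


@dataclass
class FeatureConfig:
    """Feature-extraction knobs.

    n_harmonics
        Harmonics of the stride frequency considered in the harmonic ratio;
        automatically truncated below Nyquist (at 32 Hz and a typical stride
        frequency near 0.9 Hz roughly 17 harmonics are usable).
    ml_axis
        Which raw device axis plays the medio-lateral role: the harmonic
        ratio of the ML axis is conventionally odd/even instead of even/odd.
    """

    n_harmonics: int = 20
    ml_axis: str = "y"

    def __post_init__(self):
        if self.n_harmonics < 2:
            raise ParameterError("n_harmonics must be >= 2")
        if self.ml_axis not in ("x", "y", "z"):
            raise ParameterError("ml_axis must be one of 'x', 'y', 'z'")


@dataclass
class FeatureVector14:
    """One subject's 14 features, in the fixed order of FEATURE_ORDER."""

    values: np.ndarray
    subject_id: str = "anonymous"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (14,):
            raise InputError("a feature vector has exactly 14 values")
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature vector contains non-finite values")
        corr = self.values[8:11]
        if np.any(np.abs(corr) > 1 + 1e-12):
            raise InputError("cross-correlation features must lie in [-1, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_ORDER), name=self.subject_id)


def axis_std(rec: AccelerometerRecording) -> tuple[float, float, float]:
    """Sample standard deviation (n-1 denominator) of each raw axis, in g."""
    if len(rec) < 2:
        raise InputError("need at least 2 samples for a standard deviation")
    sd = rec.samples.std(axis=0, ddof=1)
    return float(sd[0]), float(sd[1]), float(sd[2])


def zero_lag_crosscorr(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized zero-lag cross-correlation of the mean-removed series.

    Equals the product-moment correlation coefficient; always in [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("series must be 1-D, equal length and of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation of a constant series is undefined")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def harmonic_ratio(
    signal: np.ndarray,
    stride_frequency: float,
    sampling_rate: float,
    n_harmonics: int = 20,
    axis_role: str = "vertical_or_ap",
) -> float:
    """Even/odd harmonic amplitude ratio at multiples of the stride frequency.

    The signal is split into consecutive one-stride windows (window length =
    round(sampling_rate / stride_frequency) samples, so the DFT bins fall on
    the stride harmonics); per window the amplitudes at harmonics
    k = 1..n_harmonics (truncated below Nyquist) are extracted and the ratio
    of even-harmonic to odd-harmonic amplitude sums formed. For the
    medio-lateral axis (``axis_role="ml"``) the orientation is reciprocal:
    odd/even, because ML acceleration repeats once per stride rather than
    once per step. Per-stride ratios are averaged over all complete strides.
    """
    signal = np.asarray(signal, dtype=float)
    if stride_frequency <= 0:
        raise ParameterError("stride_frequency must be positive")
    if axis_role not in ("vertical_or_ap", "ml"):
        raise ParameterError("axis_role must be 'vertical_or_ap' or 'ml'")
    window = int(round(sampling_rate / stride_frequency))
    if window < 4:
        raise ParameterError("stride window shorter than 4 samples")
    n_strides = len(signal) // window
    if n_strides < 1:
        raise InputError("signal does not cover one full stride")
    k_max = min(n_harmonics, window // 2)
    # keep harmonics strictly below Nyquist
    while k_max * stride_frequency >= sampling_rate / 2.0 and k_max > 1:
        k_max -= 1
    if k_max < 2:
        raise ParameterError("n_harmonics x stride_frequency must allow >= 2 harmonics below Nyquist")

    ratios = []
    for s in range(n_strides):
        seg = signal[s * window : (s + 1) * window]
        amps = np.abs(np.fft.rfft(seg))[1 : k_max + 1] * (2.0 / window)
        even = float(np.sum(amps[1::2]))  # harmonics 2, 4, ...
        odd = float(np.sum(amps[0::2]))  # harmonics 1, 3, ...
        num, den = (even, odd) if axis_role == "vertical_or_ap" else (odd, even)
        if den == 0:
            if num == 0:
                raise DegenerateSignalError("stride window has no harmonic content")
            ratios.append(np.inf)
        else:
            ratios.append(num / den)
    ratios = np.asarray(ratios)
    if np.any(np.isinf(ratios)):
        raise DegenerateSignalError("denominator harmonics have zero amplitude")
    return float(np.mean(ratios))


def assemble_features(
    summary: GaitSummary,
    rec: AccelerometerRecording,
    ics: InitialContactSeries,
    config: FeatureConfig | None = None,
) -> FeatureVector14:
    """Build one subject-side 14-feature vector in the fixed order.

    The five gait parameters come from ``summary``; signal features are
    computed on the raw device axes. The stride frequency for the harmonic
    ratios is 1 / avg_stride_time, and harmonic analysis starts at the first
    detected initial contact so windows are stride-aligned.
    """
    config = config or FeatureConfig()
    if summary.subject_id != rec.subject_id:
        raise InputError(
            f"summary is for {summary.subject_id!r} but recording is for {rec.subject_id!r}"
        )
    if len(ics) < 3:
        raise InputError("need >= 3 initial contacts to estimate the stride frequency")

    sigma = axis_std(rec)
    axes = {"x": rec.samples[:, 0], "y": rec.samples[:, 1], "z": rec.samples[:, 2]}
    corrs = {}
    for pair in (("x", "y"), ("x", "z"), ("y", "z")):
        try:
            corrs[pair] = zero_lag_crosscorr(axes[pair[0]], axes[pair[1]])
        except UndefinedCorrelationError as exc:
            const = [ax for ax in pair if np.ptp(axes[ax]) == 0]
            raise UndefinedCorrelationError(
                f"axis {'/'.join(const) or '/'.join(pair)} is constant; "
                f"S_{pair[0]}{pair[1]} undefined"
            ) from exc

    stride_freq = 1.0 / summary.avg_stride_time
    start = int(ics.ic_indices[0])
    harmonics = {}
    for ax in ("x", "y", "z"):
        role = "ml" if ax == config.ml_axis else "vertical_or_ap"
        harmonics[ax] = harmonic_ratio(
            axes[ax][start:], stride_freq, rec.sampling_rate, config.n_harmonics, role
        )

    values = np.array(
        [
            summary.avg_step_time,
            summary.avg_stride_time,
            summary.avg_step_length,
            summary.avg_stride_length,
            summary.walking_speed,
            *sigma,
            corrs[("x", "y")],
            corrs[("x", "z")],
            corrs[("y", "z")],
            harmonics["x"],
            harmonics["y"],
            harmonics["z"],
        ]
    )
    return FeatureVector14(values=values, subject_id=summary.subject_id)


@dataclass
class PCATransform:
    """Frozen standardization + loadings fitted on a training cohort."""

    means: np.ndarray
    scales: np.ndarray
    components: np.ndarray  # (14, 14), rows are loadings, orthonormal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    def scores(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.means) / self.scales
        return z @ self.components.T


@dataclass
class AugmentedFeatureMatrix:
    """n x 28 matrix: the 14 original features followed by 14 PC scores."""

    subject_ids: list
    values: np.ndarray
    fitted_transform: PCATransform

    def __post_init__(self):
        if self.values.shape[1] != 28:
            raise InputError("augmented matrix must have exactly 28 columns")

    @property
    def columns(self) -> list[str]:
        return list(FEATURE_ORDER) + [f"pc{i + 1}" for i in range(14)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.columns)


def _as_matrix(x) -> tuple[list, np.ndarray]:
    if isinstance(x, pd.DataFrame):
        cols = [c for c in x.columns if c in FEATURE_ORDER]
        if len(cols) == 14:
            x = x[list(FEATURE_ORDER)]
        ids = list(x.index)
        return ids, x.to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float)
    return list(range(len(arr))), arr


def fit_pca(train) -> PCATransform:
    """Fit standardization + full-rank PCA on a training feature matrix.

    Features are standardized (correlation-matrix PCA) because the 14
    features carry heterogeneous units. Loadings get a deterministic sign:
    the largest-magnitude loading of each component is made positive.
    """
    _, xt = _as_matrix(train)
    n, p = xt.shape
    if p != 14:
        raise InputError(f"training matrix must have 14 feature columns, got {p}")
    if n < p + 1:
        raise InputError(f"need at least 15 training rows for a 14-feature PCA, got {n}")
    means = xt.mean(axis=0)
    scales = xt.std(axis=0, ddof=1)
    if np.any(scales == 0):
        raise InputError("a training feature is constant; cannot standardize")
    z = (xt - means) / scales
    # SVD of the standardized training matrix gives loadings and variances
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    explained = s**2 / (n - 1)
    rank = int(np.linalg.matrix_rank(z))
    if rank < p:
        warnings.warn(
            f"training matrix has rank {rank} < 14; trailing components carry zero variance",
            UserWarning,
            stacklevel=2,
        )
    # deterministic sign convention
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    total = explained.sum()
    return PCATransform(
        means=means,
        scales=scales,
        components=vt,
        explained_variance=explained,
        explained_variance_ratio=explained / total,
    )


def pca_augment(train, apply=None) -> AugmentedFeatureMatrix:
    """Fit PCA on ``train`` and append all 14 scores to ``apply`` (default: train).

    The transform is frozen from the training matrix and applied unchanged,
    so validation rows never influence the standardization or the loadings.
    """
    transform = fit_pca(train)
    target = train if apply is None else apply
    ids, x = _as_matrix(target)
    if x.shape[1] != 14:
        raise InputError("apply matrix must have 14 feature columns")
    scores = transform.scores(x)
    return AugmentedFeatureMatrix(
        subject_ids=ids,
        values=np.hstack([x, scores]),
        fitted_transform=transform,
    )
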