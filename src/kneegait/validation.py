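"""Concurrent-validity statistics against a reference motion-capture table.

For each of the five gait parameters, the per-subject mean error rate
(percentage deviation of the accelerometer estimate from the reference) and
the Pearson correlation between the two systems' per-subject values are
computed — the agreement statistics of a concurrent validation study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DivisionError, InputError, JoinError, UndefinedCorrelationError

#: Canonical parameter columns of estimated/reference tables.
PARAMETER_COLUMNS = (
    "avg_step_time_s",
    "avg_stride_time_s",
    "avg_step_length_m",
    "avg_stride_length_m",
    "walking_speed_mps",
)


@dataclass
class ValidationResult:
    """Agreement statistics for one gait parameter across subjects."""

    parameter_name: str
    per_subject_error: np.ndarray  # percent
    mean_error: float  # percent
    sd_error: float  # percent, sample (n-1) SD; NaN when n < 2
    pearson_r: float
    n_subjects: int

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "mean_error_pct": self.mean_error,
            "sd_error_pct": self.sd_error,
            "pearson_r": self.pearson_r,
            "n": self.n_subjects,
        }


def mean_error_rate(
    estimated, reference, signed: bool = False
) -> tuple[np.ndarray, float, float]:
    """Per-subject percentage error of estimates against a reference.

    Per subject, 100 x |estimated - reference| / reference (the signed
    variant, available behind ``signed=True``, omits the absolute value).
    Returns (per-subject %, mean %, sample SD %); the SD is NaN for a single
    subject.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise InputError("estimated and reference must be 1-D and equally long")
    zero = np.flatnonzero(ref == 0)
    if zero.size:
        raise DivisionError(f"reference value is 0 for subject index(es) {list(zero)}")
    err = 100.0 * (est - ref) / ref
    if not signed:
        err = np.abs(err)
    sd = float(np.std(err, ddof=1)) if len(err) > 1 else float("nan")
    return err, float(np.mean(err)), sd


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two per-subject series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("inputs must be 1-D and equally long")
    if len(x) < 3:
        raise InputError("need at least 3 subjects for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant series is undefined")
    return float(stats.pearsonr(x, y).statistic)


def validation_report(
    estimated_table: pd.DataFrame,
    reference_table: pd.DataFrame,
    parameters=PARAMETER_COLUMNS,
    signed: bool = False,
) -> list[ValidationResult]:
    """One ValidationResult per gait parameter, subjects joined by id.

    Both tables must be indexed by (or contain a column) ``subject_id`` and
    carry the five parameter columns. Subjects present in only one table
    raise a JoinError listing the offending ids.
    """
    est = _indexed(estimated_table)
    ref = _indexed(reference_table)
    only_est = sorted(set(est.index) - set(ref.index))
    only_ref = sorted(set(ref.index) - set(est.index))
    if only_est or only_ref:
        raise JoinError(
            f"subjects only in estimated table: {only_est}; only in reference table: {only_ref}",
            subject_ids=only_est + only_ref,
        )
    est = est.sort_index()
    ref = ref.sort_index()
    missing = [p for p in parameters if p not in est.columns or p not in ref.columns]
    if missing:
        raise InputError(f"missing parameter column(s): {missing}")

    results = []
    for p in parameters:
        per, mean, sd = mean_error_rate(est[p].to_numpy(), ref[p].to_numpy(), signed=signed)
        r = pearson_correlation(est[p].to_numpy(), ref[p].to_numpy())
        results.append(
            ValidationResult(
                parameter_name=p,
                per_subject_error=per,
                mean_error=mean,
                sd_error=sd,
                pearson_r=r,
                n_subjects=len(per),
            )
        )
    return results


def _indexed(table: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    return table
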