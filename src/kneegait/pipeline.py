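"""End-to-end orchestration: recordings -> gait summaries -> endpoints.

Two endpoints are produced. The validation endpoint pushes every subject's
recordings through realignment, filtering, event detection and the pendulum
model, then compares the per-subject five-parameter table against a
reference-system table (mean error rate, Pearson r per parameter). The
classification endpoint runs the four-classifier stratified-split protocol
on a 14-feature table and reports per-simulation and mean metrics.

A subject failing any stage is logged and skipped; a pipeline run fails only
when every subject fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classify as cls
from .config import PipelineConfig
from .errors import KneegaitError
from .events import find_initial_contacts
from .parameters import combine_summaries, summarize_gait
from .signal_core import lowpass_filter, read_recording, realign_to_horizontal_vertical
from .validation import PARAMETER_COLUMNS, ValidationResult, validation_report

log = logging.getLogger(__name__)


def process_recording(rec, config: PipelineConfig):
    """One recording through realign -> filter -> events -> gait summary."""
    corrected = realign_to_horizontal_vertical(rec)
    filtered = lowpass_filter(corrected.vertical, rec.sampling_rate, **config.filter_kwargs)
    ics = find_initial_contacts(
        filtered,
        rec.sampling_rate,
        config.detection_config,
        side=rec.side,
        source_id=rec.subject_id,
    )
    summary, records = summarize_gait(
        ics,
        corrected.vertical,
        rec.sampling_rate,
        config.pendulum_config,
        config.gait_options,
    )
    log.info(
        "subject %s side %s: %d initial contacts, %d steps retained",
        rec.subject_id, rec.side, len(ics), summary.n_steps,
    )
    return summary, records, ics


@dataclass
class ValidationPipelineResult:
    results: list[ValidationResult]
    estimated_table: pd.DataFrame
    n_subjects: int
    skipped: list[str]


def summarize_subject_recordings(recs, config: PipelineConfig):
    """Combine one subject's per-side summaries (unweighted mean of sides)."""
    summaries = [process_recording(r, config)[0] for r in recs]
    if len(summaries) == 1:
        return summaries[0]
    combined = summaries[0]
    for s in summaries[1:]:
        combined = combine_summaries(combined, s)
    return combined


def run_validation_pipeline(
    config: PipelineConfig,
    recordings: dict[str, list] | None = None,
    reference_table: pd.DataFrame | None = None,
) -> ValidationPipelineResult:
    """Estimate the five parameters per subject and validate against a reference.

    ``recordings`` maps subject_id -> list of AccelerometerRecording (one per
    side); when omitted, files are read from ``io.recordings_dir`` (pattern
    ``<subject>_<side>.csv``). The reference table defaults to
    ``io.reference_table``.
    """
    if recordings is None:
        recordings = _load_recordings(config)
    if reference_table is None:
        ref_path = config.io["reference_table"]
        if ref_path is None:
            raise KneegaitError("no reference table supplied or configured")
        reference_table = pd.read_csv(ref_path)
    if not recordings:
        raise KneegaitError("no recordings found")

    rows, skipped = {}, []
    for subject_id, recs in recordings.items():
        try:
            summary = summarize_subject_recordings(recs, config)
            rows[subject_id] = [
                summary.avg_step_time,
                summary.avg_stride_time,
                summary.avg_step_length,
                summary.avg_stride_length,
                summary.walking_speed,
            ]
        except KneegaitError as exc:
            log.warning("subject %s skipped: %s", subject_id, exc)
            skipped.append(subject_id)
    if not rows:
        raise KneegaitError("all subjects failed; nothing to validate")

    est = pd.DataFrame.from_dict(rows, orient="index", columns=list(PARAMETER_COLUMNS))
    est.index.name = "subject_id"
    ref = reference_table
    if "subject_id" in ref.columns:
        ref = ref.set_index("subject_id")
    ref = ref.loc[[s for s in ref.index if s in est.index]]
    results = validation_report(est, ref)
    return ValidationPipelineResult(
        results=results, estimated_table=est, n_subjects=len(est), skipped=skipped
    )


def run_classification_pipeline(
    config: PipelineConfig, feature_table: pd.DataFrame | None = None
) -> list[cls.ClassificationReport]:
    """Four-classifier stratified-split protocol on a labeled feature table.

    The table needs the 14 feature columns plus a ``label`` column; the PCA
    augmentation to 28 dimensions is fitted inside each simulation on the
    training fold.
    """
    if feature_table is None:
        path = config.io["feature_table"]
        if path is None:
            raise KneegaitError("no feature table supplied or configured")
        feature_table = pd.read_csv(path)
    if "label" not in feature_table.columns:
        missing = feature_table.get("subject_id", pd.Series(range(len(feature_table))))
        raise KneegaitError(f"feature table lacks labels for subjects: {list(missing)[:5]}...")

    from .features import FEATURE_ORDER

    missing_cols = [c for c in FEATURE_ORDER if c not in feature_table.columns]
    if missing_cols:
        raise KneegaitError(f"feature table missing columns: {missing_cols}")
    labels = feature_table["label"].to_numpy()
    x = feature_table[list(FEATURE_ORDER)].to_numpy(dtype=float)
    settings = config.classify_settings
    return cls.run_simulations(
        x,
        labels,
        kinds=tuple(settings["classifiers"]),
        n_simulations=int(settings["n_simulations"]),
        base_seed=config.seed,
        train_fraction=float(settings["train_fraction"]),
    )


def write_reports(reports, out_dir) -> tuple[Path, Path]:
    """Serialize classification reports to JSON (full) and CSV (means)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jpath = out_dir / "classification_report.json"
    with open(jpath, "w") as fh:
        json.dump([r.as_dict() for r in reports], fh, indent=2)
    cpath = out_dir / "classification_means.csv"
    pd.DataFrame(
        [
            {
                "classifier": r.classifier_kind,
                "mean_accuracy_pct": r.mean_accuracy,
                "mean_sensitivity_pct": r.mean_sensitivity,
                "mean_specificity_pct": r.mean_specificity,
            }
            for r in reports
        ]
    ).to_csv(cpath, index=False)
    return jpath, cpath


def _load_recordings(config: PipelineConfig) -> dict[str, list]:
    rec_dir = config.io["recordings_dir"]
    if rec_dir is None:
        raise KneegaitError("io.recordings_dir not configured")
    rec_dir = Path(rec_dir)
    files = sorted(rec_dir.glob("*.csv"))
    if not files:
        raise KneegaitError(f"no recording files in {rec_dir}")
    recordings: dict[str, list] = {}
    for f in files:
        stem = f.stem
        if "_" in stem and stem.rsplit("_", 1)[1] in ("left", "right"):
            subject, side = stem.rsplit("_", 1)
        else:
            subject, side = stem, "left"
        rec = read_recording(
            f,
            sampling_rate=config.sampling_rate,
            sensor_height=config.sensor_height,
            side=side,
            subject_id=subject,
        )
        recordings.setdefault(subject, []).append(rec)
    return recordings
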