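"""End-to-end orchestration: files -> exposures -> units -> labels -> prevalence."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .accel_io import read_epoch_csv, to_minutes
from .compensation import build_units, classify_cohort, labels_to_frame
from .config import AnalysisConfig
from .errors import DataError
from .exposure import compute_exposures, exposures_to_frame
from .preprocessing import ValidityVerdict, day_wear_summary, detect_nonwear, validate_participant
from .summaries import prevalence

logger = logging.getLogger(__name__)

_NON_PARTICIPANT_FILES = {"manifest.csv", "participants.csv"}


def process_file(path: str | Path, cfg: AnalysisConfig | None = None):
    """One participant's file -> (exposures, validity verdict)."""
    cfg = cfg or AnalysisConfig()
    series = to_minutes(read_epoch_csv(path))
    mask = detect_nonwear(series, cfg.nonwear)
    records = day_wear_summary(series, mask)
    verdict = validate_participant(records, cfg.validity)
    exposures = compute_exposures(series, mask, cfg.cuts, cfg.min_segment_wear_min)
    return exposures, verdict


def process_directory(input_dir: str | Path, cfg: AnalysisConfig | None = None):
    """All participant CSVs of a directory -> (exposure table, verdicts)."""
    cfg = cfg or AnalysisConfig()
    input_dir = Path(input_dir)
    files = sorted(
        p for p in input_dir.glob("*.csv") if p.name not in _NON_PARTICIPANT_FILES
    )
    if not files:
        raise DataError(f"no participant CSV files found in {input_dir}")
    all_exposures = []
    verdicts: list[ValidityVerdict] = []
    for path in files:
        exposures, verdict = process_file(path, cfg)
        all_exposures.extend(exposures)
        verdicts.append(verdict)
        if not verdict.valid:
            logger.info("participant %s excluded: %s", verdict.participant_id, verdict.reason)
    return exposures_to_frame(all_exposures), verdicts


def verdicts_to_frame(verdicts: list[ValidityVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": v.participant_id,
                "valid": v.valid,
                "reason": v.reason or "",
                "n_valid_weekdays": v.n_valid_weekdays,
                "n_valid_weekend_days": v.n_valid_weekend_days,
            }
            for v in verdicts
        ]
    )


def classify_exposures(
    exposures: pd.DataFrame,
    verdicts: list[ValidityVerdict],
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Build comparison units and classify them; returns a result bundle."""
    cfg = cfg or AnalysisConfig()
    obs_points, week_summaries = build_units(
        exposures,
        verdicts,
        min_weekdays=cfg.validity.min_weekdays,
        min_weekend_days=cfg.validity.min_weekend_days,
    )
    logger.info(
        "comparison units: %d observation points, %d girl weeks",
        len(obs_points),
        len(week_summaries),
    )
    obs_labels, week_labels, sd_obs, sd_week = classify_cohort(
        obs_points, week_summaries, cfg.threshold
    )
    return {
        "obs_points": obs_points,
        "week_summaries": week_summaries,
        "obs_labels": obs_labels,
        "week_labels": week_labels,
        "sd_obs": sd_obs,
        "sd_week": sd_week,
        "labels": labels_to_frame(obs_labels + week_labels),
    }


def run_pipeline(
    input_dir: str | Path, out_dir: str | Path, cfg: AnalysisConfig | None = None
) -> dict:
    """Process a cohort directory and write all standard outputs."""
    cfg = cfg or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposures, verdicts = process_directory(input_dir, cfg)
    exposures.to_csv(out_dir / "exposures.csv", index=False)
    verdicts_to_frame(verdicts).to_csv(out_dir / "validity.csv", index=False)
    result = classify_exposures(exposures, verdicts, cfg)
    result["labels"].to_csv(out_dir / "labels.csv", index=False)
    reports = {}
    for analysis, labels in (("observation", result["obs_labels"]), ("week", result["week_labels"])):
        if labels:
            report = prevalence(labels)
            reports[analysis] = report
            with open(out_dir / f"prevalence_{analysis}.json", "w", encoding="utf-8") as fh:
                json.dump(report.to_dict(), fh, indent=2)
    result["prevalence"] = reports
    return result


def recovery_table(labels: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per (analysis, planted class): n units, n recovered, recovery %.

    Joins pipeline labels with a generator ground-truth manifest on
    (analysis, participant, date).
    """
    lab = labels.copy()
    man = manifest.copy()
    for frame in (lab, man):
        frame["date"] = frame["date"].fillna("").astype(str)
    merged = man.merge(
        lab[["analysis", "participant_id", "date", "label"]],
        on=["analysis", "participant_id", "date"],
        how="left",
    )
    merged["recovered"] = merged["label"] == merged["planted"]
    rows = []
    for (analysis, planted), grp in merged.groupby(["analysis", "planted"], sort=True):
        rows.append(
            {
                "analysis": analysis,
                "planted": planted,
                "n": len(grp),
                "n_recovered": int(grp["recovered"].sum()),
                "recovery_pct": 100.0 * grp["recovered"].mean(),
            }
        )
    return pd.DataFrame(rows)
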