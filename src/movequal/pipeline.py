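"""End-to-end study orchestration.

Per subject: segment both trials, derive the person-specific sample-entropy
tolerance (0.2 x SD of the baseline movement-only norm), compute the
baseline profile with it and — crucially — the follow-up profile with the
*same* baseline-anchored tolerance.  Subjects failing eligibility (baseline
Quick DASH >= 15) or lacking a timepoint are excluded with a log entry;
individual metric failures are isolated per metric so one degenerate
computation never voids a subject's remaining parameters.  Cohort
statistics then run on the included subjects, and every parameter choice is
captured in a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ImuTrial,
    PromRecord,
    read_trial,
    read_prom_table,
    QUICKDASH_INCLUSION_MAX,
)
from .segmentation import SegmentationConfig, SegmentationError, segment_trial
from .metrics import (
    METRIC_NAMES,
    MetricError,
    MovementQualityProfile,
    compute_profile,
    tolerance_from_baseline,
)
from .stats import CohortStats, run_group_analysis, normality_report
from .synthetic import SyntheticCohortConfig, generate_cohort

__all__ = ["SubjectRecord", "RunManifest", "run_subject", "run_study"]

log = logging.getLogger("movequal")


@dataclass
class SubjectRecord:
    """Paired baseline/follow-up movement-quality profiles + PROMs."""

    subject_id: str
    baseline: MovementQualityProfile | None = None
    followup: MovementQualityProfile | None = None
    tolerance_r: float | None = None
    baseline_quickdash: float | None = None
    followup_quickdash: float | None = None
    baseline_pain: int | None = None
    followup_pain: int | None = None
    included: bool = True
    exclusion_reason: str | None = None


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    version: str = "0.1.0"
    seed: int | None = None
    alpha: float = 0.05
    segmentation: dict = field(default_factory=dict)
    synthetic: dict | None = None
    subjects: dict = field(default_factory=dict)
    log_entries: list = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def run_subject(
    trial_baseline: ImuTrial,
    trial_followup: ImuTrial,
    proms: dict[str, PromRecord] | None = None,
    config: SegmentationConfig | None = None,
) -> SubjectRecord:
    """Analyse one subject's two trials into a :class:`SubjectRecord`.

    Segmentation or tolerance failures flag the subject as excluded (with
    the reason) rather than raising; metric-level failures surface as NaN
    in the profiles.
    """
    record = SubjectRecord(subject_id=trial_baseline.subject_id)
    if proms:
        if "baseline" in proms:
            record.baseline_quickdash = proms["baseline"].quickdash_total
            record.baseline_pain = proms["baseline"].pain_item9
            if proms["baseline"].quickdash_total >= QUICKDASH_INCLUSION_MAX:
                record.included = False
                record.exclusion_reason = (
                    f"baseline Quick DASH {proms['baseline'].quickdash_total:g} "
                    f">= {QUICKDASH_INCLUSION_MAX:g}"
                )
        if "followup" in proms:
            record.followup_quickdash = proms["followup"].quickdash_total
            record.followup_pain = proms["followup"].pain_item9
    try:
        seg_base = segment_trial(trial_baseline, config)
        seg_follow = segment_trial(trial_followup, config)
        record.tolerance_r = tolerance_from_baseline(seg_base.concat_norm)
    except (SegmentationError, MetricError) as exc:
        record.included = False
        record.exclusion_reason = str(exc)
        log.warning("subject %s excluded: %s", record.subject_id, exc)
        return record
    fs = trial_baseline.sample_rate_hz
    record.baseline = compute_profile(seg_base, fs, tolerance_r=record.tolerance_r)
    record.followup = compute_profile(
        seg_follow, trial_followup.sample_rate_hz, tolerance_r=record.tolerance_r
    )
    return record


def _metrics_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy per-subject metric table (long format, one row per value)."""
    rows = []
    for r in records:
        for timepoint, prof in (("baseline", r.baseline), ("followup", r.followup)):
            if prof is None:
                continue
            d = prof.as_dict()
            for name in METRIC_NAMES:
                rows.append(
                    {
                        "subject_id": r.subject_id,
                        "timepoint": timepoint,
                        "metric": name,
                        "value": d[name],
                        "tolerance_r": d.get("tolerance_r"),
                        "dominant_freq_hz": d.get("dominant_freq_hz"),
                        "time_lag": d.get("time_lag"),
                        "embedding_dim": d.get("embedding_dim"),
                        "fit_start": d.get("fit_start"),
                        "fit_end": d.get("fit_end"),
                        "included": r.included,
                    }
                )
    return pd.DataFrame(rows)


def run_study(
    input_dir: str | Path | None = None,
    synthetic_config: SyntheticCohortConfig | None = None,
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
    seg_config: SegmentationConfig | None = None,
    holm: bool = False,
) -> tuple[CohortStats, list[SubjectRecord], RunManifest]:
    """Run the full study on a directory of trials or a synthetic cohort.

    ``input_dir`` must contain ``<subject>_<timepoint>.csv`` trial files and
    a ``proms.csv`` table; alternatively a :class:`SyntheticCohortConfig`
    generates the cohort in memory.  Writes ``metrics.csv``,
    ``paired_tests.csv``, ``correlations.csv``, ``normality.csv`` and
    ``manifest.json`` into ``out_dir`` when given.
    """
    if (input_dir is None) == (synthetic_config is None):
        raise ValueError("provide exactly one of input_dir or synthetic_config")
    seg_config = seg_config or SegmentationConfig()
    manifest = RunManifest(alpha=alpha, segmentation=seg_config.to_dict())

    trials: dict[tuple[str, str], ImuTrial] = {}
    prom_map: dict[tuple[str, str], PromRecord] = {}
    if synthetic_config is not None:
        manifest.seed = synthetic_config.seed
        manifest.synthetic = synthetic_config.to_dict()
        trials, proms, _ = generate_cohort(synthetic_config)
        prom_map = {(p.subject_id, p.timepoint): p for p in proms}
    else:
        input_dir = Path(input_dir)
        bad: list[str] = []
        for path in sorted(input_dir.glob("*_*.csv")):
            stem = path.stem
            sid, _, timepoint = stem.rpartition("_")
            if timepoint not in ("baseline", "followup"):
                continue
            try:
                trials[(sid, timepoint)] = read_trial(
                    path, subject_id=sid, timepoint=timepoint
                )
            except Exception as exc:  # enumerate unreadable inputs, then abort
                bad.append(f"{path.name}: {exc}")
        if bad:
            raise ValueError("unreadable trial files:\n" + "\n".join(bad))
        prom_path = input_dir / "proms.csv"
        if prom_path.exists():
            prom_map = {
                (p.subject_id, p.timepoint): p for p in read_prom_table(prom_path)
            }

    subject_ids = sorted({sid for sid, _ in trials})
    records: list[SubjectRecord] = []
    for sid in subject_ids:
        base = trials.get((sid, "baseline"))
        follow = trials.get((sid, "followup"))
        if base is None or follow is None:
            records.append(
                SubjectRecord(
                    subject_id=sid, included=False,
                    exclusion_reason="missing timepoint",
                )
            )
            manifest.log_entries.append(f"{sid}: missing timepoint, excluded")
            continue
        proms = {
            tp: prom_map[(sid, tp)]
            for tp in ("baseline", "followup")
            if (sid, tp) in prom_map
        }
        rec = run_subject(base, follow, proms, seg_config)
        if not rec.included:
            manifest.log_entries.append(f"{sid}: excluded ({rec.exclusion_reason})")
        records.append(rec)
        if rec.baseline is not None and rec.baseline.recon is not None:
            manifest.subjects[sid] = {
                "tolerance_r": rec.tolerance_r,
                "baseline_recon": asdict(rec.baseline.recon),
            }

    stats = run_group_analysis(records, alpha=alpha, holm=holm)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_df = _metrics_frame(records)
        metrics_df.to_csv(out_dir / "metrics.csv", index=False)
        stats.paired_frame().to_csv(out_dir / "paired_tests.csv", index=False)
        stats.correlation_frame().to_csv(out_dir / "correlations.csv", index=False)
        by_var = {
            f"{row.metric}_{row.timepoint}": grp["value"].to_numpy()
            for (row), grp in (
                (g.iloc[0], g)
                for _, g in metrics_df.groupby(["metric", "timepoint"])
            )
        }
        normality_report(by_var).to_csv(out_dir / "normality.csv", index=False)
        manifest.write(out_dir / "manifest.json")
    return stats, records, manifest
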