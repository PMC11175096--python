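"""Reading and writing wrist-IMU trials and PROM tables.

Trials are plain CSV with a header row and columns
``time, ax, ay, az, gx, gy, gz`` — time in seconds from trial start,
acceleration in m/s^2 (raw accelerometer output, gravity included) and
angular velocity in rad/s, both in the sensor frame.  The sensor sits at the
distal end of the forearm on the operated side.  PROM tables are CSV with
``subject_id, timepoint, quickdash_total, pain_item9`` (Quick DASH total on
0–100, its pain item 9 on 1–5).

Indices in external reports are 1-based inclusive sample numbers; everything
internal is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImuTrial",
    "PromRecord",
    "TrialFormatError",
    "TrialValidationError",
    "PromRangeError",
    "InclusionRuleWarning",
    "TRIAL_COLUMNS",
    "read_trial",
    "write_trial",
    "read_prom_table",
    "write_prom_table",
]

TRIAL_COLUMNS = ("time", "ax", "ay", "az", "gx", "gy", "gz")

#: Baseline Quick DASH must be below this for a subject to be included
#: (no pre-existing self-reported disability).
QUICKDASH_INCLUSION_MAX = 15.0

TIMEPOINTS = ("baseline", "followup")


class TrialFormatError(ValueError):
    """A trial file does not have the expected columns/layout."""


class TrialValidationError(ValueError):
    """A trial's data violate the ImuTrial invariants."""


class PromRangeError(ValueError):
    """A PROM value is outside its instrument range."""


class InclusionRuleWarning(UserWarning):
    """Baseline Quick DASH at or above the inclusion cut-off."""


@dataclass
class ImuTrial:
    """One subject/timepoint recording: synchronized accelerometer + gyroscope.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier.
    timepoint : str
        ``"baseline"`` (pre-surgery) or ``"followup"`` (post-surgery).
    sample_rate_hz : float
        Nominal sampling rate; the study device records at 60 Hz.
    t : ndarray
        Time in seconds from trial start, strictly increasing, nominal
        spacing ``1/sample_rate_hz`` within 1% jitter.
    accel_xyz : ndarray, shape (n, 3)
        Raw accelerometer output in m/s^2 (gravity included), sensor frame.
    gyro_xyz : ndarray, shape (n, 3)
        Angular velocity in rad/s, sensor frame.
    meta : dict
        Free-form metadata (task, load_kg, operated side, ...).
    """

    subject_id: str
    timepoint: str
    sample_rate_hz: float
    t: np.ndarray
    accel_xyz: np.ndarray
    gyro_xyz: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel_xyz = np.asarray(self.accel_xyz, dtype=float)
        self.gyro_xyz = np.asarray(self.gyro_xyz, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise TrialValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if not self.sample_rate_hz > 0:
            raise TrialValidationError("sample_rate_hz must be positive")
        n = len(self.t)
        if n < 2:
            raise TrialValidationError("trial must contain at least 2 samples")
        for name, arr in (("accel_xyz", self.accel_xyz), ("gyro_xyz", self.gyro_xyz)):
            if arr.shape != (n, 3):
                raise TrialValidationError(
                    f"{name} must have shape ({n}, 3), got {arr.shape}"
                )
            bad = ~np.isfinite(arr)
            if bad.any():
                row = int(np.argwhere(bad)[0, 0])
                raise TrialValidationError(f"non-finite sample in {name} at row {row}")
        if not np.isfinite(self.t).all():
            row = int(np.flatnonzero(~np.isfinite(self.t))[0])
            raise TrialValidationError(f"non-finite time at row {row}")
        dt = np.diff(self.t)
        if not (dt > 0).all():
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise TrialValidationError(f"time not strictly increasing at row {row}")
        nominal = 1.0 / self.sample_rate_hz
        if np.abs(dt - nominal).max() > 0.01 * nominal + 1e-12:
            raise TrialValidationError(
                "sample spacing deviates from nominal by more than 1%"
            )


@dataclass(frozen=True)
class PromRecord:
    """Patient-reported outcomes at one timepoint.

    ``quickdash_total`` is the Quick DASH score (0 = no disability, 100 =
    maximal); ``pain_item9`` is its pain-severity item on 1 (none) – 5
    (extreme).  ``excluded`` flags a baseline record violating the
    no-baseline-disability inclusion rule (Quick DASH >= 15).
    """

    subject_id: str
    timepoint: str
    quickdash_total: float
    pain_item9: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise PromRangeError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if not 0.0 <= self.quickdash_total <= 100.0:
            raise PromRangeError(
                f"quickdash_total must be in [0, 100], got {self.quickdash_total}"
            )
        if self.pain_item9 not in (1, 2, 3, 4, 5):
            raise PromRangeError(
                f"pain_item9 must be an integer in 1..5, got {self.pain_item9}"
            )


def _infer_sample_rate(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def read_trial(
    path: str | Path,
    subject_id: str | None = None,
    timepoint: str = "baseline",
    column_map: Mapping[str, str] | None = None,
) -> ImuTrial:
    """Read a trial CSV into a validated :class:`ImuTrial`.

    The sample rate is inferred from the median time step.  ``column_map``
    maps the canonical names (``time, ax, ...``) to the names used in the
    file, to accommodate other sensor exports.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    colmap = {c: c for c in TRIAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise TrialFormatError(f"{path.name}: missing column {actual!r}")
    t = df[colmap["time"]].to_numpy(dtype=float)
    accel = df[[colmap[c] for c in ("ax", "ay", "az")]].to_numpy(dtype=float)
    gyro = df[[colmap[c] for c in ("gx", "gy", "gz")]].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrialValidationError(f"{path.name}: trial must contain at least 2 samples")
    return ImuTrial(
        subject_id=subject_id if subject_id is not None else path.stem,
        timepoint=timepoint,
        sample_rate_hz=_infer_sample_rate(t),
        t=t,
        accel_xyz=accel,
        gyro_xyz=gyro,
        meta={"source": str(path)},
    )


def write_trial(trial: ImuTrial, path: str | Path, precision: int = 9) -> Path:
    """Write a trial as CSV readable by :func:`read_trial` (lossless at
    ``precision`` decimal digits)."""
    trial.validate()
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": trial.t,
            "ax": trial.accel_xyz[:, 0],
            "ay": trial.accel_xyz[:, 1],
            "az": trial.accel_xyz[:, 2],
            "gx": trial.gyro_xyz[:, 0],
            "gy": trial.gyro_xyz[:, 1],
            "gz": trial.gyro_xyz[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{precision}g")
    return path


def read_prom_table(path: str | Path) -> list[PromRecord]:
    """Read and validate a PROM CSV; returns one record per row.

    Out-of-range values raise :class:`PromRangeError`.  A baseline row with
    Quick DASH >= 15 violates the cohort inclusion rule: it is kept but
    flagged ``excluded=True`` and a warning is emitted (eligibility screening
    happens at the pipeline level, not here).
    """
    df = pd.read_csv(path, comment="#")
    required = ("subject_id", "timepoint", "quickdash_total", "pain_item9")
    for col in required:
        if col not in df.columns:
            raise TrialFormatError(f"{Path(path).name}: missing column {col!r}")
    records: list[PromRecord] = []
    for _, row in df.iterrows():
        pain = row["pain_item9"]
        if float(pain) != int(pain):
            raise PromRangeError(f"pain_item9 must be an integer, got {pain}")
        excluded = False
        if (
            row["timepoint"] == "baseline"
            and float(row["quickdash_total"]) >= QUICKDASH_INCLUSION_MAX
        ):
            excluded = True
            warnings.warn(
                f"subject {row['subject_id']}: baseline Quick DASH "
                f"{row['quickdash_total']} violates inclusion rule (< "
                f"{QUICKDASH_INCLUSION_MAX:g})",
                InclusionRuleWarning,
                stacklevel=2,
            )
        records.append(
            PromRecord(
                subject_id=str(row["subject_id"]),
                timepoint=str(row["timepoint"]),
                quickdash_total=float(row["quickdash_total"]),
                pain_item9=int(pain),
                excluded=excluded,
            )
        )
    return records


def write_prom_table(records: Sequence[PromRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "timepoint": r.timepoint,
                "quickdash_total": r.quickdash_total,
                "pain_item9": r.pain_item9,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path
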