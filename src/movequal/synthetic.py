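"""Synthetic cohorts emulating the reaching-task study conditions.

The study's raw recordings cannot be shared, so this module generates
cohorts with the statistical structure the analysis pipeline assumes:

* **Trials** — 14 pseudo-cyclic repetitions at 60 Hz, each a minimum-jerk
  up-and-back movement of 5/3 s (≈ 100 samples), separated by 1 s rests in
  which the angular velocity is exactly zero.  Gravity sits on a fixed
  sensor axis (the norm is all the analysis uses, so no orientation
  dynamics are simulated).  Controllable degradations target one metric
  each: per-repetition amplitude jitter (variability / entropy), a
  high-frequency ripple (smoothness), alternating-cycle scaling (symmetry)
  and smooth random waveform perturbations (local dynamic stability).
  Gaussian measurement noise is added to the accelerometer channels;
  angular velocity stays exactly zero at rest so the rest/movement ground
  truth is unambiguous.

* **PROMs** — Quick DASH totals drawn from the cohort's observed
  distributions (pre 3.35 ± 4.36, post 18.59 ± 17.44) and pain item 9 from
  a rounded latent normal (pre 1.1 ± 0.3, post 1.9 ± 1.0).  In ``clip``
  mode values are clamped to the instrument ranges and baseline scores
  rejection-sampled below the < 15 inclusion cut-off; ``none`` mode returns
  the latent draws for distribution-recovery testing.

All randomness flows from one root seed through ``numpy`` SeedSequence
spawning, so identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io import ImuTrial, PromRecord, write_trial, write_prom_table

__all__ = [
    "SyntheticCohortConfig",
    "SubjectParams",
    "minimum_jerk_pulse",
    "generate_trial",
    "generate_prom",
    "generate_cohort",
]

GRAVITY = 9.81  # m/s^2, placed on the sensor z axis


@dataclass
class SubjectParams:
    """Per-subject, per-timepoint movement-degradation knobs.

    Each knob drives one movement-quality metric:
    ``amplitude_jitter`` — SD of the per-repetition amplitude factor
    (raises variability and sample entropy); ``ripple_amp`` — depth of a
    multiplicative 6 Hz modulation of the movement acceleration (lowers
    LDLJ);
    ``alternation_factor`` — relative shrinkage of every second repetition
    (lowers the symmetry autocorrelation peak); ``perturbation_sd`` —
    relative SD of a smooth (low-pass) random waveform perturbation
    (raises the Lyapunov exponent).
    """

    amplitude_jitter: float = 0.0
    ripple_amp: float = 0.0
    alternation_factor: float = 0.0
    perturbation_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amplitude_jitter", "ripple_amp", "perturbation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.alternation_factor < 1:
            raise ValueError("alternation_factor must be in [0, 1)")


@dataclass
class SyntheticCohortConfig:
    """Study-condition constants and cohort-level distributions.

    Task constants mirror the protocol: 30 subjects, 14 repetitions at
    60 Hz, one repetition ≈ 100 samples (5/3 s) so a trial yields ≈ 1400
    movement samples, load 0.5 kg.  PROM distribution parameters are the
    cohort's published mean ± SD at each timepoint.  ``effects`` holds the
    pre→post additive shifts applied to each degradation knob at follow-up
    (empty = null cohort, baseline and follow-up exchangeable).
    """

    n_subjects: int = 30
    n_reps: int = 14
    sample_rate_hz: float = 60.0
    rep_duration_s: float = 5.0 / 3.0
    rest_duration_s: float = 1.0
    accel_amplitude: float = 3.0  # m/s^2 peak movement acceleration
    gyro_amplitude: float = 2.0  # rad/s peak angular velocity
    noise_sd_frac: float = 0.01
    baseline_params: SubjectParams = field(default_factory=SubjectParams)
    effects: dict[str, float] = field(default_factory=dict)
    quickdash_mean: dict[str, float] = field(
        default_factory=lambda: {"baseline": 3.35, "followup": 18.59}
    )
    quickdash_sd: dict[str, float] = field(
        default_factory=lambda: {"baseline": 4.36, "followup": 17.44}
    )
    pain_mean: dict[str, float] = field(
        default_factory=lambda: {"baseline": 1.1, "followup": 1.9}
    )
    pain_sd: dict[str, float] = field(
        default_factory=lambda: {"baseline": 0.3, "followup": 1.0}
    )
    clip_mode: Literal["none", "clip"] = "clip"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.rep_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.rep_duration_s * self.sample_rate_hz < 4:
            raise ValueError("repetition shorter than 4 samples is non-physical")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")

    @property
    def rep_samples(self) -> int:
        return int(round(self.rep_duration_s * self.sample_rate_hz))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration_s * self.sample_rate_hz))

    def params_for(self, timepoint: str) -> SubjectParams:
        """Degradation knobs at a timepoint (baseline + effects at followup)."""
        if timepoint == "baseline" or not self.effects:
            return self.baseline_params
        kwargs = asdict(self.baseline_params)
        for k, v in self.effects.items():
            if k not in kwargs:
                raise ValueError(f"unknown effect target {k!r}")
            kwargs[k] = max(0.0, kwargs[k] + v)
        return SubjectParams(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def minimum_jerk_pulse(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration shapes of a minimum-jerk stroke.

    ``phase`` in [0, 1] is normalized stroke time.  Returns the classic
    quintic profiles v(p) = 30 p^2 (1-p)^2 and a(p) = 60 p - 180 p^2 +
    120 p^3 (unit displacement, unit duration).
    """
    p = np.asarray(phase, dtype=float)
    v = 30.0 * p**2 * (1.0 - p) ** 2
    a = 60.0 * p - 180.0 * p**2 + 120.0 * p**3
    return v, a


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float = 3.0):
    """Band-limited unit-variance noise (FFT low-pass of white noise)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[freqs > cutoff] = 0.0
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_trial(
    config: SyntheticCohortConfig,
    params: SubjectParams | None = None,
    subject_id: str = "S01",
    timepoint: str = "baseline",
    seed: int | np.random.SeedSequence | None = None,
) -> ImuTrial:
    """One synthetic trial: rest, then n_reps minimum-jerk up-and-back
    repetitions separated by rests, then a final rest.

    Each repetition is an up stroke followed by a down stroke (half the
    repetition each).  Angular velocity follows the stroke speed on one
    gyro axis and is exactly zero during rests; movement acceleration
    follows the stroke acceleration on the x axis with a fixed gravity
    offset on z.  Sampling inside a repetition is cell-centred (phase
    (k + 1/2)/n) so every movement sample has strictly nonzero angular
    velocity — the segmentation ground truth is exactly ``rep_samples``
    samples per repetition.
    """
    if params is None:
        params = config.params_for(timepoint)
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    fs = config.sample_rate_hz
    n_rep = config.rep_samples
    n_rest = config.rest_samples
    n_total = n_rest + config.n_reps * (n_rep + n_rest)

    accel = np.zeros((n_total, 3))
    gyro = np.zeros((n_total, 3))
    accel[:, 2] = GRAVITY

    half = n_rep / 2.0
    local = np.arange(n_rep) + 0.5  # cell-centred sample positions in the rep
    up = local < half
    stroke_phase = np.where(up, local / half, (local - half) / half)
    v_shape, a_shape = minimum_jerk_pulse(stroke_phase)
    a_shape = np.where(up, a_shape, -a_shape)  # return stroke decelerates back

    t_rep = local / fs
    for k in range(config.n_reps):
        start = n_rest + k * (n_rep + n_rest)
        amp = 1.0 + params.amplitude_jitter * rng.standard_normal()
        if params.alternation_factor and k % 2 == 1:
            amp *= 1.0 - params.alternation_factor
        a_move = config.accel_amplitude * amp * a_shape
        w_move = config.gyro_amplitude * amp * v_shape
        if params.ripple_amp:
            # multiplicative 6 Hz modulation: raises squared jerk roughly
            # with (ripple_amp * 2 pi f)^2 while leaving the acceleration
            # peak nearly unchanged, a clean smoothness degradation
            a_move = a_move * (1.0 + params.ripple_amp * np.sin(2 * np.pi * 6.0 * t_rep))
        if params.perturbation_sd:
            pert = _smooth_noise(rng, n_rep, fs)
            a_move = a_move + params.perturbation_sd * config.accel_amplitude * (
                v_shape * pert
            )
        sl = slice(start, start + n_rep)
        # movement acceleration mostly along the gravity axis: the norm's
        # gravity cross-term then varies linearly with the movement, as a
        # wrist sensor's norm does, instead of rectifying a transverse
        # component
        accel[sl, 0] += 0.45 * a_move
        accel[sl, 1] += 0.25 * a_move
        accel[sl, 2] += 0.85 * a_move
        gyro[sl, 1] = w_move
    if config.noise_sd_frac:
        accel += (
            config.noise_sd_frac
            * config.accel_amplitude
            * rng.standard_normal(accel.shape)
        )
    t = np.arange(n_total) / fs
    return ImuTrial(
        subject_id=subject_id,
        timepoint=timepoint,
        sample_rate_hz=fs,
        t=t,
        accel_xyz=accel,
        gyro_xyz=gyro,
        meta={
            "task": "cyclic weighted reaching",
            "load_kg": 0.5,
            "synthetic": True,
        },
    )


def generate_prom(
    config: SyntheticCohortConfig,
    timepoint: str,
    seed: int | np.random.SeedSequence | None = None,
    n: int = 1,
) -> pd.DataFrame:
    """Draw ``n`` PROM value pairs for a timepoint.

    Quick DASH ~ Normal(mean, sd) for the timepoint.  ``clip`` mode clamps
    to [0, 100] and rejection-samples baseline draws below the < 15
    inclusion cut-off; ``none`` returns the latent (unclamped) scores so
    distribution moments can be recovered.  Pain item 9 is a latent normal
    rounded into {1..5}.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    mu = config.quickdash_mean[timepoint]
    sd = config.quickdash_sd[timepoint]
    qd = rng.normal(mu, sd, size=n)
    if config.clip_mode == "clip":
        if timepoint == "baseline":
            bad = (qd < 0) | (qd >= 15)
            while bad.any():
                qd[bad] = rng.normal(mu, sd, size=int(bad.sum()))
                bad = (qd < 0) | (qd >= 15)
        qd = np.clip(qd, 0.0, 100.0)
    pain_latent = rng.normal(config.pain_mean[timepoint], config.pain_sd[timepoint], n)
    pain = np.clip(np.rint(pain_latent), 1, 5).astype(int)
    return pd.DataFrame(
        {"timepoint": timepoint, "quickdash_total": qd, "pain_item9": pain}
    )


def generate_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
):
    """Generate a full two-timepoint cohort.

    Returns ``(trials, proms, truth)`` where ``trials`` maps
    ``(subject_id, timepoint)`` to :class:`~movequal.io.ImuTrial`, ``proms``
    is a list of :class:`~movequal.io.PromRecord` and ``truth`` a DataFrame
    of every subject's degradation parameters (for parameter-recovery
    tests).  With ``out_dir`` the trials, the PROM table and the ground
    truth are also written as CSV via :mod:`movequal.io`.
    """
    root = np.random.SeedSequence(config.seed)
    trial_seeds = root.spawn(config.n_subjects * 2)
    prom_seed = root.spawn(1)[0]
    prom_rng_seq = prom_seed.spawn(config.n_subjects * 2)

    trials: dict[tuple[str, str], ImuTrial] = {}
    proms: list[PromRecord] = []
    truth_rows = []
    k = 0
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        for timepoint in ("baseline", "followup"):
            params = config.params_for(timepoint)
            trials[(sid, timepoint)] = generate_trial(
                config, params, sid, timepoint, seed=trial_seeds[k]
            )
            prom = generate_prom(config, timepoint, seed=prom_rng_seq[k], n=1)
            proms.append(
                PromRecord(
                    subject_id=sid,
                    timepoint=timepoint,
                    quickdash_total=float(
                        np.clip(prom["quickdash_total"].iloc[0], 0, 100)
                    ),
                    pain_item9=int(prom["pain_item9"].iloc[0]),
                )
            )
            truth_rows.append(
                {"subject_id": sid, "timepoint": timepoint, "seed": config.seed,
                 **asdict(params)}
            )
            k += 1
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (sid, timepoint), trial in trials.items():
            path = out_dir / f"{sid}_{timepoint}.csv"
            if path.exists() and not overwrite:
                raise FileExistsError(f"{path} already exists")
            write_trial(trial, path)
        write_prom_table(proms, out_dir / "proms.csv")
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return trials, proms, truth
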