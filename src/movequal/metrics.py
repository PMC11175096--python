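"""The five movement-quality metrics on the concatenated acceleration norm.

All metrics operate on the movement-only Euclidean norm of the raw
acceleration produced by :mod:`.segmentation`:

1. **Local dynamic stability** — maximum Lyapunov exponent by Rosenstein's
   short-term nearest-neighbor divergence method in a delay-embedded state
   space; larger positive values mean faster divergence of nearby
   trajectories, i.e. less stability.
2. **Predictability** — sample entropy (Richman–Moorman), the negative log
   of the conditional probability that template vectors matching for m
   points (Chebyshev distance <= r, self-matches excluded) still match at
   m+1; higher = less predictable.
3. **Smoothness** — log dimensionless jerk, the acceleration-signal
   variant: a duration- and amplitude-normalized integral of squared jerk,
   negated log, computed per repetition and averaged.  Under this standard
   convention smoother movement gives a higher (less negative) value.
4. **Symmetry** — height of the first dominant peak of the normalized
   autocorrelation at a lag near the movement period; identical consecutive
   repetitions give 1.
5. **Variability** — mean sliding-window RMS (window 10 samples) of the
   mean-removed norm.

State-space reconstruction uses the de-facto standard pairing: the time lag
is the first minimum of average mutual information, and the embedding
dimension the smallest with a false-nearest-neighbor fraction below 5 %
(Kennel Rtol = 15, Atol = 2).  The divergence fit range and Theiler window
are set from the task's dominant frequency (power spectral analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal
from scipy.spatial import cKDTree

from .segmentation import SegmentationResult

__all__ = [
    "ReconstructionParams",
    "MovementQualityProfile",
    "MetricError",
    "dominant_frequency",
    "average_mutual_information",
    "select_time_lag",
    "false_nearest_neighbors",
    "select_embedding_dim",
    "delay_embed",
    "lyapunov_rosenstein",
    "sample_entropy",
    "tolerance_from_baseline",
    "log_dimensionless_jerk",
    "symmetry_autocorrelation",
    "rms_variability",
    "compute_profile",
    "METRIC_NAMES",
]

METRIC_NAMES = ("lyapunov", "sample_entropy", "ldlj", "symmetry", "variability_rms")


class MetricError(ValueError):
    """A metric's preconditions are violated or its result is degenerate."""

    def __init__(self, message: str, metric: str | None = None):
        super().__init__(message if metric is None else f"{metric}: {message}")
        self.metric = metric


@dataclass
class ReconstructionParams:
    """State-space reconstruction parameters used for the Lyapunov exponent.

    ``fit_range`` is a half-open (start, end) window, in samples of the
    divergence curve, over which the mean log divergence is fit by least
    squares; ``theiler_window`` excludes temporally correlated neighbors.
    """

    dominant_freq_hz: float
    time_lag: int
    embedding_dim: int
    theiler_window: int
    fit_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.dominant_freq_hz <= 0:
            raise ValueError("dominant_freq_hz must be positive")
        if self.time_lag < 1:
            raise ValueError("time_lag must be >= 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        s, e = self.fit_range
        if not 0 <= s < e:
            raise ValueError("fit_range must satisfy 0 <= start < end")


@dataclass
class MovementQualityProfile:
    """The five scalar movement-quality parameters of one trial.

    ``lyapunov`` is in nats/s; per-sample and per-cycle normalizations are
    exposed as properties since the field reports all three conventions.
    ``tolerance_r`` is the absolute sample-entropy tolerance (m/s^2) used;
    for follow-up trials it is carried over from the subject's baseline.
    """

    lyapunov: float
    sample_entropy: float
    ldlj: float
    symmetry: float
    variability_rms: float
    recon: ReconstructionParams | None = None
    tolerance_r: float | None = None
    sample_rate_hz: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def lyapunov_per_sample(self) -> float | None:
        if self.sample_rate_hz is None:
            return None
        return self.lyapunov / self.sample_rate_hz

    @property
    def lyapunov_per_cycle(self) -> float | None:
        if self.recon is None:
            return None
        return self.lyapunov / self.recon.dominant_freq_hz

    def as_dict(self) -> dict:
        out = {name: getattr(self, name) for name in METRIC_NAMES}
        out["tolerance_r"] = self.tolerance_r
        if self.recon is not None:
            out.update(
                dominant_freq_hz=self.recon.dominant_freq_hz,
                time_lag=self.recon.time_lag,
                embedding_dim=self.recon.embedding_dim,
                theiler_window=self.recon.theiler_window,
                fit_start=self.recon.fit_range[0],
                fit_end=self.recon.fit_range[1],
            )
        return out


# ---------------------------------------------------------------------------
# spectral / reconstruction helpers


def dominant_frequency(
    series: np.ndarray,
    fs: float,
    f_min: float = 0.1,
    peak_ratio_warn: float = 30.0,
) -> float:
    """Dominant frequency by averaged modified periodogram (Welch).

    Hann window, 50 % overlap, segment length min(n, 4 fs / f_min), DC bin
    excluded.  Warns when the peak is not well separated from the background
    (peak-to-median power ratio below ``peak_ratio_warn``) or when fewer
    than ~4 cycles of the peak frequency are present.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise MetricError("no dominant frequency in a constant series")
    nperseg = int(min(len(x), round(4 * fs / f_min)))
    freqs, pxx = signal.welch(x, fs=fs, window="hann", nperseg=nperseg)
    freqs, pxx = freqs[1:], pxx[1:]  # drop DC
    k = int(np.argmax(pxx))
    f0 = float(freqs[k])
    if f0 <= 0:
        raise MetricError("no dominant frequency found")
    if pxx[k] < peak_ratio_warn * np.median(pxx):
        warnings.warn(
            "dominant spectral peak not well separated from background",
            stacklevel=2,
        )
    if len(x) < 4 * fs / f0:
        warnings.warn("fewer than 4 cycles of the dominant frequency", stacklevel=2)
    return f0


def average_mutual_information(
    series: np.ndarray, max_lag: int, n_bins: int | None = None
) -> np.ndarray:
    """AMI (nats) of the series with its lagged copy, for lags 0..max_lag.

    Equal-width histogram estimate; default bin count follows the common
    ``n**(1/3)`` rule, floored at 8.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be below the series length")
    if n_bins is None:
        n_bins = max(8, int(round(n ** (1 / 3))))
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    edges[-1] += 1e-12  # include the max in the last bin
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: n - lag] if lag else x
        b = x[lag:] if lag else x
        joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        ami[lag] = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return ami


def select_time_lag(
    series: np.ndarray, fs: float | None = None, f0: float | None = None,
    max_lag: int | None = None, min_window: int = 5, floor_frac: float = 0.05,
) -> int:
    """Embedding delay: first robust minimum of AMI over lags 1..fs/f0.

    A lag qualifies when its AMI is below the previous lag and no lower AMI
    occurs within the next ``min_window`` lags (spurious one-sample dips of
    the histogram estimate are ignored), or immediately when the AMI has
    already collapsed to ``floor_frac`` of its lag-0 value (the memoryless
    case, e.g. white noise).  Falls back to a quarter of the dominant
    period, round(fs/(4 f0)), when no minimum exists within the range.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise MetricError("cannot select a time lag for a constant series")
    if max_lag is None:
        if fs is None or f0 is None:
            raise ValueError("either max_lag or (fs, f0) must be given")
        max_lag = max(2, int(round(fs / f0)))
    max_lag = min(max_lag, len(x) - 2)
    ami = average_mutual_information(x, min(max_lag + min_window, len(x) - 1))
    floor = floor_frac * ami[0]
    for lag in range(1, max_lag + 1):
        if ami[lag] <= floor:
            return lag
        ahead = ami[lag + 1 : lag + 1 + min_window]
        if ami[lag] < ami[lag - 1] and (len(ahead) == 0 or ami[lag] <= ahead.min()):
            return lag
    if fs is not None and f0 is not None:
        return max(1, int(round(fs / (4 * f0))))
    return max(1, int(np.argmin(ami[1:])) + 1)


def delay_embed(series: np.ndarray, dim: int, lag: int) -> np.ndarray:
    """Delay-coordinate embedding: rows are (x_i, x_{i+lag}, ..., x_{i+(dim-1)lag})."""
    x = np.asarray(series, dtype=float)
    n = len(x) - (dim - 1) * lag
    if n < 1:
        raise MetricError(
            f"series of length {len(x)} too short for dim={dim}, lag={lag}"
        )
    return np.lib.stride_tricks.sliding_window_view(x, (dim - 1) * lag + 1)[:, ::lag]


def false_nearest_neighbors(
    series: np.ndarray,
    dim: int,
    lag: int,
    rtol: float = 15.0,
    atol: float = 2.0,
) -> float:
    """Fraction of false nearest neighbors at embedding dimension ``dim``.

    Kennel criteria: a neighbor is false when the extra coordinate jumps by
    more than ``rtol`` x the d-dimensional distance, or the (d+1)-distance
    exceeds ``atol`` x the attractor size.
    """
    x = np.asarray(series, dtype=float)
    emb = delay_embed(x, dim, lag)
    n_next = len(x) - dim * lag  # points with an available (d+1)-th coordinate
    if n_next < 2:
        raise MetricError("series too short for FNN test")
    emb = emb[:n_next]
    nxt = x[dim * lag :][:n_next]
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=2)
    dist, idx = dist[:, 1], idx[:, 1]
    attractor_size = float(np.std(x))
    extra = np.abs(nxt - nxt[idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, extra / dist, np.inf)
    d1 = np.sqrt(dist**2 + extra**2)
    false = (ratio > rtol) | (d1 > atol * attractor_size)
    return float(np.mean(false))


def select_embedding_dim(
    series: np.ndarray,
    lag: int,
    max_dim: int = 10,
    fnn_threshold: float = 0.05,
    rtol: float = 15.0,
    atol: float = 2.0,
) -> int:
    """Smallest dimension in 2..max_dim with FNN fraction below threshold;
    returns ``max_dim`` with a warning if never reached."""
    for dim in range(2, max_dim + 1):
        if false_nearest_neighbors(series, dim, lag, rtol, atol) < fnn_threshold:
            return dim
    warnings.warn(
        f"FNN fraction never dropped below {fnn_threshold:.0%}; "
        f"using dim={max_dim}",
        stacklevel=2,
    )
    return max_dim


# ---------------------------------------------------------------------------
# (1) local dynamic stability


def lyapunov_rosenstein(
    series: np.ndarray,
    fs: float,
    recon: ReconstructionParams,
    return_curve: bool = False,
):
    """Maximum Lyapunov exponent (nats/s) by Rosenstein's method.

    Each embedded point is paired with its nearest neighbor outside the
    Theiler window; the mean log distance between the pairs is tracked for
    k = 0 .. fit_range end, and the exponent is the least-squares slope of
    that curve over ``fit_range``, converted to per-second units.
    """
    x = np.asarray(series, dtype=float)
    emb = delay_embed(x, recon.embedding_dim, recon.time_lag)
    n = len(emb)
    w = recon.theiler_window
    k_max = recon.fit_range[1]
    if k_max >= n - 1:
        raise MetricError("fit_range end exceeds the divergence-curve length")
    if n < 10 * max(w, 1):
        raise MetricError(
            f"embedded series ({n} points) shorter than 10x the Theiler window ({w})"
        )
    # nearest neighbor outside the Theiler window, brute force in blocks
    nn = np.full(n, -1, dtype=int)
    nn_dist = np.full(n, np.inf)
    block = 512
    idx = np.arange(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = np.linalg.norm(emb[start:stop, None, :] - emb[None, :, :], axis=2)
        excl = np.abs(idx[start:stop, None] - idx[None, :]) <= w
        d[excl] = np.inf
        nn[start:stop] = np.argmin(d, axis=1)
        nn_dist[start:stop] = d[idx[start:stop] - start, nn[start:stop]]
    valid = np.isfinite(nn_dist)
    if valid.sum() < 10:
        raise MetricError(
            f"only {int(valid.sum())} valid neighbor pairs (need >= 10)"
        )
    # mean log divergence over k, averaging only pairs still inside the series
    curve = np.full(k_max + 1, np.nan)
    i_all = np.flatnonzero(valid)
    j_all = nn[i_all]
    for k in range(k_max + 1):
        keep = (i_all + k < n) & (j_all + k < n)
        if keep.sum() < 10:
            raise MetricError(f"too few pairs ({int(keep.sum())}) at step {k}")
        d = np.linalg.norm(emb[i_all[keep] + k] - emb[j_all[keep] + k], axis=1)
        d = d[d > 0]
        if len(d) < 10:
            raise MetricError(f"too few nonzero divergences at step {k}")
        curve[k] = float(np.mean(np.log(d)))
    s, e = recon.fit_range
    kk = np.arange(s, e)
    slope = float(np.polyfit(kk, curve[s:e], 1)[0])
    lam = slope * fs
    if return_curve:
        return lam, curve
    return lam


# ---------------------------------------------------------------------------
# (2) predictability


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy (nats), Richman–Moorman.

    ``-ln(A/B)`` where B counts pairs of m-length templates and A pairs of
    (m+1)-length templates within Chebyshev distance ``r``; self-matches are
    excluded and both counts use the first ``n - m`` templates.  The signal
    is not normalized: ``r`` is in the signal's units (here m/s^2).  Returns
    ``inf`` when no (m+1)-template pair matches (flagged by a warning).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if r is None or r <= 0:
        raise MetricError("tolerance r must be positive", metric="sample_entropy")
    if n <= m + 1:
        raise MetricError(
            f"series length {n} must exceed m+1 = {m + 1}", metric="sample_entropy"
        )
    # templates: rows i = x[i..i+m] ; both B (first m cols) and A (all m+1)
    # use the same n-m starting indices
    tpl = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n-m, m+1)
    nt = len(tpl)
    b_count = 0
    a_count = 0
    for i in range(nt - 1):
        cheb_m = np.max(np.abs(tpl[i + 1 :, :m] - tpl[i, :m]), axis=1)
        match_m = cheb_m <= r
        b_count += int(match_m.sum())
        if match_m.any():
            cheb_last = np.abs(tpl[i + 1 :, m] - tpl[i, m])
            a_count += int((match_m & (cheb_last <= r)).sum())
    if b_count == 0:
        raise MetricError("no m-length template matches", metric="sample_entropy")
    if a_count == 0:
        warnings.warn(
            "no (m+1)-length template matches; sample entropy is infinite",
            stacklevel=2,
        )
        return float("inf")
    return float(-np.log(a_count / b_count))


def tolerance_from_baseline(baseline_concat_norm: np.ndarray, frac: float = 0.2) -> float:
    """Person-specific entropy tolerance r = 0.2 x SD (ddof=1) of the
    baseline movement-only norm; reused verbatim at follow-up."""
    x = np.asarray(baseline_concat_norm, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise MetricError("zero tolerance: baseline signal is constant")
    return frac * sd


# ---------------------------------------------------------------------------
# (3) smoothness


def log_dimensionless_jerk(accel_segment: np.ndarray, fs: float) -> float:
    """Log dimensionless jerk of one movement segment (acceleration variant).

    With T the segment duration, a(t) the mean-removed acceleration norm,
    j = da/dt (central differences interior, one-sided at the edges) and
    a_peak = max |a|::

        LDLJ = -ln( (T / a_peak^2) * integral j(t)^2 dt )

    Dimensionless by construction: invariant to amplitude scaling and to
    shape-preserving time scaling.  More negative = less smooth.
    """
    a = np.asarray(accel_segment, dtype=float)
    if len(a) < 5:
        raise MetricError(f"segment of {len(a)} samples too short (need >= 5)",
                          metric="ldlj")
    a = a - a.mean()
    a_peak = float(np.max(np.abs(a)))
    if a_peak == 0:
        raise MetricError("zero peak acceleration", metric="ldlj")
    dt = 1.0 / fs
    jerk = np.gradient(a, dt)
    duration = len(a) * dt
    dlj = duration / a_peak**2 * float(np.trapezoid(jerk**2, dx=dt))
    return -float(np.log(dlj))


def ldlj_per_trial(seg: SegmentationResult, fs: float) -> float:
    """Trial-level smoothness: mean per-repetition LDLJ.  Computed on each
    repetition separately because concatenation seams would otherwise inject
    artificial jerk spikes."""
    values = [log_dimensionless_jerk(rep, fs) for rep in seg.iter_segments()]
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# (4) symmetry


def symmetry_autocorrelation(
    concat_norm: np.ndarray, fs: float, f0: float
) -> float:
    """Height of the first dominant autocorrelation peak near the period.

    Unbiased, mean-removed, variance-normalized autocorrelation, maximized
    over lags in [0.5, 1.5] x (fs / f0).  Identical consecutive repetitions
    give 1 (perfect symmetry); the estimate is clipped to [-1, 1].
    """
    x = np.asarray(concat_norm, dtype=float)
    period = fs / f0
    lo = max(1, int(np.floor(0.5 * period)))
    hi = int(np.ceil(1.5 * period))
    n = len(x)
    if hi >= n:
        raise MetricError(
            f"autocorrelation search window (lag {hi}) exceeds series length {n}",
            metric="symmetry",
        )
    xc = x - x.mean()
    var = float(np.mean(xc**2))
    if var == 0:
        raise MetricError("zero-variance signal", metric="symmetry")
    lags = np.arange(lo, hi + 1)
    rho = np.array(
        [np.sum(xc[: n - k] * xc[k:]) / (n - k) / var for k in lags]
    )
    return float(np.clip(np.max(rho), -1.0, 1.0))


# ---------------------------------------------------------------------------
# (5) variability


def rms_variability(concat_norm: np.ndarray, window: int = 10) -> float:
    """Mean sliding-window RMS (stride 1) of the mean-removed norm (m/s^2)."""
    x = np.asarray(concat_norm, dtype=float)
    if window < 1:
        raise MetricError("window must be >= 1", metric="variability_rms")
    if window > len(x):
        raise MetricError(
            f"window {window} exceeds series length {len(x)}",
            metric="variability_rms",
        )
    xc = x - x.mean()
    sq = np.lib.stride_tricks.sliding_window_view(xc**2, window)
    return float(np.mean(np.sqrt(sq.mean(axis=1))))


# ---------------------------------------------------------------------------
# orchestration


def compute_profile(
    seg: SegmentationResult,
    fs: float,
    tolerance_r: float | None = None,
    m: int = 2,
    rms_window: int = 10,
    max_embedding_dim: int = 10,
    ldlj_on_concatenated: bool = False,
    negate_ldlj: bool = False,
    raise_on_error: bool = False,
) -> MovementQualityProfile:
    """Compute all five movement-quality parameters of one segmented trial.

    ``tolerance_r`` is the absolute sample-entropy tolerance; when omitted
    it is derived from this trial's own norm (0.2 x SD), which is the
    baseline convention — follow-up trials must pass their subject's
    baseline-derived value instead.

    ``ldlj_on_concatenated`` computes the smoothness on the whole
    concatenated norm instead of per repetition (the default per-repetition
    mean avoids artificial jerk spikes at concatenation seams);
    ``negate_ldlj`` flips the smoothness sign for conventions that read a
    high value as unsmooth.

    Metric failures are isolated: unless ``raise_on_error``, a failing
    metric is reported as NaN with the error recorded in ``extras`` so one
    degenerate computation cannot void the remaining parameters.
    """
    x = seg.concat_norm
    errors: dict[str, str] = {}

    def _try(name, fn):
        try:
            return fn()
        except (MetricError, ValueError) as exc:  # propagate tagged, or record
            if raise_on_error:
                raise MetricError(str(exc), metric=name) from exc
            errors[name] = str(exc)
            return float("nan")

    f0 = dominant_frequency(x, fs)
    if tolerance_r is None:
        tolerance_r = tolerance_from_baseline(x)

    recon = None

    def _lyap():
        nonlocal recon
        lag = select_time_lag(x, fs, f0)
        dim = select_embedding_dim(x, lag, max_dim=max_embedding_dim)
        period = fs / f0
        recon = ReconstructionParams(
            dominant_freq_hz=f0,
            time_lag=lag,
            embedding_dim=dim,
            theiler_window=int(round(period)),
            fit_range=(0, max(2, int(round(0.5 * period)))),
        )
        return lyapunov_rosenstein(x, fs, recon)

    lam = _try("lyapunov", _lyap)
    sampen = _try("sample_entropy", lambda: sample_entropy(x, m=m, r=tolerance_r))
    def _ldlj():
        if ldlj_on_concatenated:
            value = log_dimensionless_jerk(x, fs)
        else:
            value = ldlj_per_trial(seg, fs)
        return -value if negate_ldlj else value

    ldlj = _try("ldlj", _ldlj)
    sym = _try("symmetry", lambda: symmetry_autocorrelation(x, fs, f0))
    rms = _try("variability_rms", lambda: rms_variability(x, window=rms_window))

    return MovementQualityProfile(
        lyapunov=lam,
        sample_entropy=sampen,
        ldlj=ldlj,
        symmetry=sym,
        variability_rms=rms,
        recon=recon,
        tolerance_r=tolerance_r,
        sample_rate_hz=fs,
        extras={"errors": errors, "m": m, "rms_window": rms_window},
    )
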