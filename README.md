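# movequal

Movement-quality analysis of a cyclic, weighted upper-limb reaching task
from a single wrist-worn inertial measurement unit (IMU), for researchers
studying upper-limb function — for example before and after breast-cancer
surgery — who want objective digital biomarkers next to patient-reported
outcomes such as the Quick DASH.

The task: moving a 0.5 kg load from the side of the body to a plate at 90°
humerothoracic elevation and back, 14 times, recorded at 60 Hz by a sensor
at the distal forearm. The package segments the repetitions, computes five
movement-quality parameters on the movement-only acceleration norm, and
runs the pre/post cohort statistics — plus a synthetic-cohort generator so
the whole pipeline is testable without access to patient data.

## The five parameters

All are computed on the concatenated Euclidean norm
`‖a‖ = √(aₓ² + a_y² + a_z²)` of the raw acceleration, restricted to the
detected movement repetitions (≈ 1400 samples per trial):

1. **Local dynamic stability** — maximum Lyapunov exponent λ (nats/s) by
   Rosenstein's nearest-neighbor divergence method in a delay-embedded
   state space (lag τ from the first robust minimum of average mutual
   information, dimension d from false nearest neighbors, Theiler window
   and divergence fit range set from the task's dominant frequency f₀).
   Larger λ ⇒ nearby trajectories diverge faster ⇒ less stable.
2. **Predictability** — sample entropy, `SampEn = −ln(A/B)` with template
   length m = 2 and a person-specific tolerance r = 0.2 × SD of the
   *baseline* signal, reused verbatim at follow-up. Higher ⇒ less
   predictable.
3. **Smoothness** — log dimensionless jerk (acceleration variant),
   `LDLJ = −ln((T / a_peak²) ∫ ȧ(t)² dt)`, computed per repetition and
   averaged. More negative ⇒ less smooth.
4. **Symmetry** — height of the first dominant peak of the normalized
   autocorrelation at a lag near the movement period (1 = consecutive
   repetitions identical).
5. **Variability** — mean sliding-window RMS (10-sample windows) of the
   mean-removed norm (m/s²).

Cohort statistics are rank-based: Wilcoxon signed-rank tests compare
baseline vs follow-up per parameter, and Spearman correlations relate
follow-up parameters to follow-up disability (Quick DASH total, 0–100) and
pain (Quick DASH item 9, 1–5), with strength labelled by |r_s|:
[0, 0.25) little-to-no, [0.25, 0.5) fair, [0.5, 0.75) moderate-to-good,
[0.75, 1] good-to-excellent. α = 0.05, no multiplicity adjustment by
default.

## Worked example

Simulate a small cohort in which every subject's follow-up movement gains a
high-frequency ripple (a smoothness degradation), then run the full study:

```sh
cat > cfg.yaml <<EOF
n_subjects: 8
baseline_params:
  amplitude_jitter: 0.08
effects:
  ripple_amp: 0.2
EOF
movequal study --synthetic --config cfg.yaml --out demo --seed 7
movequal report demo
```

prints

```
Paired baseline vs follow-up (Wilcoxon signed rank):
  lyapunov         n=  8  W=   15.0  p=0.742  median diff=+0.006052
  sample_entropy   n=  8  W=    0.0  p=0.008  median diff=+0.04241
  ldlj             n=  8  W=    0.0  p=0.008  median diff=-0.04366
  symmetry         n=  8  W=    5.0  p=0.078  median diff=-0.003288
  variability_rms  n=  8  W=    0.0  p=0.008  median diff=+0.08044
...
```

The injected ripple is detected: follow-up LDLJ drops (median difference
−0.044, p = 0.008 — more negative = less smooth), and because the
modulation also adds cycle-to-cycle amplitude variance, sample entropy and
RMS variability rise with it, while stability and symmetry are unaffected.
`demo/` also contains the tidy per-subject `metrics.csv`,
`paired_tests.csv`, `correlations.csv`, a descriptive `normality.csv`, and
a `manifest.json` recording every parameter used.

A single trial can be profiled directly:

```sh
movequal metrics trial.csv
```

```
lyapunov: 0.2094003320618354
sample_entropy: 0.3558644438468581
ldlj: -4.514525535692159
symmetry: 1.0
variability_rms: 7.096557499929762
tolerance_r: 1.4731642682184172
dominant_freq_hz: 0.5999998799999843
time_lag: 6
embedding_dim: 2
...
```

— a clean synthetic trial is perfectly symmetric (1.0), nearly neutral in
stability (λ ≈ 0.2 nats/s) and highly regular (SampEn ≈ 0.36), with the
reconstruction parameters (f₀, τ, d) reported alongside.

## Layout

| module | role |
| --- | --- |
| `movequal.io` | CSV trial / PROM reading and writing, validation |
| `movequal.segmentation` | zero-phase Butterworth filtering, repetition detection, concatenation |
| `movequal.metrics` | the five movement-quality parameters and state-space reconstruction |
| `movequal.stats` | Wilcoxon / Spearman cohort statistics, strength bands |
| `movequal.synthetic` | synthetic cohorts: task kinematics, degradations, PROM distributions |
| `movequal.pipeline`, `movequal.cli` | per-subject and study orchestration, `movequal` CLI |

See `docs/methods.md` for the full methodological account.
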