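# Methods

## Physical model of the instrumented bed

Four single-axis load cells under the bed legs measure vertical forces
`LH, RH, LF, RF` at 50 Hz. Treating the bed and occupant as a rigid body
in quasi-static equilibrium, the planar centre of mass follows from moment
balance about the two bed axes (see README). The moment balance determines
only two linear combinations of the four forces; the remaining degree of
freedom — the diagonal difference `LH − RH − LF + RF` — is not observable
from the CoM. The simulator therefore sets it to zero, which is the
unique minimal inversion of the measurement equations and reproduces every
signal the downstream features consume.

The simulator composes, per sample:

* a static corner-force distribution for the configured CoM: the
  occupant's habitual lateral offset plus a roll-dependent lateral shift
  (`lateral_shift_coeff`, m/rad of TPA) in x, and a fixed longitudinal
  position (`com_longitudinal_frac` of bed length) in y;
* a respiration term: a sinusoidal CoM displacement of amplitude
  `resp_amplitude` along the direction `resp_angle_map(TPA)`;
* a cardiac term: a force sinusoid at `cardiac_rate`, split equally across
  channels, so the ballistocardiographic band is non-empty;
* additive white Gaussian sensor noise per channel (`noise_sd`).

Within a held pose the realized TPA wanders as low-pass-filtered noise
rescaled to `jitter_sd` and clipped just inside ±5° of the target,
emulating an experimenter correcting drifts beyond that tolerance.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| bed `l × w` | 2.0 × 0.9 m | typical hospital-bed leg spacing |
| frame mass | 60 kg | typical frame + mattress |
| body mass / height | N(77.9, 19.2) kg, N(1.744, 0.106) m, truncated | emulated cohort statistics |
| `resp_rate` | U(0.20, 0.33) Hz | 12–20 breaths/min at rest |
| `resp_amplitude` | U(1.8, 3.5) mm | sub-centimetre CoM excursion per breath |
| `resp_angle_map` | 75°·sin(TPA/2) | see below |
| `cardiac_rate`, amplitude | U(0.9, 1.4) Hz, U(0.3, 0.8) N | resting heart rate; sub-newton recoil |
| `noise_sd` | 0.5 N | load-cell + conditioner noise floor |
| `lateral_offset` | U(−5, +5) cm | habitual lying position varies between people |
| `lateral_shift_coeff` | U(0.015, 0.035) m/rad | rolling in place moves the CoM a few cm at most |
| pose jitter sd | 2° | drift within the ±5° correction tolerance |

The respiration-direction map is the one genuinely invented component: no
quantitative relation between roll angle and breathing-ellipse orientation
is available for humans. `75°·sin(TPA/2)` was chosen because it is
monotone over (−180°, 180°], assigns distinct ranges to the three coarse
classes and to every side bin, and stays inside the (−90°, 90°] range that
an arctangent can recover. It is a separability device, not physiology;
conclusions about real patients require real recordings.

The scripted protocol holds 11 poses (0°, ±15°, ±30°, ±45°, ±60°, ±90°)
for 3 min each, separated by 1-min intermediate holds — supine in general,
with a 90° side hold staged before each fully rolled pose. The free-choice
protocol draws 10 targets uniformly from (−180°, 180°]. Transition
intervals are not synthesized; segment boundaries delimit clean trials,
matching recordings from which positional changes have been cut.

## Signal processing choices

* **Respiration isolation.** Chebyshev type II low-pass, order 4, 40 dB
  stopband attenuation, applied forward–backward (zero net phase). The
  "personalized" cutoff is 1.5× the recording's dominant breathing
  frequency; that frequency is estimated per pose segment from the
  demeaned CoM periodogram in 0.1–0.5 Hz and pooled with the median,
  because a whole-recording spectrum is dominated by pose-to-pose CoM
  steps. A fixed cutoff (e.g. 0.5 Hz) is selectable.
* **Breath extrema.** Sign changes of the forward difference, with exact
  zeros carrying the previous sign; alternation is enforced by keeping the
  more prominent member of same-type adjacent pairs. Extrema are detected
  on whichever respiration component has the larger variance, and each
  maximum is paired with the first following minimum; the ellipse angle is
  invariant to which component supplied the extrema.
* **Ellipse angle.** A plain arctangent with range (−90°, 90°]; a zero
  x-difference returns the 90° limit. Per-window angles are averaged
  arithmetically — the bounded range precludes wrap-around, so no circular
  mean is needed.
* **Cardiac band.** Butterworth band-pass 0.8–2.5 Hz (48–150 bpm),
  zero-phase, applied to all four channels.

## Features and windowing

45-s windows (2250 samples) stepped by 15 s, fully contained in one pose:
a 3-min pose yields exactly 10 windows. The rms of the respiration-band
CoM components is computed on the within-window demeaned signal and
normalized by the 97th percentile of the *resultant* oscillation magnitude
over the whole participant-phase recording. A single common scale is used
for both axes deliberately: normalizing each axis by its own percentile
would cancel in the y/x rms ratio and erase the ellipse orientation the
ratio exists to capture. Windows with no detectable breath, or a zero
denominator in a ratio, carry NaN and are filled by linear interpolation
across the pose's window sequence (nearest value at the edges); a pose
missing a field everywhere is dropped with a warning. Ground-truth TPA per
window is the circular mean of the per-sample truth.

Feature importance uses impurity-based importances from a
gradient-boosted-tree fit, normalized to sum to one. In this generator the
within-pose variance of `CoM_y` is breathing-driven by construction, so
`stdCoM_y`/`ratio_stdCoM` act as respiration-amplitude features alongside
the explicit respiration-band set.

## Classification protocol

Phase One is a 3-class problem over the twelve features; backends are
LightGBM, scikit-learn gradient boosting, AdaBoost, XGBoost, logistic
regression, SVM, and three MLP sizes (32; 64-32; 128-64-32), all with
library-default hyperparameters and fixed seeds (a hyperparameter hook
accepts user grids). Windows Phase One misclassifies are discarded; the
correct left/right windows feed per-side Phase Two models over the bin
schemes. Supine has fixed width and is never refined. The `supplemental`
hook adds coarse-label-only windows to every fold's Phase One training
set, mirroring studies that pool extra unlabeled-angle cohorts.

LOPO: each fold trains on all other participants and tests on the
held-out one. The held-out participant's windows are split 70/30 per
coarse class (largest-remainder allocation so the pool is exactly
`floor(0.3 n)`), the 30 % pool is seed-shuffled and round-robin
interleaved across classes, and incremental level `c` takes the first
`floor(pool · c/0.3)` windows — so the test set is identical across
levels and the subsets are nested. Phase One runs for every
(backend, level); per backend the level with the best mean F1 across
participants is carried into Phase Two, which trains on the other
participants' correctly classified side windows (plus the IL subset) and
tests on the held-out participant's correctly classified test windows.
A leakage assertion inside `run_lopo` verifies per fold that no test
window enters any training set. Ties in posterior resolve to the lowest
class index.

Scores are macro F1 (unweighted mean of per-class F1, classes absent from
both sides excluded) and accuracy, per participant; aggregates are
mean ± sd across participants. Comparisons use the Friedman rank test
(df = k−1) and post-hoc paired Wilcoxon signed-rank tests reporting the
positive-rank sum V (exact p for n ≤ 25 without ties), with Bonferroni
thresholds 0.05/k.

## Problem sizes used in the test and acceptance runs

Simulated cohorts in the test suite use 90-s scripted poses, 45-s
intermediate holds and six 90-s free-choice poses (the generator defaults
keep the full 180 s/60 s protocol): six participants for the leakage and
monotonicity checks (five master seeds for the latter), ten participants
at `noise_sd = 0.1` for the coarse-posture recovery check. The CoM oracle
runs 1000 random static loads against an independent torque-balance
solution; the bin partition sweeps a 0.1° grid.

## What passing tests do and do not show

The generator reproduces the *structure* real recordings are believed to
have — force conservation, a posture-dependent breathing ellipse, a
cardiac micro-oscillation, sensor noise, bounded pose drift — but not
mattress/frame dynamics, multi-segment biomechanics, posture-dependent
breathing-rate changes, movement artifacts, or the true human
TPA-to-ellipse relation. Passing the recovery and monotonicity checks
shows the pipeline is correct and that the precision–accuracy trade-off
emerges whenever posture information degrades gracefully with bin width;
it does not certify the F1 levels achievable on real patients. The
published headline scores are kept in `bedpose.reference` as inputs for
the composition identities, not as reproduction targets.

## Known limitations

* Sequence models (LSTM, 1-D CNN) are out of scope; only feature-based
  backends are provided.
* The Phase Two train/test granularity (training on other participants'
  correct windows) is one of several defensible designs; the original
  fold-level procedure at this granularity is not fully specified
  anywhere, so the choice is fixed here for reproducibility.
* Synthetic cohorts are easier than real ones: on low-noise settings most
  backends saturate near F1 = 1 at coarse precision.
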