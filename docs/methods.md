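# Methods

This note documents the models, parameter choices and numerical
conventions behind `swayquest`, and what the synthetic experiments do
and do not establish about recorded data.

## Adaptive threshold tracking

The tracker maintains a discrete posterior over candidate detection
thresholds `T` on a uniform grid (201 points spanning the prior mean
± 5 prior SD, floored at a small positive value), with a Gaussian prior.
The psychometric model is a Weibull yes/no function,

    p(x; T) = δγ + (1 − δ)·(γ + (1 − γ)·(1 − e^{−(x/T)^β}))

which is the classic Weibull in log10 intensity written in ratio form:
substituting x = 10^u, T = 10^t gives exp(−10^{β(u−t)}). The slope is
β = 3.5 — the conventional choice for this family of adaptive
procedures — and the threshold sits where the contamination-free core
reaches 1 − 1/e ≈ 0.632. Guess and lapse rates default to γ = δ = 0.01;
a yes/no task has no forced-choice floor, so γ is a false-alarm rate,
and both values are configurable. An `intensity_scale` switch selects a
shifted (Gumbel-type) variant for devices whose unit steps are
perceptually linear; all grids and priors are kept in linear device
units either way, because the quantities a device accepts — and the
printed experimental parameters — are integers on that scale.

Updates multiply each candidate's weight by `p` (detected) or `1 − p`
(not detected), accumulated in log space with a log-likelihood floor of
−745 so a long run of identical responses cannot underflow the grid;
normalization uses log-sum-exp. The next probe is the posterior mean,
rounded half-away-from-zero to an integer and clipped to the device
range (≥ 1: a zero-amplitude stimulus is undefined). Rounding means
successive trials frequently repeat the same integer command even
though the underlying recommendation drifts.

**Threshold determination.** A block's threshold is the plateau of the
integer recommendations: the smallest trial index k\* such that the
recommendation after every trial ≥ k\* equals the recommendation after
k\*; if the last two recommendations differ there is no plateau. The
estimate is valid only when the responses of the remaining trials
(k\*+1 … 30) contain both categories; convergence on the final trial is
therefore invalid by construction (an empty remainder cannot show both).
"Recommendation after trial k" means the quantized intensity proposed
for trial k+1, i.e. the product of trial k's response.

**Per-interval tracks.** Perturbation blocks interleave three
independent 30-trial tracks, one per probe interval, each seeded with
the training-block estimate; this is the only reading under which each
interval yields its own converged recommendation sequence. Whether the
original software shared state between intervals is unknowable from the
outside; the independent-track reading is an interpretation.

## Synthetic observers and the device scale

Simulated observers respond Bernoulli(p) at the presented integer
intensity using the same Weibull family (matched slope β = 3.5 —
steeper observers were found to destabilize the plateau rule and are
not the default). The defaults place the population at
5 ± 1.2 device units (floored at 2.5), with the training prior at
(mean 5, SD 1.5) standing in for an unpublished pilot estimate, and
later blocks re-seeded at the training estimate with prior SD 0.5 —
tighter, because the training posterior is itself already concentrated.
Each track additionally receives a Gaussian threshold offset of SD 0.75
device units, modelling block-to-block physiological fluctuation
(vigilance, posture, skin state). That fluctuation matters twice: it is
realistic, and it keeps the integer-valued Δthreshold distributions
non-degenerate, so interquartile ranges do not collapse to a point.

These scales were chosen to reproduce the operating characteristics a
plateau-based rule needs to function: with posterior-mean placement the
posterior SD in device units grows with the threshold magnitude, so
thresholds high on the integer scale make rounded recommendations flip
indefinitely and the plateau rule fails for a third of all tracks.
At the default scale the generator yields roughly 10% invalid tracks
and ~10 trials to plateau, with about a quarter to a third of simulated
participants retaining all six ANOVA cells. This is less favorable than
a well-tuned laboratory run (where invalid rates near 4% and ~15 of 20
complete participants are attainable); the residual gap appears
intrinsic to mean-placement tracking with integer-quantized commands
and matched-slope Bernoulli observers, and is a known limitation of the
simulation, not of the analysis code.

## Sway model

Quiet stance is a zero-mean Ornstein–Uhlenbeck process simulated
exactly at the native rates (COP 300 Hz, head 90 Hz): mean-reversion
rate θ = 1 s⁻¹ and stationary SD 5 mm (COP) / 3 mm (head), values in
the centimeter-amplitude range typical of quiet-stance posturography —
deliberately generic, configurable, and not calibrated to any
particular dataset. Trials with a perturbation add a deterministic
posterior-positive excursion: a raised-cosine ramp of amplitude 20 mm
(COP) / 10 mm (head) beginning 150 ms after onset, rising over 0.8 s,
holding 1 s, then decaying (an optional anterior dip is off by
default). In predictable (countdown) trials the innovation noise in the
2.25 s before onset is scaled by 0.5, producing the anticipatory
damping the analysis should detect. Gap (≥100 ms missing run) and
outlier (>15 cm spike) artifacts can be injected per COP trial at
configurable rates, defaulting to zero.

The model is a statistical stand-in, not biomechanics: no inverted
pendulum, no closed postural control loop, no coupling between sway and
tactile responses. Passing tests therefore establish that the analysis
recovers what the generator plants under realistic noise — not that the
generator reproduces human sway spectra.

## Cleaning and metrics

Pipeline order is fixed: gap exclusion → quiet-stance re-referencing →
outlier blanking → smoothing → metrics.

* Gap rule: a trial is dropped when missing samples run continuously
  for ≥ 100 ms (30 samples at 300 Hz, 9 at 90 Hz), and the drop removes
  the trial from kinematic *and* psychophysical analyses.
* Re-referencing subtracts the mean of the first 0.5 s (quiet stance).
* Samples with |displacement| > 15 cm are set missing — strictly
  greater, applied before smoothing (the sentence order of the original
  procedure implies this; it is not stated outright), and never
  interpolated.
* Smoothing is a centered moving average of ~100 ms. "Symmetric"
  requires an odd window, so 100 ms at 300 Hz (30 samples) becomes 31,
  and 9 at 90 Hz. Missing samples are excluded from window means and
  remain missing; windows shrink at trial edges rather than pad.
* Anticipatory metric: max |x| over [onset − 2.25 s, onset), half-open,
  so the onset sample itself is excluded. Reactive amplitude: the
  positive maximum over [onset, onset + 3.5 s] minus the minimum between
  onset and that maximum — non-negative by construction. Windows are
  anchored to each trial's actual (possibly jittered) onset.
* Kinematic averages use only trials up to the associated track's
  convergence trial; invalid tracks contribute no kinematic trials.
* Head and COP are processed at native rates and never resampled; all
  metrics are per-stream extrema.

## Statistics

* Δthreshold = interval threshold − baseline threshold. Experiment 1
  normalizes against the matching standing baseline (countdown to
  countdown); experiment 2 against the sitting baseline. The two
  standing baselines are averaged only for the standing-vs-sitting
  paired test.
* t statistics are reported as absolute values; p-values honor the
  configured direction (anticipatory reduction one-sided under low
  uncertainty, two-sided under high; reactive increase one-sided;
  Δthreshold tests two-sided in experiment 1, one-sided greater in
  experiment 2). All-values-exactly-zero inputs return a null result
  (t = 0, p = 1); zero variance away from the null raises.
* The 3×2 within-subject ANOVA uses complete cases (listwise deletion),
  each effect tested against its own effect-by-subject error term.
* η² is SS_effect / SS_total with SS_total including between-subject
  variance — not partial η². For one-sample tests this reduces to
  n·(x̄−μ₀)² / Σ(xᵢ−μ₀)². The total-SS convention cannot be fully
  disambiguated from published values; it is the one consistent with
  small effect sizes at moderate t.
* Holm correction is the step-down adjustment (statsmodels), applied to
  the three post-hoc interval comparisons.
* Outlier fences are Q3 + 3.5·IQR / Q1 − 3.5·IQR with type-7
  (linear-interpolation) quantiles and strict comparisons, applied per
  condition; an excluded *baseline* removes the three dependent deltas
  of that participant's condition, since normalization is impossible.
  Fences are skipped for cells with fewer than four values.

## Problem sizes and determinism

Every random path flows from a single integer seed through
`numpy.random.Generator`; identical seeds give byte-identical outputs.
The acceptance script uses the sizes its checks are defined at: 1000
random cases for the Bayes-update and convergence-rule oracles, 200
30-trial blocks for parameter recovery, 500 simulated n = 20 null
cohorts for the false-positive calibration of the time main effect, and
200 cohorts with a planted 2-unit "after" facilitation for
direction-of-effect fidelity. A full n = 20 psychophysics-only cohort
simulates in well under a second; kinematics adds a few hundred
milliseconds per subject.

## Known limitations

* The plateau/validity operating characteristics undershoot a
  well-behaved laboratory run (see above); complete-case counts for the
  ANOVA are correspondingly lower, which costs ANOVA power but leaves
  its calibration nominal.
* The sway generator has no biomechanical content and its parameters
  are not fitted to data.
* Sequential dependencies (practice, fatigue) are deliberately absent
  from the observer model.
* Exclusion bookkeeping for gap-dropped trials removes them from both
  analyses, but the adaptive track itself is taken as logged — the
  in-session recommendations cannot be retroactively changed.
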