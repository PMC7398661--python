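# Methods

## Signal model

A session is modeled as

    F(t) = F_b · (1 + k · r(t)) · bleach(t) + B + ε(t)

where `F_b > 0` is the biological baseline fluorescence (a.u.), `B ≥ 0` a
rig background present with or without a mouse, `ε` white Gaussian noise of
standard deviation σ on the raw samples, `bleach(t) = exp(−t/τ_bleach)` an
optional mono-exponential decay (disabled by default, `τ_bleach = ∞`), and
`r(t)` a dimensionless stimulus-response kernel with `r = 0` before the
event. The attenuation factor `k ∈ [0, 1]` scales the response amplitude
multiplicatively and stands in for the diet-induced-obese state; the
generator stores `k·A` as the session's effective amplitude so downstream
estimates can be compared against exact truth.

### Kernels

All kernels are zero until an onset latency `ℓ`, then with `s = t − ℓ`:

| kind | form | emulates |
|---|---|---|
| `sensory` | `A(1 − e^{−s/τ_on})`, sustained | rapid inhibition at food presentation |
| `infusion_ramp` | linear from 0 to `A` over the ramp duration, then sustained | progressive inhibition across a 12-min infusion |
| `cck_transient` | `A(1 − e^{−s/τ_on})·e^{−s/τ_rec}` | transient inhibition with recovery |
| `ghrelin_rise` | as `sensory` with `A > 0` | sustained activation |

The transient kernel is the standard product form (approach × decay); its
peak is therefore slightly below `A`, which is immaterial because the
associated summary statistic is an AUC, not a peak.

### Default parameters

The source observations for these response shapes are qualitative
(population traces and heatmaps), so defaults are package choices, fixed
once and not tuned thereafter:

* amplitudes: `A = −0.25` (sensory), `−0.30` (infusion, CCK), `+0.30`
  (ghrelin) — i.e. 25–30% ΔF/F, the magnitude regime typical of bulk
  GCaMP recordings from these neurons;
* time constants: `τ_on` = 3 s (sensory, latency 2 s), 60 s with
  `τ_rec` = 420 s (CCK, latency 30 s), 120 s (ghrelin, latency 60 s);
  infusion ramp = 720 s, matching the 12-min infusion at 100 µL/min
  (total volume 1.2 mL);
* acquisition: 250 Hz sampling; `F_b = 10`, `B = 0.5` a.u.;
  `σ = 0.2` (2% of `F_b`); 3 trials per session;
* recording spans: 600 s before the stimulus (the F0 window needs 360 s;
  the default leaves margin) and 360/1620/2100/2100 s after it for
  presentation/infusion/CCK/ghrelin respectively;
* cohort structure: per-mouse amplitude drawn once as
  `Normal(A, 0.05)` and held constant across timepoints (between-animal
  variability enters the subject term of the ANOVA); attenuation
  `k = 1` throughout for lean controls and `(1, 0.4, 0.8)` at
  (baseline, wk6, wk10) for the DIO group — blunted at 6 weeks of
  high-fat diet, partially recovered 4 weeks after return to chow.

Noise is white on the raw fluorescence. The acquisition chain's lock-in
smoothing (~30 ms) can be emulated by an optional first-order filter on ε
(`noise_smooth_tau`), default off: the pipeline's own 0.5 Hz low-pass
renders any pre-smoothing immaterial.

## Conditioning chain

Order is fixed and enforced through provenance: background subtraction →
low-pass → downsample → align → trial average.

* **Filter.** Second-order Butterworth at 0.5 Hz applied forward-backward
  (`sosfiltfilt`, even-reflection padding), giving zero phase — a
  symmetric pulse keeps its peak location to within one sample, so event
  latencies are preserved. A causal filter would delay features by up to
  ~1/(2·cutoff) = 1 s. The first and last 2 s are flagged edge-affected.
* **Downsampling.** 25:1 bin means (250 → 10 Hz), output timestamps at bin
  centers. Bin averaging is exactly mean-preserving and suppresses
  residual broadband noise, unlike simple decimation.
* **No detrending.** Photobleach correction is deliberately absent; with
  low excitation power and ~1 h sessions a slow-drift correction risks
  over-correcting genuinely sustained responses.

## Quantification

* **F0**: median of samples with `t_rel ∈ [−360, −240] s`. "A 2-min window
  flanking the −5 min time point" is read as the symmetric window centered
  on −5 min; the window is configurable. The median makes F0 robust to
  transient artifacts in the baseline.
* **ΔF/F** is reported in percent. Scale invariance holds exactly: after
  background subtraction, multiplying a trace by any c > 0 leaves ΔF/F
  unchanged.
* **Windows**: presentation = [0, 300] s mean; infusion = mean over the
  final 2 min of the 12-min infusion, [600, 720] s (the closed-form value
  for a noiseless ramp of amplitude A is A·660/720, e.g. −27.5% for
  A = −0.30); CCK = AUC over [0, 1200] s; ghrelin = AUC over [0, 1800] s.
  AUC is the signed trapezoidal integral with time in minutes, so
  inhibition yields negative %·min. The end-of-infusion window placement
  is a package choice (the convention is stated only as "at the end of
  infusion") and is configurable.
* **QC**: a mouse is excluded when the magnitude of its baseline chow
  5-min mean is below 20 percentage points, boundary inclusive (a −20.0%
  response is kept). The criterion is applied to the window mean — the
  response statistic the rest of the analysis uses — since the defining
  convention does not specify peak vs mean. Mice with no baseline
  measurement are flagged unevaluable and reported, never silently kept.

## Behavioral scoring

Consumption = number of deliveries followed by at least one removal before
the next delivery (taking the first), minus the end-of-session drop count,
floored at zero. Removal events with no pending pellet are counted as
anomalies and reported; the naive alternative (total removals minus drops)
is also reported, and the two can disagree only on such malformed logs.
Dropped pellets are subtracted at session level, not attributed to
specific deliveries.

## Inference

* **One-way RM-ANOVA**: classical partition SS_subject + SS_within +
  SS_error on the complete subject × level pivot; F = MS_within/MS_error
  with (t−1, (n−1)(t−1)) df. With two levels this reproduces the paired t
  exactly (F = t²).
* **Two-way mixed ANOVA**: between-group effect tested against
  subjects-within-groups; timepoint and interaction against the
  subject × timepoint residual. With unequal group sizes the within-factor
  and interaction effects use observed-margin (group-size-weighted) cell
  means, which keeps the five components summing exactly to the total SS;
  for balanced designs this is the textbook partition. Agreement with
  pingouin's `mixed_anova` is exact on both balanced and unbalanced
  fixtures.
* **Degenerate data**: zero numerator and denominator variance returns
  F = 0, p = 1 rather than NaN. Missing cells are rejected naming the
  subject and level; there is no imputation.
* **Sphericity** is not corrected by default (no correction is part of the
  emulated convention); a Greenhouse–Geisser option is available for the
  within-subject effects.
* **Holm–Šídák**: `p_adj(i) = 1 − (1 − p_(i))^(m−i+1)` on ascending raw
  p-values with a running maximum for monotonicity. Contrast families
  mirror figure comparisons: paired across timepoints within group,
  unpaired between groups at each timepoint, or both in one family — the
  family is a user choice, not guessed.
* Tests are two-sided with α = 0.05.

## What the simulations do and do not establish

The generator reproduces the statistical structure the analysis assumes:
uniform sampling, additive Gaussian noise, a multiplicative response on a
positive baseline, trial replication, between-animal amplitude variance,
and group-by-timepoint attenuation. Passing recovery and discrimination
tests therefore establishes the correctness and calibration of the
*pipeline*. Real recordings additionally contain motion and cable
artifacts, hemodynamic contamination, non-exponential bleaching, sensor
nonlinearity, and animal-state drift between trials — none of which are
modeled, so the tests bound algorithmic error, not total experimental
error. Biological effect sizes reported by in-vivo studies depend on
per-animal data that are not publicly deposited; the package therefore
validates against simulated ground truth rather than reproducing animal
numbers.

## Problem sizes in the validation suite

Chosen as the package's own study conditions: noiseless recovery on a
k × A grid of 6 sessions; noisy recovery with 10 mice × 3 trials at
σ = 2% of baseline; type-I calibration from 2000 null cohorts simulated at
the summary-measure level (the F-test's calibration depends only on the
normal mixed model, so trace-level simulation would add cost without
information); discrimination from 200 full trace-pipeline replicates of a
10-mice-per-group design with one trial per session and the minimal 360-s
pre-stimulus span. The pellet-scoring oracle runs on 500 random logs of up
to 20 events, half dispenser-shaped and half adversarial orderings.

## Known limitations

* The two-way design supports exactly one between factor and one within
  factor; no mixed-effects modeling of missing cells.
* Event alignment is nearest-sample; sub-sample interpolation is
  pointless at 10 Hz output after 0.5 Hz filtering.
* Vendor acquisition formats (TDT, Doric binary) are out of scope; traces
  enter as CSV + JSON sidecar.
* The isosbestic (405 nm) reference-channel regression used by some rigs
  is not implemented — the emulated rig design does not record one.
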