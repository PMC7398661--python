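# fiberphot

Quantification and inference for **fiber-photometry calcium recordings** of
the kind used to track hypothalamic hunger neurons (AgRP neurons) across
longitudinal metabolic studies: food presentation, intragastric nutrient
infusion, and gut-hormone (CCK, ghrelin) injection paradigms, recorded in
lean and diet-induced-obese (DIO) cohorts at multiple timepoints.

The package is for experimentalists and analysts who need a tested,
scriptable version of the standard ΔF/F workflow — plus a synthetic session
generator with known ground truth, so every stage of the analysis can be
validated by parameter recovery rather than by eye.

## What it computes

**Trace conditioning.** Raw fluorescence `F(t)` (250 Hz) is background
subtracted (rig signal recorded without a mouse), low-pass filtered at
0.5 Hz with a second-order zero-phase Butterworth, and downsampled to 10 Hz
by non-overlapping bin means. No photobleach correction is applied.

**Peri-event normalization.** With time zero at the stimulus (chamber
opening, pump start, or injection), the baseline is

    F0 = median{ F(t) : t ∈ [−6, −4] min }

(the 2-min window flanking the −5 min time point) and

    ΔF/F(t) = 100 · (F(t) − F0) / F0   [percent].

**Summary statistics.** Window mean ΔFa/F0 (5 min after food presentation;
final 2 min of a 12-min infusion) or the signed trapezoidal AUC in
%·min (20 min post-CCK, 30 min post-ghrelin). Trials from the same mouse
are averaged and treated as a single replicate. Implants whose baseline
chow response magnitude is below 20 percentage points are excluded as
technical failures.

**Behavior.** Pellet-dispenser logs are scored by the first-removal rule:
a pellet is consumed at the first removal event after its delivery; pellets
found dropped at session end are subtracted from the total.

**Inference.** One-way repeated-measures ANOVA, two-way mixed-design ANOVA
(group × timepoint, with subjects-within-groups and subject × timepoint
error terms computed from first-principles sums of squares), Holm–Šídák
step-down multiple comparisons (`p_adj(i) = 1 − (1 − p_(i))^(m−i+1)` with
monotonicity enforcement), pooled-variance t-tests and OLS regression.

**Simulation.** Sessions are generated as
`F(t) = F_b·(1 + k·r(t))·bleach(t) + B + ε(t)` with white Gaussian noise
and a parametric stimulus kernel `r(t)` per paradigm (rapid sustained
inhibition, 12-min linear ramp, transient inhibition with recovery,
sustained activation). The factor `k ∈ [0, 1]` models DIO attenuation of
the response; the generator records the exact effective amplitude `k·A`
for parameter-recovery testing.

## Worked example

Simulate a longitudinal two-group study (6 mice per group, 2 trials per
session) in which the DIO group's sensory response is attenuated to
k = 0.4 at week 6 and partially recovers (k = 0.8) at week 10, then run
the full pipeline:

```python
import fiberphot as fp

cfg = fp.RunConfig(paradigm="presentation", seed=7, n_per_group=6,
                   n_trials=2, pre_duration=360.0, out_dir="demo")
bundle = fp.run(cfg)
print(bundle.anova.table())
```

```
              effect         ss  df         ms          F            p
               group 447.631525   1 447.631525  12.138370 5.881558e-03
subject_within_group 368.773987  10  36.877399        NaN          NaN
           timepoint 409.750272   2 204.875136 149.075641 9.637473e-13
     group:timepoint 410.393928   2 205.196964 149.309816 9.496742e-13
               error  27.486065  20   1.374303        NaN          NaN
```

The group × timepoint interaction (F(2, 20) = 149.3, p ≈ 1e-12) is the
signature of the simulated attenuation: mean ΔF/F in the 5-min
post-presentation window stays near −27% in lean mice at every timepoint
but collapses to −10.8% in the DIO group at week 6 and returns to −21.6%
after recovery. The accompanying Holm–Šídák contrasts localize the effect
(DIO week 6 vs baseline adjusted p = 5.2e-4; lean contrasts all
non-significant; groups indistinguishable at baseline). `fp.run` writes
`cohort.csv`, `stats.json`, per-timepoint heatmap matrices and a run log
with the seed and config hash; rerunning with the same seed reproduces the
bundle byte for byte.

The same operations are available from the shell:

```sh
fiberphot simulate --paradigm presentation --seed 4 --out session/
fiberphot quantify session/ --paradigm presentation --background 0.5
fiberphot run --seed 7 --out-dir demo
```

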