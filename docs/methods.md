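# Methods

## The measurement model

A walking bout is observed as *footfall events*: for each limb, the 1-D
position of each placement along the travel axis (cm for mouse, m for
human) and the times its stance and swing phases begin.  Consecutive
events of one limb define a gait cycle, from which we derive

- stride length `L` = distance between consecutive placements;
- cycle duration `T` = stance onset to next stance onset;
- stance time = stance onset to swing onset, swing time = swing onset to
  next stance onset, so stance + swing = `T` exactly by construction;
- stride velocity `v = L / T`;
- step length = own placement position minus the most recent opposing
  placement position (negative when the foot lands behind the opposing
  foot; ties in onset time break toward the earlier opposing event).

Strides never span trial boundaries, and all derived metrics are invariant
under translation of the position and time origins.  Frame-based inputs
are converted to seconds by the reader (120 fps is typical for runway
video; the rate is a reader argument, never stored).

## Speed-referenced regression

Every gait metric varies with speed, so comparisons are made between
*curves over stride velocity* within a fixed speed window — 3–16 cm/s for
mice (walking/trotting; a narrowed 4–16 window is used when too few slow
strides exist) and 0.3–1.5 m/s for humans.  The model ladder is

| family | form | parameters |
|---|---|---|
| linear | `b0 + b1 v` | 2 |
| one-phase association | `Y0 + (Plateau − Y0)(1 − e^{−Kv})` | 3 |
| two-phase association | `Y0 + SpanFast(1 − e^{−K_fast v}) + SpanSlow(1 − e^{−K_slow v})` | 5 |

The exponential forms follow the GraphPad convention, the de-facto
standard parameterisation in this literature.  Rate constants are bounded
positive and the two-phase fit is relabelled post hoc so `K_fast ≥ K_slow`
(resolving label switching).  Nonlinear fits use bounded trust-region
least squares with three data-driven starts (level from the curve ends, K
from the half-rise point, seeded perturbations); linear fits are solved
exactly.  Model promotion along the ladder requires an extra-sum-of-squares
F test to reject the simpler fit; the promotion alpha defaults to 0.05 and
is configurable (a stringent 0.001 makes whole-grid speed-window sweeps
robust to multiplicity).  The simplest adequate family is kept to avoid
over-fitting.  `sweep_speed_ranges` re-selects the model while trimming
the slowest (from a 0–1 bin upward) and fastest (from 25 downward) speeds
and reports the widest window over which one family is consistently
chosen.

Stance time behaves hyperbolically in `v` (a direct consequence of
stance = `L/v` − swing); it is analysed after the transform
`Y = 1 − log10(stance)`, `X = log10(v) + 1`, paired with the linear
family, for both species.  The log base is immaterial to linear-family F
tests (any fixed base is an affine re-expression).

### Curve sharing

Two datasets are compared by fitting one parameter set to the pooled
points versus independent parameter sets:

    SS_sep = SS_A + SS_B,  df_sep = n_A + n_B − 2p,  df_shared = n_A + n_B − p
    F = [(SS_shared − SS_sep)/p] / [SS_sep/df_sep],  p-value = F(p, df_sep) upper tail

"Sharing" means *all* parameters — for the linear family the test captures
slope and Y intercept jointly; partial sharing is deliberately not
implemented.  The comparison alpha defaults to 0.001: a stringent level
stands in for multiplicity control across metrics (no further correction
is applied) and guards against the pseudo-replication inherent in many
strides per subject.  Numerical guards: if the pooled fit is essentially
exact (SS_shared ≤ 1e-12 × total SS) or improves on the separate fits by
less than 1e-9 relative (optimizer noise), F is clamped to 0 with a logged
warning; if the separate fits are exact but pooling is not, the verdict is
"different" with p = 0.  The test is symmetric in its two datasets and
invariant under affine rescaling of x and y.

Two further guards are provided.  The runs test (Wald–Wolfowitz, about the
mean or any reference) checks for systematic deviation of residuals; we
report the normal-approximation Z with
`mu_R = 2 n+ n− / n + 1`, `sigma_R² = 2 n+ n− (2 n+ n− − n)/(n²(n−1))`,
and for n ≤ 50 an exact two-sided p from the closed-form runs
distribution (doubled smaller tail); values equal to the reference are
dropped.  The per-subject *averaged analysis* collapses each subject to
one (mean speed, mean metric) point per side, repeats the curve
comparison on those points and adds a two-tailed paired t test — if a
result survives averaging it is not an artifact of a few prolific
subjects.

## Alternation ratios and circular statistics

Interlimb coordination is summarised on the circle [0, 1), with 0 and 1
identifying identical events:

- spatial ratio = step length / the opposing limb's *spanning* stride
  (the stride whose cycle contains the placement), wrapped mod 1 so a
  negative step maps near 1;
- temporal ratio = (opposing footfall time − cycle start)/cycle duration,
  for cycles containing exactly one opposing footfall (cycles with zero or
  several are skipped and counted as arrhythmic).

Each ratio carries the stride velocity of the opposing
(denominator/cycle-defining) limb — the ratio is defined on that limb's
stride, so its speed is the natural label for speed-bin analyses.  Bins
default to [3, 10) and [10, 16] cm/s, the boundary going to the upper bin.

With `theta = 2*pi*ratio`, a series is summarised by the circular mean
direction and the mean resultant length `r = |Σe^{i theta}|/n` (1 = perfect
clustering).  Conditions are compared with the two-sample Watson–Williams
test, `F = c (N−2)(R1 + R2 − R)/(N − R1 − R2)` against F(1, N−2), with the
standard correction `c = 1 + 3/(8 kappa)` and kappa estimated from the
pooled within-sample resultant length by Fisher's approximation.  The
correction factor is always applied and reported in the result (toolbox
implementations differ here; a 10^4-permutation oracle in the test suite
bounds the resulting p within 0.01).  Warnings are attached for samples
below n = 5 and pooled resultant length below 0.45, the usual validity
guidance.  Polar plots are data exports first (angle, radius per group);
rendering is cosmetic and optional.

## Cohort utilities

Welch's t from (n, mean, SD) summaries uses
`t = (m1 − m2)/sqrt(s1²/n1 + s2²/n2)` with Welch–Satterthwaite degrees of
freedom, reported both raw and rounded (summary tables print integers).
Patient asymmetries fall on either side at random, so subjects with a
clinically rated shorter-left step have all left/right metrics swapped
before group analysis (an involution; controls and symmetric subjects keep
true sides).  Subgroup splits (postural-instability/gait-difficulty vs
tremor-dominant; clinically asymmetric vs symmetric) consume supplied
labels — the subtyping algorithms themselves are out of scope — excluding
and counting indeterminate subjects.  The left/right asymmetry ratio
defaults to min/max of the side means (bounded (0, 1], 1 = symmetric) with
a signed `(L−R)/(L+R)` alternative; the choice is recorded in the result
because published analyses rarely state their convention.

The bundled clinical summary table (`gaitasym.datasets`) carries the
example cohort's group statistics; where a measurement was missing for a
subject the effective n is recorded, since Welch df are sensitive to it.

## The simulator

`GaitProfile` specifies nominal curves for stride length and swing time,
a speed range, an opposing-limb spatial fraction (default 0.5) and
temporal phase (default 0.5), per-stride noise SDs, and an optional
asymmetry.  Generation lays down the reference limb cumulatively
(position += `L`, time += `T = L/v`) and places the opposing limb at the
configured fractions of each stride/cycle; stance is always derived as
cycle − swing, so the additivity invariant holds exactly and the stance
curve emerges hyperbolic, as in real data.  Asymmetries scale (or shift)
the opposing limb's spatial fraction and/or temporal phase, optionally
only inside a speed gate.

Mouse defaults: stride length one-phase (Y0 3 cm, plateau 8 cm,
K 0.15 s/cm), swing one-phase decaying 0.20 → 0.08 s, range 3–16 cm/s,
noise SDs 0.45 cm (stride), 12 ms (swing), 0.03 (placement and phase
fractions); fore pair generated 3.5 cm ahead of the hind pair.  Human
defaults: stride length linear 0.40 + 0.70 v m, swing one-phase
0.30 → 0.42 s, range 0.3–1.5 m/s.  These produce stride counts, cycle
durations and metric magnitudes in the range reported for mouse runways
and human gait mats.

Speed is sampled per trial: a target drawn uniformly over the range, with
small within-trial jitter (SD 4% of the range).  This was a deliberate
choice over iid per-stride draws: a limb's step length derives from the
*previous* stride of the opposite limb, so per-stride independent speeds
— which are also biomechanically impossible — decorrelate step length
from its attached velocity and manufacture a spurious left–right curve
difference in perfectly symmetric gait.  Trial-level targets match how
runway passes and instructed-speed gait-mat trials actually sample speed
(preferred/slow/very-slow/fast/very-fast); iid sampling remains available
as `speed_sampler="uniform"`.

All randomness flows from one seed through SeedSequence spawning per
subject/condition/trial; identical seed and profile give bit-identical
event tables.  Cohorts add a lognormal per-subject random effect (SD 0.05
on the log scale) to curve levels, shared across conditions so each
subject is its own control.  Three preset scenarios fix the study
conditions used throughout the tests: *unilateral* (right step length
scaled by 0.9 inside 10–16 cm/s — spatial asymmetry emerging at faster
walking, timing untouched), *bilateral* (stride ×0.8 and swing ×0.85 on
both sides — global slowing, no asymmetry) and *control* (two identical
assessments).

### What the simulator does and does not capture

It reproduces the speed dependence, noise scale, stance/swing additivity
and asymmetry structure of stride-level gait data, which is what the
statistical pathways consume.  It does not model kinematics, forces,
festination, freezing, dyskinesia, missing placements (occlusions), or
diagonal/ipsilateral limb coupling.  Passing scenario tests therefore
demonstrate that the *analysis* detects the asymmetries it should and
nothing else under realistic noise — not that any particular biological
model produces those asymmetries.

## Problem sizes and numerical choices

- Scenario cohorts in the tests: 12–17 subjects × 4 trials × 12
  strides/limb, matching typical runway study sizes.
- Type-I error of the curve-sharing test: 2000 null replicates at
  n = 100 strides/side (linear family), checked against binomial
  compatibility at alpha 0.001 and 0.05.
- Power property: a 10% one-sided step shortening at ~300 strides/side is
  detected at alpha 0.001 in >80% of replicates (30 seeded replicates).
- Watson–Williams is validated against a 10^4-permutation oracle on the
  circular mean-direction difference; circular summaries against a naive
  vector-sum oracle (1e-12) and pingouin; the runs-test exact p against
  exhaustive enumeration of sign arrangements; F tail probabilities
  against quadrature of the density (1e-6); noiseless parameter recovery
  to 1e-6 relative error for all three families.
- Invariant tolerance 1e-9 in input units; exact arithmetic is expected
  from extraction, so violations indicate corrupted input.
- Automatic outlier elimination exists nowhere in the validated paths and
  the pipeline configuration refuses to enable it.

## Known limitations

- The curve-sharing test assumes independent residuals within a dataset;
  with many strides per subject this is optimistic, which is why the
  stringent 0.001 alpha and the averaged analysis exist.  Mixed-effects
  models are deliberately out of scope (valid designs use each subject as
  its own control).
- The Watson–Williams test assumes von Mises samples with common, high
  concentration; results with pooled resultant length below ~0.45 carry a
  warning and should be read qualitatively.
- Welch df rounding can differ by one from published tables when the
  underlying means/SDs were rounded for printing.
- Step lengths whose opposing placement is missing are dropped and
  counted, not imputed.
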