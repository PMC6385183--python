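# gaitasym

Speed-referenced detection of left–right gait asymmetries in quadruped
(mouse) and biped (human) walkers.

Parkinsonian gait is often asymmetric, and the asymmetry can be *spatial*
(where the feet land) or *temporal* (when they land) — two phenomena that
occur independently and implicate different circuit mechanisms.  Because
every gait metric depends strongly on walking speed, naive side-by-side
averages confound asymmetry with speed differences.  This package
implements a translational toolkit that works identically for mouse runway
data (walking/trotting range, 3–16 cm/s) and human gait-mat data
(0.3–1.5 m/s):

1. **Stride metrics from footfall events.**  From each limb's placement
   positions and stance/swing onset times it derives stride length, step
   length (distance a foot lands past the opposing foot — negative if it
   lands behind), swing time, stance time, cycle duration and stride
   velocity *v* = stride length / cycle duration.

2. **Curve-sharing F tests.**  Each metric is modelled as a curve over
   stride velocity using a nested ladder — linear
   `y = b0 + b1·v`, one-phase association
   `y = Y0 + (Plateau − Y0)(1 − e^(−K·v))`, and two-phase association —
   promoted only when an extra-sum-of-squares F test demands it.  Two
   datasets (left vs right limb, or one limb before vs after an
   intervention) are compared by fitting one shared parameter set to the
   pooled points against independent fits:

       F = [(SS_shared − SS_sep)/p] / [SS_sep/(n_A + n_B − 2p)]

   with p parameters per curve.  For the linear family this captures slope
   and intercept jointly.  The comparison alpha defaults to a stringent
   0.001.  Stance time, which behaves hyperbolically with speed, is
   analysed after the log transform `Y = 1 − log10(stance)`,
   `X = log10(v) + 1` with the linear family.  A Wald–Wolfowitz runs test
   guards against systematic lack of fit, and a per-subject averaged
   analysis (with a paired t test) guards against pseudo-replication.

3. **Alternation ratios and circular statistics.**  Interlimb coordination
   is summarised on the circle [0, 1): the *spatial alternation ratio*
   (step length / opposing spanning stride length) and the *temporal
   alternation ratio* (opposing footfall phase within the cycle), both 0.5
   for perfectly symmetric gait.  Ratios are summarised by circular mean
   direction and resultant length r, and compared between conditions with
   the Watson–Williams test (alpha 0.05), optionally within speed bins
   (3–10 and 10–16 cm/s for mice).

4. **Cohort utilities.**  Welch's unequal-variance t test from published
   (n, mean, SD) summaries, left/right re-assignment so the shorter-step
   side is uniform across patients, subgroup splits on supplied clinical
   labels, and Pearson correlation of left/right asymmetry ratios between
   gait and clinical measures.

5. **A synthetic gait simulator** with configurable speed-dependent curve
   families, stride-to-stride noise, and injectable spatial/temporal
   asymmetries (optionally gated to a speed window) — the validation bed
   for every analysis path, emulating unilateral-lesion, bilateral-lesion
   and control study designs.

## Worked example

Simulate a unilateral-lesion cohort (12 animals, baseline and lesioned
conditions, 10% step shortening on the right gated to 10–16 cm/s), then
test left vs right step length in the lesioned condition:

```python
import gaitasym as g
from gaitasym.speedfit import CurveShareTest

profile, conditions = g.scenario("unilateral")
events = g.make_cohort(profile, n_subjects=12, conditions=conditions, seed=42)
ds = g.filter_speed_range(g.build_dataset(events), 3, 16)

res = CurveShareTest.from_dataset(
    ds.select(condition="lesioned"), "step_length", pair="hind").fit()
print(res.summary())
```

```
Curve-sharing F test
====================================================
model family:   linear
datasets:       LH (n=527), RH (n=522)
F(2, 1045) = 111.6
p = 1.177e-44   (alpha = 0.001)
verdict:        different
shared params:  intercept=2.309, slope=0.1027
LH params:       intercept=2.146, slope=0.1365
RH params:       intercept=2.488, slope=0.0666
```

The left and right step-length curves cannot share one parameter set
(p ≪ 0.001): the injected spatial asymmetry is detected.  The same
datasets through the circular route:

```python
s1 = g.spatial_ratios(*ds.select(condition="baseline").side_pair("hind")[::-1])
s2 = g.spatial_ratios(*ds.select(condition="lesioned").side_pair("hind")[::-1])
ww = g.watson_williams(s1, s2)
print(f"Watson-Williams: F(1,{ww.df_den}) = {ww.F:.2f}, p = {ww.p:.2e}")
```

```
Watson-Williams: F(1,1010) = 85.60, p = 1.28e-19
baseline: mean ratio 0.502, r = 0.983, n = 491
lesioned: mean ratio 0.483, r = 0.975, n = 521
```

The lesioned condition's spatial alternation ratio shifts away from the
symmetric 0.5 (0.483) while staying tightly clustered (r ≈ 0.98), and the
Watson–Williams test flags the change in circular mean.  Stride length,
swing time and stance time stay "shared" in this scenario — the asymmetry
is purely spatial, as in a unilateral dopaminergic lesion.

The same workflow is available from the shell:

```bash
gaitasym simulate --scenario unilateral --subjects 12 --seed 42 --out events.csv
gaitasym extract --events events.csv --out strides.csv
gaitasym compare --strides strides.csv --metric step_length --lo 3 --hi 16
gaitasym run --events events.csv --out report/
```

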