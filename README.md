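# rootposture

Quantitative phenotyping of plant root posture from digitized
centerlines.

Seedling roots grown along an agar surface are commonly traced by hand
(e.g. with the ImageJ/Fiji segmented-line tool) into an ordered polyline
from the root–hypocotyl junction (the *basal point*) to the root tip.
`rootposture` turns such traces into per-root posture statistics and
group-level nonparametric comparisons, and ships a synthetic wavy-root
generator with analytic ground truth so every stage of the pipeline can
be validated against closed-form answers.

## The indices

For a root of total centerline length *L* with base-to-tip displacement
(*L<sub>x</sub>*, *L<sub>y</sub>*) (horizontal and along-gravity
components) and Euclidean base-to-tip distance
*L<sub>c</sub>* = √(*L<sub>x</sub>*² + *L<sub>y</sub>*²):

* **HGI** = *L<sub>x</sub>* / *L* — horizontal growth index
* **VGI** = *L<sub>y</sub>* / *L* — vertical growth index
* **SI** = *L<sub>c</sub>* / *L* — straightness index (1 for a straight
  root; SI = √(HGI² + VGI²) by construction)

These global indices cannot distinguish a root with a few large, gradual
curves from one with many small, sharp kinks.  The **curvature index
(CI)** does: the centerline is resampled by spline to a uniform density
of 1,000 dots cm⁻¹, and at every dot the CI is the unsigned turning
angle between the two adjacent chords divided by the mean chord length —
a discrete |dθ/ds| in cm⁻¹.  A straight line has CI = 0 and a circle of
radius *r* has CI = 1/*r*.  The raw profile is smoothed with a centred
moving average of 0.005 cm before and after each dot (0.01 cm in total),
the first and last 20 dots are eliminated, and per-root summaries are
computed: the 1%-trimmed mean (0.5% lowest and highest values removed),
the maximum, the number of dots exceeding a threshold (default
50 cm⁻¹), and plain means within arc-length compartments (0.0–0.5,
0.5–1.0, ≥1.0 cm from the basal point).

Because manually clicked dots carry positional noise that an
interpolating spline would convert into spurious curvature, the
resampler fits a noise-adaptive penalized smoothing spline; the noise
level is estimated from the trace itself and noise-free traces are
interpolated exactly (see `docs/methods.md`).

For gravistimulation assays the **tip angle** is the signed angle
between the horizontal plane and the root-tip direction (0° horizontal,
+90° pointing along gravity), summarized per group in 20° classes.

Group comparisons use the tie-corrected Kruskal–Wallis rank ANOVA, the
asymptotic Steel–Dwass all-pairs procedure (studentized range), the
Brunner–Munzel test with optional Bonferroni correction, and
compact-letter displays (groups share a letter iff not significantly
different at α = 0.05).

## Worked example

Simulate three cohorts — straight roots, gradual wavers and sharp
kinkers — digitize them with a manual-marking noise model, and measure:

```python
import rootposture as rp

coll, truth = rp.make_cohort(
    {"wild_type": rp.straight(), "waver": rp.gradual_wave(), "kinker": rp.sharp_wave()},
    n_per_group=10, model=rp.DigitizerModel(n_points=250), seed=7)
df = rp.measure_collection(coll).results_frame()
print(df.groupby("group")[["L", "SI", "ci_mean", "ci_max", "n_exceed"]].mean().round(3))
```

```
               L     SI  ci_mean  ci_max  n_exceed
group
kinker     1.741  0.862   15.719  35.654       0.0
waver      2.197  0.911    4.164   7.807       0.0
wild_type  2.003  0.997    0.051   0.185       0.0
```

Straight roots measure SI ≈ 1 and CI ≈ 0; the kinkers' mean CI is ~4×
the wavers' (their wave is 4× sharper) even though both are far from
straight.  Comparing the mean CI across groups:

```python
cmp = rp.compare_groups(df, "ci_mean")
print(f"Kruskal-Wallis H={cmp.omnibus_H:.2f}, p={cmp.omnibus_p:.3g}")
print(cmp.letters)
```

```
Kruskal-Wallis H=25.81, p=2.49e-06
{'wild_type': 'a', 'waver': 'b', 'kinker': 'c'}
```

All three groups are pairwise distinct (Steel–Dwass p = 0.0005 for each
pair), so each gets its own letter.  `rp.bonferroni_threshold(0.05, 9)`
returns 0.00556, the family-wise significance bar for a battery of nine
such rank ANOVAs.

The same works from a shell:

```sh
rootposture simulate --archetype gradual_wave --n 30 --seed 42 --out traces.csv
rootposture measure traces.csv --out-dir out/ --figures
rootposture compare out/results.csv --index SI --index ci_mean
```

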