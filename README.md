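# apicodyn

Quantitative analysis of **pulsed apical constriction and cell ingression
in segmented epithelia**, with a fully ground-truthed synthetic data
generator.

During epithelial-to-mesenchymal transitions such as mouse gastrulation,
epiblast cells at the primitive streak constrict their apical surfaces in
a ratchet-like sequence of contraction pulses separated by stable phases,
shrink their junctions asynchronously, and finally ingress — their apical
footprint disappears from the epithelial plane. Fixed-tissue imaging of
the same cells shows junctional proteins (actomyosin components, Crumbs
complex) accumulating anisotropically and reciprocally across the
junctions of single cells. `apicodyn` implements the measurements behind
these observations as a tested, reusable pipeline for tracked
segmentation label images (or equivalent long-format CSV tables), aimed
at quantitative developmental biologists who already have segmented,
tracked time-lapse data.

## What it computes

**Constriction kinetics** — signed rate series with the convention

    rate(t) = (area(t−1) − area(t)) / Δt        [µm²/min, positive = contraction]

a reference pulse threshold *mean + k·SD* of pooled contraction rates of
non-ingressing cells (k = 1 by default, ≈ 0.7 µm²/min under the default
generator conditions); constriction pulses as maximal supra-threshold
runs with magnitude = max rate in the run; constriction-period bounds;
time fractions spent contracting/expanding/stable; per-junction shrinkage
rates by pulse/stable phase; junction-pair length correlation matrices.

**Ingression events** — detection of label disappearance (censoring
border and movie-end tracks), isolated vs clustered classification with
the 30-min / neighbor-adjacency rule (strict boundary: ≥ 30 min apart is
isolated), per-hour ingression rates in the ~40 µm streak domain, and
track displacement/convergence summaries.

**Junctional anisotropy (fixed tissue)** — intensity measured along
3-px-wide (~500 nm) junction bands; normalization per embryo, per cohort
or to the medial (cytoplasmic) pool; per-cell anisotropy as the sample SD
and Max/Min ratio of junction mean intensities; planar-polarity nematics

    Q = Σⱼ wⱼ·e^{2iθⱼ} / Σⱼ wⱼ ,  wⱼ = Iⱼ·Lⱼ ,  magnitude |Q|, axis ½·arg Q

15°-bin orientation profiles; and pairwise channel correlation with a
low-intensity junction filter that reveals reciprocal (anti-correlated)
enrichment confined to high-intensity junctions.

**Group statistics** — unpaired two-sided Mann-Whitney U (exact for small
samples), one-way ANOVA, and WT-vs-mutant reporting tables with
significance stars.

**Synthetic generator** — a Lloyd-relaxed Voronoi epithelium evolved as a
shared-vertex polygon mesh: ingressing cells follow programmed pulse
schedules realized by scheduled junction-edge contraction (neighbors
absorb the freed area), non-ingressing cells oscillate with zero mean,
and painted channels carry a two-group latent structure (actomyosin-like
vs Crumbs-like) plus a planar-polarized control. Every programmed event
is echoed in a machine-readable ground truth.

## Worked example

```python
from apicodyn import pipeline

out = pipeline.run(
    {"seed": 3,
     "simulate": {"n_cells": 36, "n_frames": 24, "ingressing_fraction": 0.3}},
    "demo_run",
)
```

simulates a 36-cell epithelium for 24 five-minute frames, measures it,
and writes `annotations.csv`, `pulses.csv`, `events.csv`, `threshold.json`
and `summary.json`. Summarizing those artifacts prints:

```
pulse threshold : 0.621 um2/min (reference mean 0.227 + 1 x SD 0.393)
ingressing cells: 7 annotated
pulses per cell : 2.86 (range 2-4)
pulse magnitude : 1.57 um2/min mean
mean constriction rate: 0.81 um2/min
time contracting: 83%
events          : 7, cluster sizes {'1': 0.714..., '2': 0.285...}
```

Reading: the pulse threshold was rebuilt from this movie's own
non-ingressing cells (mean + 1 SD of their pooled contraction rates); the
seven ingressing cells showed 2–4 constriction pulses each with mean
pulse magnitude 1.57 µm²/min, spent 83% of their constriction period
contracting, and five ingressed alone while two ingressed as a pair
(within 30 min of an adjacent neighbor).

The same pipeline is available from the shell:

```sh
apicodyn run --config run.yaml --seed 3 --out demo_run
apicodyn show-config          # all defaults, including every constant above
```

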