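# Methods

This note documents the models, conventions and numerical choices behind
`apicodyn`, and what the synthetic benchmark does and does not show about
real microscopy data.

## Input model and conventions

The canonical input is a tracked label-image series: one 2D integer
image per time point where a given positive label denotes the same cell
wherever it appears, label 0 is exterior/background, and optional
co-registered fluorescence channels share the label grid. Calibration
carries the pixel size (µm/px, default 0.17 so that a 3-px line is
~0.5 µm), the frame interval (min, default 5) and, optionally, the
x-position of the tissue midline with a streak half-width (default
20 µm, i.e. a 40 µm domain).

Conventions, fixed once and used everywhere:

* coordinates: x = column axis, y = row axis (pointing down), origin at
  the top-left pixel center; physical units via the pixel size;
* frames are 0-based; time = frame × interval;
* angles are degrees from +x folded to [0, 180), because junction and
  polarity orientations are axial (180°-periodic) quantities;
* cells touching the image border are flagged and excluded from
  per-cell statistics (their geometry is censored by the field of view);
* CSV outputs are UTF-8, comma-separated, "." decimal, with headers.

## Geometry extraction

**Cells.** Area = pixel count × pixel size²; elongation from the
eigen-decomposition of the second central area moments: with a ≥ b the
equivalent-ellipse semi-axes, index = (a−b)/(a+b) (0 = disc, → 1 = line)
and the angle is the major-axis direction. A per-pixel variance term
(px²/12) regularizes single-pixel degenerate cases; near-isotropic cells
are flagged `angle_unstable`. This satisfies the 0-to-1 endpoints of the
elongation index reported by segmentation tools while being size
invariant.

**Junctions.** The skeleton of junction {L, M} is the set of pixels
8-adjacent to exactly one other label; pixels adjacent to two or more
other labels are tricellular vertices and belong to no junction (vertex
puncta would bias intensity means). Length is the geodesic length of the
one-sided skeleton chain (longest shortest path through the 8-connected
pixel graph, + 1 px for endpoint extent, calibrated); orientation is the
chord between the chain endpoints. The chord is robust for short
junctions; a PCA alternative was considered and rejected as less stable
below ~6 px. The exact skeleton rule inside interactive segmentation
tools is not published; this 8-connectivity rule is a documented
stand-in, and the handshake identity (Σ per-cell junction counts =
2·interior + border junctions) plus rotation consistency pin its
behavior.

**Intensity.** Junction intensity is the channel mean over the skeleton
dilated to a 3-px-wide band, clipped to the two member cells, with
tricellular vertices and any pixel at least as close to another
junction's skeleton excluded — bands of neighboring junctions therefore
never overlap, which makes painted ground truth exactly recoverable on
noiseless fixtures. Medial (cytoplasmic) intensity is the mean over the
cell mask eroded by 3 px; if erosion empties a sliver cell the
measurement falls back to non-boundary pixels and warns.

**Tracks.** Per-entity series are assembled from stable labels;
one-frame dropouts are bridged by linear interpolation and flagged;
longer gaps split a track (fresh id, warning). A junction track persists
while its member pair shares a boundary.

## Constriction kinetics

Rates follow Δvalue(t) = value(t−1) − value(t), divided by the frame
interval: positive = contraction (µm²/min) or shrinkage (µm/min). Rates
are never smoothed — the published per-5-min derivative is the object of
interest; smoothing exists only inside period detection. The telescoping
identity Σ rate·Δt = first − last holds exactly and is tested.

**Pulse threshold.** mean + k·sample SD (n−1; small per-embryo samples)
of pooled positive rates of reference (non-ingressing) cells, k = 1 by
default. Under the generator's default oscillation this reproduces the
~0.7 µm²/min epiblast reference value.

**Pulses.** Maximal runs of frames with rate > threshold; runs separated
by ≤ merge_gap sub-threshold frames can be merged (default 0). Magnitude
is the maximum rate within the pulse; occurrence is pulses per unit
time. The original pulse counts were curated manually; this maximal-run
automation is this package's addition and its parameters are exposed
rather than asserted as the authors' procedure. Note the pulse *count*
is deliberately not monotone in the threshold (a run can split across a
dip); the supra-threshold frame *set* is monotone and is the tested
invariant.

**Constriction period.** The verbal definition — the moment a cell
starts reducing its apical area "and so continually" until the apical
domain is lost — is operationalized as: ingression frame = last present
frame; start = the latest frame whose moving-average area (window 3) is
within the re-expansion tolerance (0.5 µm²) of the track's peak, with no
later re-expansion above it and a remaining decline of at least half the
area at that frame. A literal "latest frame with no re-expansion and
≥ 50% decline" is degenerate (frames just before ingression qualify);
anchoring the start at the area peak reproduces the intended
flat-then-decline behavior (onset ± half smoothing window). Tracks
ending at the movie end or at the border are censored, not annotated.

**Phases.** Contracting ⇔ rate > ε, expanding ⇔ rate < −ε, stable
otherwise; ε defaults to 0 (rasterized areas make exact zeros common
enough that the three-way split is meaningful). The per-cell mean
constriction rate is (area(start) − area(end)) / period duration.
Junction shrinkage is averaged per phase (pulse_1, stable_1, …);
junctions absent in a phase yield missing values, never zero.

## Ingression events

An event is a track that ends by label disappearance before the final
frame with its last record off the border. Two events are clustered when
they are < 30 min apart (strict: exactly 30 min is isolated) and the
cells were adjacent neighbors; connected components of this relation
define clusters, so chained clusters spanning > 30 min end-to-end are
allowed. Adjacency defaults to "ever adjacent while both cells existed":
evaluating adjacency at the last common frame — the other natural
anchor — proved unreliable even on clean synthetic data, because a fully
constricted cell routinely loses raster contact with a co-constricting
partner a few frames before its label disappears. The stricter rule
remains available (`adjacency="last_common"`). Without neighbor-exchange
events the two rules differ only at this collapse artifact; with heavy
tissue rearrangement the "ever" rule can over-link cells that separated
long before ingressing, which the 30-min window mitigates.

The per-hour ingression rate slides a 60-min window one frame at a time:
(# events in window and domain) ÷ (# cells present in the domain at the
window start), reported as mean ± s.e.m. across windows. Window-start
occupancy (not time-averaged occupancy) is the documented denominator
choice. The streak domain is |x − midline| ≤ half-width; the midline is
a config input, with an optional kernel-density estimator left off by
default.

## Junctional anisotropy and polarity

Normalization modes: per-embryo grand mean (default), pooled-cohort
grand mean (for WT-vs-mutant intensity comparisons), or medial — each
junction divided by its own cell's medial mean, junctions between two
cells using the mean of the two. Per-cell anisotropy uses the sample SD
and the Max/Min ratio of the cell's junction means; cells with fewer
than 3 retained junctions, or any non-positive intensity, are excluded.
Whether the SD is computed on embryo-normalized or raw intensities is a
flag (embryo-normalized by default).

Planar polarity is the length- and intensity-weighted nematic order
parameter Q (weights I·L: intensity and the junction-geometry term);
cell-shape elongation is reported separately rather than folded into the
weights. |Q| ∈ [0, 1]; the axis is undefined (flagged) below 1e−6. For a
single cell with uniform intensity, |Q| vanishes only on centrally
symmetric shapes; on irregular cells it reflects shape anisotropy, so
the symmetry check for an unpolarized channel is the *population mean*
nematic vector (`mean_polarity`), which vanishes when per-cell axes are
random. Orientation profiles use half-open 15° bins ([0,15), …,
[165,180)).

Channel-pair correlation min-max normalizes both channels to [0, 1] per
embryo using the 1st–99th percentiles (hot-pixel resistant; exact
min/max by flag), optionally removes junctions whose two-channel maximum
is at or below the q-quantile of that maximum (q = 0.5 by default — the
published analysis filters "low intensity" junctions without stating a
threshold, so q is exposed and acceptance checks sign recovery, not a
specific r), and returns pooled Pearson r (Spearman by flag) or the
per-cell r distribution.

## Statistics

Mann-Whitney U is two-sided and unpaired, exact (full U null
distribution) for n_a + n_b ≤ 20 without ties, tie-corrected normal
approximation otherwise. One-way ANOVA uses the F distribution; all
groups identical constants is flagged degenerate. The genotype report
gives means ± s.e.m. (cells pooled across embryos — the cell-level unit
is the default, switchable) and raw p-values; Benjamini-Hochberg is
available but off by default, matching the reporting convention of the
figures this mirrors. Embryo-level mixed-effects modeling is a known
limitation, not attempted here.

## Synthetic generator

The generator exists so every stage can be verified without microscopy
data. It is *not* a mechanical model: geometry evolves by per-frame
re-rasterization of a shared-vertex polygon mesh (Lloyd-relaxed Voronoi
partition of a rectangular field), chosen for testability and speed over
force balance.

Study conditions realized by the defaults: mean apical area 45 µm² with
a natural 20–80 µm² spread (one Lloyd iteration keeps the spread);
5-min frames; ingressing cells with 2–4 constriction pulses of magnitude
~N(1.4, 0.35²) µm²/min truncated to [1.0, 4.6]; stable phases between
pulses with small, occasionally negative rates (mean 0.12, SD 0.18,
clipped below the 0.7 threshold); schedules consume the cell's area to a
sub-pixel remnant within a ≤ 90-min period, scaling pulse rates toward
the 4.6 ceiling when the slot is short. Realized aggregates under these
conditions: ~90% of constriction-period frames contracting, mean
expansion rate ~0.07 µm²/min, mean per-cell constriction rate
~0.9–1.0 µm²/min, mean pulse magnitude ~1.48 µm²/min (truncation raises
it slightly above the 1.4 location parameter).

Non-ingressing cells breathe via sinusoidal vertex motion; their
analytic counterpart draws per-frame rates a·sin(2πt/P + φ) + ε with
per-cell amplitude a ~ U(0.15, 1.1) µm²/min, period P ~ U(20, 50) min
and noise SD 0.12. These constants were calibrated once so the pooled
positive rates have mean + 1 SD ≈ 0.7 µm²/min — the reference-threshold
construction — and ~50% contracting-time fraction; they are study
conditions, not free parameters.

Ingression is realized by contracting the scheduled junction edges of
the cell (each pulse owns a subset of junctions, so junctions shrink
asynchronously and the scheduled set ranks fastest in its phase);
per-edge contraction is capped at 85% so a constricting cell keeps
contact with all neighbors until its label disappears, as real cells do.
When scheduled edges saturate, a whole-cell centroid contraction
finishes the frame's area target (bisection on the contraction
parameter against the polygon shoelace area). Shared vertices guarantee
neighbors absorb every freed pixel: total labelled area is conserved
frame to frame. Cluster plans (isolated/pair/triplet/quadruplet groups)
are placed on the mesh adjacency with a one-cell halo between groups so
the 30-min rule recovers the plan exactly; an explicit
`{size: count}` plan raises if unplaceable, and the halo can be disabled
for dense ingression-rate runs. Border cells never ingress (their
unshared field edge cannot hand area to a neighbor, and they are
censored downstream anyway).

Painted channels draw one latent strength and one latent activity per
junction. On the top-tertile-strength junctions, actomyosin-like
channels scale with the activity and Crumbs-like channels with its
complement (anti-correlated); low-strength junctions draw independent
intermediate values chosen so the pooled correlation is near zero —
reproducing the signature that reciprocal enrichment appears only after
filtering low-intensity junctions. A control group paints a
planar-polarized channel ∝ 1 + amp·cos 2(θ − axis), and a uniform group
a homogeneous membrane marker. Bands are painted with the same 3-px band
definition the measurement uses, then optionally Gaussian-blurred and
Poisson-noised.

What the generator does **not** emulate: neighbor exchanges (T1s, off by
default), cell division, out-of-plane curvature, uneven illumination,
segmentation errors beyond rasterization noise, and mechanical coupling
between neighbors' oscillation phases. Passing tests therefore
demonstrate the correctness of the measurements and detectors on data
with the assumed statistical structure — not robustness to segmentation
noise or tissue rearrangement.

## Numerical choices and problem sizes

Seeds: one global seed fans out to per-stage children via
`SeedSequence.spawn`; all seeds stay below 2³¹; fixed seeds give
bit-identical label grids and byte-identical CSVs. Rasterization assigns
each pixel to the first polygon (ascending label) claiming it, with
unclaimed boundary pixels filled by nearest labelled pixel. Bisection
uses 40 iterations. Correlations match the textbook formula to 1e−12;
the polarity nematic matches a direct complex sum to 1e−12.

Default verification sizes — chosen as the package's own benchmark
scale: 200 programmed cells for pulse-recovery statistics (analytic area
schedules; the raster path is exercised end-to-end on 36–60-cell
tissues), 3 × 60-cell pseudo-embryos for the ingression rate, 5 for the
cluster mix, 100 seeded draws for correlation-sign recovery, and 10,000
replicates for the ANOVA type-I simulation.
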