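# Methods

## The division-site statistic

A dividing rod is described by its two pole-to-septum distances d₁, d₂.
The mother length is their sum, the daughter is the smaller distance, and
the relative division site is S = min(d₁, d₂)/(d₁ + d₂), confined to
(0, ½] by construction.  Because phase-contrast images do not identify
which pole is which, S is mirrored: every observation S < ½ is represented
by the pair {S, 1 − S} with weight ½ each, and S = ½ by a single
unit-weight point.  Weighted mirroring (rather than duplicating rows)
keeps the effective sample size equal to the number of cells, so
histograms and densities remain per-cell normalized, and it makes the
estimated density exactly symmetric about ½.

Cells are gated by mother length into three classes — short (L ≤ 5 µm),
mid (5 < L ≤ 8 µm) and long (L > 8 µm).  The boundaries are left-open /
right-closed; the 5 and 8 µm values reflect where asymmetric division at
⅓ and ¼ begins to appear in populations of this kind.  Within a class, S
is assigned to the nearest canonical fraction of the class's allowed set
(short {½}, mid {½, ⅓}, long {½, ⅓, ¼}); a distance tie (to floating-point
tolerance) goes to the larger, more symmetric fraction.  This
nearest-fraction gate is a reproducible surrogate for grouping scatter
plots by eye.  The per-class mean of S is reported as the slope of the
line daughter = S̄ · mother through the origin, with its SD and n.

## Density estimation and modes

The mirrored sample is smoothed with a weighted Gaussian KDE (Silverman's
bandwidth rule by default; a numeric override is accepted) and evaluated
on a regular grid over [0, 1] with step 0.005.  Modes are local maxima
whose topographic prominence is at least 10% of the global maximum,
with the prominence evaluated inside a 0.2-wide window around each peak.
The window matters: it is the spacing scale of the canonical fractions
(⅓ to ½ is ≈ 0.17), so genuine fraction modes keep their prominence while
the broad featureless hump that any KDE produces from uniform data does
not qualify — without the window, the single widest bump of a structure-
free sample would always be reported as a mode.  Histograms use a fixed
bin width of 0.02.

## Placement-model contrast

Two hypotheses about where septa can form are compared on the mirrored
data as equal-weight Gaussian mixtures truncated to (0, 1) and
renormalized component-wise:

- **odd_fraction** — sites at ½ for short cells, {⅓, ½, ⅔} for mid, and
  {¼, ⅓, ½, ⅔, ¾} for long cells;
- **min_system** — sites at the even fractions k/(2m), k odd, produced by
  a Min-type oscillator with m potential sites; m is tied to the length
  class (short 1, mid 2, long 3), since the number of Min wave nodes grows
  with cell length.

Each cell contributes its mirrored, weighted points to the likelihood of
the fraction set selected by its own length class.  The component SD
(`noise_sd_S`, default 0.02) represents measurement scatter of S; equal
component weights are used because no prevalence information exists for
the alternative model.  Reported per model: total weighted log-likelihood,
BIC with k = number of distinct fractions used, and the winner by
log-likelihood; numerically identical likelihoods (e.g. short-cell-only
data, where both models reduce to a single site at ½) are reported as a
tie.  Increasing `noise_sd_S` broadens both mixtures equally and does not
flip the winner on well-separated data.

## Synthetic populations

The generator emulates the statistical structure the analysis assumes,
with parameters fixed at the study conditions:

| parameter | default | meaning |
|---|---|---|
| length distribution | log-normal, mean 2.0 µm, SD 0.6 µm | typical rod sizes |
| tail | 8% uniform on 5–12 µm | elongated cells populating the mid/long classes |
| class boundaries | 5, 8 µm | division-fraction switch points |
| class fractions | ½, ⅓, ¼ | true septum position per class |
| sphere rate | 0.007 | rare inert spherical cells (0.7% of the population) |
| appendage rate | 0.02 | polar spherical appendages on rods |
| noise_sd | 0.05 µm | SD of one manual pole-distance measurement |
| segment_length | 10 µm | span of a single manual measurement |

The 0.05 µm measurement noise (≈1.7 px at 0.029 µm/px) is a judgement
call — manual click accuracy of about two pixels — since no empirical
error figure exists for hand measurements; it is exposed in the config.
Distances longer than `segment_length` are simulated as k = ⌈d/segment⌉
summed sub-measurements with independent noise, so their variance is
k·noise_sd², matching how an operator chains measurements across a long
cell.  Spheres and appendaged cells never carry division sites: the
spherical bodies are inert, not daughter cells.  The canonical 300-cell
dataset (`make_reference_measurements`) fixes the composition at 200
short, 70 mid and 30 long dividing cells.

The renderer draws spherocylinders (length = pole to pole, width =
diameter) placed by rejection sampling of non-overlapping poses, with a
Gaussian-profile width constriction (default relative depth 0.3, σ =
0.15 µm) at the true division plane of dividing cells, an optional
tangent polar disk for appendages, phase-contrast-like contrast (cells
darker than background), Gaussian PSF blur (σ = 1 px) and additive
Gaussian noise.  The label mask is unblurred.  Pixel size defaults to
0.029 µm.

What the generator does **not** emulate: touching/overlapping cells in
dense fields, uneven illumination, focus drift, halo artifacts of real
phase contrast, curved or branched cells, ternary fission, and the rare
engulfment of rods by spherical structures.  Tests passing on these
synthetic scenes therefore validate the measurement chain's geometry and
statistics, not its robustness to the full messiness of real micrographs.

## Morphometry

Segmentation is a global Otsu threshold on the inverted image followed by
8-connected labeling and removal of components under `min_area` (50 px).
Cell length is the geodesic length of the skeleton's diameter path plus
the end-cap extent at each tip; three numerical details keep the bias
under a pixel:

- the diameter path (longest shortest path through the skeleton graph)
  implicitly prunes side branches;
- the 8-connected path zigzags around the true centerline, inflating its
  chamfer length by up to ~8% depending on orientation, so path
  coordinates are smoothed with a 7-px moving average before arc lengths
  are taken;
- the discrete skeleton stops short of the cap centers, so each end is
  extended by marching along the local tangent and taking the maximum of
  (distance + EDT), minus half a pixel for the raster bias of the
  Euclidean distance transform.

Width is twice the **median** EDT value along the axis (median, not mean,
so the septal dip does not bias it).  A region is classified as a sphere
when length/width ≤ 1.5 (`aspect_cutoff`; no published criterion exists,
so this conservative aspect gate is configurable), and as a cluster —
excluded from summaries, mimicking manual curation of stuck-together
elongated cells — when the skeleton carries substantially more off-path
pixels than a single rod's spurs would produce.

Constrictions are local minima of the smoothed width profile along the
axis with relative depth ≥ 0.15 versus the median width, at least 0.3 µm
(`pole_exclusion`) from either end; nearby minima within one cell width
are merged and each minimum is refined to sub-pixel position by a
parabolic fit around the dip.  On noise-free renders the detector has
recall 1 and no false positives at depth 0.3, and recall degrades
monotonically as the depth approaches the threshold on noisy profiles.

Population summaries report per-replicate and pooled n, rod length/width
mean ± SD and the sphere fraction, in a layout directly usable for
superplots (per-cell points plus per-replicate means).

## Taxonomic markers

Percent identity between aligned 16S sequences is matches / compared
columns × 100 with an explicit convention: mutual-gap columns and
terminal-gap overhangs are skipped; internal gap-vs-base columns count as
mismatches by default (a `skip` policy is available, since alignment
tools differ and the convention of the original matrix tool is
undocumented).  Rank verdicts use inclusive lower bounds at 94.5%
(genus), 86.5% (family) and 82.0% (order), so a value exactly at a
threshold counts as at-or-above — consistent with reading 82.8% as above
the order threshold.

POCP counts a query protein as conserved when it has a hit with e-value
< 1e-5, identity > 40% and alignable length > 50% of the query, and is
(C1 + C2)/(T1 + T2) × 100 over the two reciprocal searches; the cutoffs
live in a config object (`PocpCutoffs`), not in the code path.

Genome feature arithmetic (genes/Mb, protein-coding genes/Mb, %
hypothetical proteins) rounds half-up to integers, which reproduces all
published integers from the underlying counts (including 5641 genes on
6.784 Mb → 831.46 → 831).  The published per-genome counts for the six
reference strains are bundled as constants; every derived column is
recomputed at run time.

## Problem sizes and determinism

The default analyses run at the study scale: 300 dividing cells for the
division-site statistics, 20,000 cells for population composition, 100
seeds for the model-comparison win rate, and single-cell renders at
0.029 µm/px for morphometry validation.  All stochastic steps consume a
`numpy.random.default_rng` seeded from the user-supplied seed (sub-streams
use fixed offsets), so identical configuration and seed give bit-identical
populations, scenes and output files.

## Known limitations

- The morphometry chain assumes isolated, roughly straight rods; touching
  cells are flagged and excluded rather than split.
- The cluster flag and the sphere aspect cutoff are heuristics standing in
  for manual curation; both are configurable but not validated against
  hand-curated data.
- The model contrast assumes one septum per record and equal component
  weights; it is a likelihood comparison of site locations, not a
  mechanistic simulation of Min oscillations or FtsZ dynamics.
- Identity values depend on the upstream aligner's gap placement; small
  deviations from published matrices are expected when conventions differ.
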