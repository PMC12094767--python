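# Methods

## Scope and model of the data

`shgfiber` analyses paired forward/backward second-harmonic-generation (SHG)
images of fibrillar collagen. A study consists of two cohorts of tumor
samples (the default design uses 10 and 17 samples), each imaged at 20
randomly chosen sites; a site is a pair of 512x512 8-bit frame stacks (20
frames per channel) covering an approximately 45.96 um square field of view.
Because no raw patient images are publicly deposited, the package ships a
synthetic scene generator whose outputs carry exact ground truth, and every
downstream stage is validated by parameter recovery against that truth
rather than against any external image set.

### Pixel size

The acquisition geometry states both a 45.96 um square field at 512 px and
"approximately 0.13 um/px", which are mutually inconsistent
(45.96/512 = 0.0898 um/px). The package treats 45.96/512 as the sampling
pitch and reads the 0.13 um figure as the optical resolution of the
system, not the pixel pitch. `pixel_size_um` is configurable everywhere it
matters (fiber thickness is the only metric that uses it).

## Synthetic scenes (`shgfiber.synthetic`)

Fibers are correlated random walks: the initial orientation is von Mises
(axial, concentration `orientation_kappa`; 0 = isotropic), each 1-px step
turns by Normal(0, `step_angle_sd`) degrees, and the drawn length is a
truncated Normal with floor `length_min` (default 20 px — shorter bundles
are not resolvable as lines at a 15 px line width). With probability
`branch_prob` a fiber spawns one branch at a random interior vertex at a
Normal(45, 10) degree relative angle, inheriting the parent's width,
intensity and FB ratio. Each fiber is rendered with a Gaussian cross-section
(FWHM = `width`) into a continuous forward field; the backward field shares
the geometry with amplitude divided by the fiber's FB ratio, and both sit on
a common `background_level`. Ground truth records total centerline length,
endpoint/branchpoint counts, mean width, the doubled-angle circular
resultant of the root orientations (the axial order parameter), and the mean
FB ratio.

Per-fiber FB ratios are drawn from a two-mode mixture centered at 50 and
225 on the 8-bit ratio axis, matching the bimodal per-segment cluster
structure the analysis is designed to resolve.

### Noise model

Frames are quantised Poisson photon counts: a frame value is
`round(gain * Poisson(field / gain))` clipped to [0, 255], with
`detector_gain` in DN per detected photon (default 0.2, i.e. five photons
per digital unit, a typical PMT/preamp scaling). Pure Poisson noise at DN
scale (gain 1) is available but makes the backward channel of high-FB
fibers (ratio 225 means a backward signal near 1 DN) so noisy that
saturation censoring biases per-segment ratio means down by ~15%, which no
real acquisition showing a cluster *at* 225 can have; the photon-gain model
is the smallest refinement that restores physical plausibility.

Scenes used to probe FB microstructure set `background_level = 0`: the
ratio map is computed from raw averaged channels, so any common background
b distorts the on-fiber ratio to (s + b)/(s/rho + b), which collapses a
rho = 225 fiber to ~140 even at b = 0.5 DN. Morphometric scenes keep the
default background of 2 DN.

### Heterogeneity

Between-sample biological variation is modelled as multiplicative jitter on
fiber count and mean length (`sample_jitter_frac`, default 0.10); sites
within a sample differ only by sampling noise. The within-sample
heterogeneity of real tissue is not quantified by any source this package
follows, so the jitter knob is exposed rather than fixed by fiat.

## Morphometrics (`shgfiber.morphometrics`)

The processing chain mirrors the TWOMBLI workflow: contrast saturation,
ridge detection, mask, skeleton, ten pattern metrics plus two derived ones.

* **Contrast saturation** follows the ImageJ "Enhance Contrast" convention:
  clip the top and bottom `fraction/2` quantiles, stretch linearly to
  [0, 255]. The published setting "0.35" is in ImageJ *percent* units, so
  the default fraction is 0.0035. (Treating it as a fraction of 0.35 clips
  at the 17.5%/82.5% quantiles, which on a sparse fiber image stretches
  pure background noise across the full 8-bit range and floods the ridge
  detector with false positives.)
* **Ridge detection** is Steger-style: ridge strength is the negative of
  the smaller Hessian eigenvalue at Gaussian derivative scale
  sigma = line_width/(2 sqrt 3), scale-normalised by sigma^2. Candidate
  regions come from hysteresis thresholding (`ridge_low`/`ridge_high`,
  defaults 8/20 DN on the saturated image — for a matched-width Gaussian
  ridge of amplitude A the center response is ~0.26 A, so the defaults
  correspond to contrasts of ~30/75 DN); candidates are thinned, dilated to
  the nominal line width, gap-closed up to `min_gap_diameter`, and
  re-thinned. Binary disk morphology is computed via Euclidean distance
  transforms (exact disks, much faster than footprint filters at 512x512).
* **Skeleton hygiene.** Thinning a dilated tube leaves artifacts with
  topological consequences: Y-forks and small loops at rounded end caps,
  and 3-clique "staircase" residues that read as junctions. The skeleton is
  therefore pruned (terminal spurs and fragments below
  `min_branch_length`; loops shorter than twice that), freed of redundant
  triangle corners, and its ends are peeled back by line_width/2 pixels to
  undo the end extension introduced by dilation. On 20 seeded scenes of 10
  isolated fibers this yields exact endpoint and branchpoint counts and
  total length within 10% of ground truth (typical error 4-7%).
* **Endpoints/branchpoints**: degree-1 skeleton pixels; junction pixels
  (degree >= 3) merged by 8-connected components so one thick crossing
  counts once.
* **Total length**: 1 per lateral skeleton adjacency, sqrt(2) per diagonal.
* **Lacunarity**: gliding-box Lambda(r) = E[m^2]/E[m]^2 with unit-step
  windows, averaged over dyadic box sizes 2-128 (clipped to the image);
  empty mask = 0 by convention, any non-empty mask gives Lambda >= 1. The
  exact box schedule of the reference implementation is unpublished, so
  absolute lacunarity values are implementation-relative; group contrasts
  are what the pipeline reports on.
* **Box-counting fractal dimension**: least-squares slope of log N(s) vs
  log(1/s) over dyadic s, grid anchored at the origin. Filled square -> 2,
  line -> 1, depth-7 Sierpinski raster -> log3/log2, each within 0.05.
* **Curvature**: branch-free skeleton paths are smoothed with a 5-px moving
  average (the digital staircase otherwise inflates arc length by ~6%,
  biasing the chord angles low), resampled at arc spacing `window`
  (default 40 px, the configured value is a per-image-set constant in
  [40, 120]), and the mean absolute turning angle between successive chords
  is averaged over paths weighted by length. A radius-200 arc with window
  40 gives 11.46 degrees as the inscribed-chord geometry requires.
* **HDM**: fraction of pixels at or above the display threshold (200).
* **Alignment**: coherency (l1-l2)/(l1+l2) of the summed gradient structure
  tensor with nearest-edge padding (zero padding would fabricate border
  edges that dominate the sum).
* **HGU** is total length / endpoints (the AnaMorf convention); the
  alternative reading "endpoints per unit length" is dimensionally inverted
  and incompatible with cohort values of ~42 px/endpoint at ~4700 px total
  length and ~120 endpoints.
* **Derived metrics**: average fiber length = total length / (0.5 *
  (endpoints + branchpoints)); approximate fiber thickness = HDM * field
  area / average fiber length, with field area in um^2 and length converted
  to um. Only under that unit convention do the cohort's printed values
  (~33 um) reconcile; a pixel-only mode is available via `um_units=False`.

Missing values are NaN throughout, never silent zeros. Morphometrics are
computed on the forward channel, the channel the acquisition tunes for
adequate collagen signal.

## FB ratio mapping (`shgfiber.fbratio`)

The ratio map stores `round(scale * forward/backward)` per pixel on an
8-bit axis (default scale 1 DN per unit ratio — the stored-axis scale is
the one convention the source material leaves fully open and is therefore
configurable). Censoring is explicit: stored 0 (zero forward signal, or a
ratio rounding to 0) and stored 255 (zero backward with signal, or a ratio
off the axis) are excluded from all means but counted in the
N_zeros/N_255/total-N accounting. Masking to detected fibers is a logical
restriction: retained pixels are bit-identical, excluded pixels leave every
count. Contours are re-detected on the masked map with the same ridge
operator (relaxed thresholds, since the off-fiber background is exactly
zero), dilated by line_width/2 into ROIs, and measured with the sample
(n-1) SD convention. Per-sample summaries take mean/median/SD/IQR over
per-segment means (IQR by linear order-statistic interpolation, the
"type 7" rule). The optical-bench calibration constant (1.079) is an
instrument property and is exposed only as an optional off-by-default
correction.

## Group statistics (`shgfiber.stats`)

Welch t-tests (Welch-Satterthwaite df) per metric, Mann-Whitney tests
(midrank ties; exact by full enumeration for combined n <= 12, normal
approximation with tie and continuity corrections otherwise), and
Benjamini-Hochberg adjustment within each family — the 12 morphometrics
form one family, the 8 FB-distribution features another, with flags at FDR
0.05 and 0.01. All tests are two-sided; missing data are complete-case per
metric. PCA is computed on the correlation matrix; variable-PC
correlations are loadings scaled by sqrt(eigenvalue), components are
oriented so each one's largest-magnitude correlation is positive, and
equal-variance t-tests compare per-component score means between groups.
Under a 1000-replicate two-group null with exchangeably correlated metrics
(rho = 0.5) the per-metric false-flag rate of the full Welch+BH table is
below 1% — comfortably within the documented 8% tolerance, which allows
for BH's behaviour under positive dependence.

`shgfiber.cohort_data` bundles the printed per-sample summary moments and
variable-PC correlation structure of the TNBC cohort that motivated the
default study design. Since the per-sample table itself is not deposited,
`synthetic_sample_table` builds a labelled synthetic surrogate: the
correlation matrix is reconstructed with exactly the leading eigenstructure
the printed PC correlations imply (eigenvalues = column sums of squared
correlations, 6.22/3.15/1.32, flat residual spectrum), giving PC1+PC2
cumulative variance of 78.5% by construction when the sample correlation is
matched exactly. Group-shifted draws from this surrogate reproduce the
qualitative score-test pattern: PC1 separates the cohorts (significant in
~95% of draws, p on the order of 1e-4), PC2 does not (~10%). PC3 and PC4
are not constrained: the printed group differences in HDM and fiber
thickness load on PC3, so the surrogate cannot also force those score tests
to be null.

## Pipeline (`shgfiber.pipeline`, `shgfiber.cli`)

`run_study` executes the two-phase design per site (average -> mask ->
morphometrics + FB map; contours -> segment measures), aggregates
arithmetic per-sample means over sites, summarises FB distributions per
sample, and runs the statistics phase. Processing order is a seeded random
permutation of samples and no site-level output contains a group label;
labels join only at the statistics phase (verifiable by inspecting
`site_metrics.csv`/`segments.csv`). Site failures are logged in the
manifest and excluded with an explicit count. All randomness descends from
one seed through per-site `SeedSequence` spawns, so reruns with the same
configuration are byte-identical; CSVs are written with a fixed float
format to keep that guarantee at file level. The image split into two
visually chosen parameter sets in the original workflow is replaced by an
explicit per-set curvature-window configuration entry; no visual step is
automated.

## Problem sizes used in the test suite

The suite validates the paper-scale layout — 27 samples x 20 sites = 540
sites at 512x512 — with scene content scaled down (12-16 fibers, 4 frames
per channel) so the full run stays fast on one CPU; byte-identical rerun
determinism is asserted on a reduced design, which exercises the identical
seeding path. Parameter-recovery suites use 10-12 isolated fibers per
512x512 scene with 20-frame stacks. The null-calibration run uses 1000
replicate 10-vs-17 cohorts at the metrics-table level: the quantity under
test is the error rate of the Welch+BH layer, and simulating images would
only add Monte-Carlo noise around the same null.

## Known limitations

* Absolute lacunarity, BCFD and curvature scales are implementation
  dialects (box schedules, window choices); cross-tool comparisons should
  use group contrasts, not absolute values.
* The ridge detector assumes one dominant line width; strongly mixed-width
  networks would need a multi-scale extension.
* The generator renders 2-D scenes with Gaussian profiles and intensity
  noise only; polarization effects, 3-D sectioning, and H&E background
  structure are out of scope, so passing recovery tests demonstrate
  correctness of the measurement chain, not realism of tissue texture.
* Overlapping fibers merge in the mask; ground-truth topology is only
  recoverable for scenes whose fibers are separated by at least the line
  width, which is how the recovery suites are constructed.
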