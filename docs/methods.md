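# Methods

`nbprox` quantifies the spatial association between gene loci and
nuclear bodies in 3D immuno-FISH images, and bundles the quantitative
companions such an imaging study typically carries: protein half-life
estimation from cycloheximide-chase densitometry, qPCR relative
quantification, dual-reporter normalization, grouped rank correlation
of expression tables, and promoter/peak interval arithmetic.  Because
raw microscopy of this kind is rarely deposited at reusable scale, the
package ships a synthetic-scene generator with exact ground truth;
every imaging claim the test suite makes is a recovery or calibration
statement against that truth.

## The proximity model

A field of view is a 3-channel volume (DNA counterstain, FISH foci,
nuclear-body immunostain) on an anisotropic voxel grid.  All distances
are Euclidean in physical micrometres; voxel `i` is centred at
`(i + 0.5) * voxel_size` per axis, axis order `(z, y, x)`.

For each detected focus the statistic is the distance to the nearest
body **of the same nucleus**; the unit of analysis is the nucleus (the
arithmetic mean over its foci), matching the per-cell design used in
this assay family.  Per-nucleus means are compared between probes by a
two-sided Welch t test by default (Mann-Whitney optional); no
multiple-testing correction is applied.  Mean distances are classified
against the distance regimes established for locus/body association:
<= 1.6 um associated, >= 2.0 um unassociated, the gap indeterminate
(both thresholds configurable).  A complete-spatial-randomness (CSR)
Monte-Carlo null re-places the observed foci counts uniformly over each
nucleus's segmented voxels (jittered within the voxel) and reports the
add-one empirical p-value `p = (1 + #{null <= obs}) / (1 + n_reps)`,
which is never exactly zero and is exactly uniform under the null.

Distance is centroid-to-centroid.  Measuring to the body *surface*
would give systematically smaller values; centroids are the
reproducible choice given only point detections.

## The scene simulator

Nuclei are random ellipsoids flattened along z (defaults: semi-axes
2.2-2.6 um axial, 6.0-7.5 um lateral), emulating adherent
osteosarcoma-like cells imaged with a 63x widefield objective at voxel
size (0.25, 0.10, 0.10) um.  Bodies and foci are points; foci are
placed either

* **CSR** — uniform over the nucleus ellipsoid.  With the default 10
  bodies per nucleus the expected focus-to-nearest-body distance is
  ~2 um, reproducing the regime in which unassociated loci are found; or
* **tethered** — displaced from a uniformly chosen body by a
  truncated-normal distance (default mean 1.4 um, sd 0.3 um, support
  >= 0) in a uniform random direction, rejection-sampled to stay inside
  the nucleus.  Only mean distances are reported in the literature this
  emulates, so the sd is a free parameter; 0.3 um keeps the four
  programmed conditions (1.1/1.4/1.7/2.0 um) clearly ordered at 50
  nuclei per condition.

Rendering: filled ellipsoids in the DNA channel; each point object is
an anisotropic Gaussian (PSF sigma default (0.35, 0.13, 0.13) um)
integrating to `photon_scale` counts; Poisson noise on signal +
background, additive Gaussian read noise, clipped at zero.  Objects are
kept half a voxel diagonal inside their ellipsoid so every object falls
inside the rasterized nuclear mask.  Rejection sampling is capped at
10,000 attempts per object; infeasible configurations raise a
`PlacementError` naming the crowded parameter rather than degrading
silently.

Identical `(config, seed)` is bit-identical, for the stack and the
ground truth.

What the simulator does **not** model: spherical aberration,
chromatic shift, channel bleed-through, intensity variation between
bodies, chromatin texture in the DNA channel, touching nuclei, or
z-dependent PSF broadening.  Passing recovery tests therefore show
that the measurement chain is correct and unbiased under the stated
optics, not that segmentation is robust to every real-world artifact.

## Segmentation and detection

Nuclei: threshold on the DNA channel (Otsu by default — appropriate
there because nuclear foreground occupies a large fraction of the
field), per-slice hole filling, 26-connected labeling, minimum-volume
and optional border filters, labels renumbered by descending volume.
An all-constant channel yields zero nuclei with a warning.

Spots: thresholded **within the union of nuclear masks**, 26-connected
components (8-connected for single-plane stacks), size-filtered, then
reduced to intensity-weighted centroids.  The default spot threshold is
*not* Otsu: spot voxels are of order 0.1% of the nuclear volume, and
under that class imbalance Otsu's between-class criterion collapses
onto the background mode (we measured thresholds inside the background
noise and catastrophic over-detection).  The default is a robust
background rule, `median + 8 * 1.4826 * MAD` of in-mask intensities,
floored at 10% of the brightest in-mask voxel so that noise-free data
(MAD = 0) still yields compact blobs.  Otsu, absolute and quantile
thresholds remain available.  All relative rules are invariant to
global intensity rescaling.

A focus whose centroid voxel lands on background (possible for
non-convex masks) is assigned to the majority-overlap nucleus and
logged.

Two Gaussian spots closer than ~5 sigma bridge above any relative
threshold and fuse into a single connected component — an optics
limit, not a detector defect.  The simulator therefore enforces a
minimum same-channel separation (generator default 0.6 um; the
detection-fidelity and recovery studies use 1.8 um ~ 5 sigma_z) so
that "detected counts equal ground truth" is a meaningful claim about
resolvable objects.

## Simulation studies and their problem sizes

* **Detection fidelity** — 20 noise-free single-nucleus scenes; counts
  must match truth exactly and the mean Hungarian-matched centroid
  error stays below half a voxel diagonal (0.14 um; measured ~0.04 um).
* **Tether recovery** — 4 programmed means x 50 single-nucleus noisy
  fields through the full pipeline (segment, detect, summarize), one
  body per nucleus so the programmed tether distance *is* the
  nearest-body distance (with many bodies the nearest distance is the
  minimum of the tether and the CSR field, which no estimator could
  map back to the programmed mean).  Recovered grand means track the
  ground-truth means to ~0.02 um and preserve the programmed ordering.
* **Probe power** — 20 replicates of tethered (1.4 um) vs CSR groups,
  50 nuclei each, on ground-truth geometry (the estimand itself);
  Welch p < 0.01 in 100% of replicates at these conditions.
* **Null calibration** — 200 datasets generated under CSR, 999 null
  replicates each; the rejection rate at alpha = 0.05 stays within
  Monte-Carlo error of 5%.  Observed foci are drawn by the same
  voxel-jitter sampler the null uses, which makes the p-value exactly
  uniform by exchangeability.  One sequential RNG stream drives truth,
  observed and null draws per run; per-dataset derived seed triplets
  were found to give overdispersed rejection counts across runs and
  were abandoned.
* **Half-life recovery** — two conditions (true 10 vs 16 min), three
  replicate series each over 0-40 min, 10% lognormal densitometry
  noise; per-replicate log-linear fits, medians, and a
  replicate-bootstrap comparison.

These sizes were chosen as the smallest designs at which the claims
are statistically meaningful (50 nuclei per condition mirrors the
standard "at least 50 nuclei per probe" design of this assay family).

## Decay fitting

A chase series is target/loading densitometry, anchored to 1 at t = 0.
Under first-order decay the log-abundance is linear through the
origin, so `k = -sum(t ln A) / sum(t^2)` (clipped at 0), with the CI
from the through-origin slope's standard error (df = n - 1) and
`t_1/2 = ln 2 / k` (infinite when k ~ 0).  The closed form makes the
noise-free oracle exact to machine precision; a nonlinear fit would
add no information at the 4-6 time points these experiments have.
Replicates are aggregated by median; two conditions are compared by
bootstrap over replicates (add-one two-sided p).

## Tabular statistics

* **Spearman** — Pearson correlation of mid-ranks (tie-aware).  p is
  exact (full enumeration of orderings) for 3 <= n < 10 and the
  classical t approximation for n >= 10; n = 2 with distinct values
  reports rho = +/-1 with an undefined p; constant input is undefined.
  Grouped correlation adds a pooled "All" row and keeps degenerate
  groups visible with NaN flags rather than dropping them.
* **qPCR** — efficiency-corrected ddCq with the normalizer as the
  geometric mean over reference genes; efficiency defaults to 2.0
  (perfect doubling) and may be per-gene.  Folds are invariant to any
  global Cq offset; the calibrator condition is 1 by construction.
  Replicate dispersion is the sd of per-replicate folds against the
  calibrator mean.
* **Dual reporter** — firefly/Renilla per measurement, construct means
  relative to the promoterless control; invariant to common
  transfection-efficiency factors.
* **Intervals** — closed, TSS-relative (TSS = 0), so printed
  coordinates like "-193 to +122" are used verbatim; conversion to
  0-based half-open BED is an explicit transform.

## Numerical conventions

* Nearest-body ties break to the lowest body id; label maps renumber
  by descending volume; quartiles use linear interpolation and
  whiskers the Tukey 1.5 IQR convention (stated because "box and
  whisker" is otherwise ambiguous).
* All randomness flows from a single top-level seed expanded per stage
  via `SeedSequence`; no global RNG state is touched.
* Empirical and bootstrap p-values use the add-one convention and are
  never exactly zero.

## Known limitations

* 2D (single-plane) support reuses the 3D path with 8-connectivity and
  areas; it is exercised less heavily than the 3D path.
* Touching nuclei are not split (no watershed); the simulator never
  generates them.
* The CSR null conditions on the *detected* body positions; it tests
  focus placement, not joint focus/body clustering.
* Per-focus vs per-nucleus aggregation is a genuine design fork for
  RNA-FISH-style data; both are available (the distance-record table
  is per focus), with per-nucleus the default unit for testing.
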