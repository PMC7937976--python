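# Methods

`phenospectra` implements a proximal hyperspectral phenotyping pipeline for
single plants imaged top-down by two pushbroom line scanners (VNIR,
400–1000 nm; SWIR, 970–2500 nm), together with a synthetic scene simulator
that provides ground truth for every stage. This note records the models,
the parameters that matter, and the design decisions taken where the design
was genuinely open.

## Reflectance calibration

Raw digital numbers are converted to relative reflectance per sample column
and band:

    rho = (raw − dark) / (white − dark)

The references are applied per sample column (not as scalars) because a
pushbroom geometry has genuine cross-track non-uniformity in both sensor
response and illumination. Reference pixels whose dynamic range
`white − dark` falls at or below ε = 1e-6 of the global dynamic range are
flagged invalid and propagate as NaN rather than infinities. Reflectance is
stored as a fraction in [0, 1]; the percent scale appears only in reports
(diurnal slopes are conventionally quoted in percent reflectance per hour).

ENVI I/O is a minimal in-package reader/writer for the flat-binary +
text-header format (BIL/BSQ/BIP interleaves, little-endian data types 1, 2,
3, 4, 5, 12). Write∘read is the identity on values and wavelengths.

## Synthetic scenes

The simulator is first-class code, not a fixture: its outputs define the
conditions under which every pipeline property is asserted.

**Leaf spectrum.** A parametric template rather than a physical leaf-optics
model — exact ground-truth control matters more here than radiometric
realism. Components: a low visible base (0.10) with a Gaussian green peak at
551 nm (default height 0.10) and a red trough at 670 nm (depth 0.06); a
logistic red edge centred at 715 nm (width 12 nm) rising to a NIR plateau
(0.45); a linear relaxation from the plateau to a SWIR level (0.62 × plateau)
over 1300–1700 nm; a dry-matter shoulder (+0.03) climbing from 1650 nm and
flat past 1825 nm; and Gaussian water-absorption valleys at 979, 1232, 1445
and 1955 nm (default depths 0.05, 0.06, 0.16, 0.14; widths 30, 40, 60,
55 nm). The shoulder's slope exceeds the inward tail of the 1955 nm valley,
which pins the local ridge between the 1445 and 1955 nm valleys at 1825 nm;
because the baseline is flat past 1825 nm, setting all valley depths to zero
makes the 1955 nm floor exactly equal the 1825 nm shoulder — a testable
identity.

**Drought response** (`drought_level` in [0, 1]) adds signed Gaussian bumps:
reflectance rises at 523, 658, 1482 and 2110 nm and falls at 551, around the
red edge (708/721 nm) and at 976 nm, strictly monotonically in the drought
level. The red–green ratio index (RGRI) computed on generated spectra is
therefore strictly increasing in drought.

**Diurnal response** (`hour_of_day`) is linear around solar noon with
per-wavelength slopes: positive in the visible (+0.0857, +0.0303,
+0.0828 %/h at 523/551/658 nm for well-watered plants), negative at the red
edge, NIR and SWIR bands, and steeper under water deficit at 721, 976 and
1694 nm. Slopes interpolate linearly between the well-watered and
water-deficit profiles with the drought level, so a noiseless series is
exactly linear in the hour and ordinary least squares recovers the
configured slope to machine precision.

**Scene rendering.** Default geometry is 511 lines × 328 (VNIR) / 320 (SWIR)
samples with 194 / 256 bands. The plant is a rosette of elongated elliptical
leaves; the background is flat 3 % reflectance so red-edge segmentation
separates cleanly. Illumination has three ground-truth components:

* a linear multiplicative gain field (smooth random surface in [0.65, 1.35]
  by default, optionally times a per-scene level ~N(1, `gain_scene_sd`)) —
  the distance/inclination effect;
* non-linear shading: ~8 % of plant pixels attenuated by a factor drawn from
  U(0.2, 0.5), applied after the gain;
* specular glint: ~0.5 % of plant pixels saturate at 0.98 of the white
  signal, independent of the leaf spectrum.

Raw signal: `dark + (white − dark) · gain · reflectance`. The SWIR view is
the same scene pulled back through the ground-truth affine registration
(sample scale 320/328, identity in lines, configurable shift). With unit
gain and no shading/glint, calibration inverts rendering exactly.

**Per-plant spectra tables** emulate plant-mean spectra over a drought time
course: pigment/structure parameters vary between plants (green peak sd
0.01, NIR plateau sd 0.02), the water-valley depths vary between
observations (15 % multiplicative jitter — leaf water status changes across
days and within a day, which makes the SWIR valleys informative beyond the
visible bands), and additive per-band noise of 0.002 represents the residual
uncertainty of a mean over ~10⁴ pixels. Water-deficit plants ramp their
drought level linearly over the experiment days.

**Trait links.** A trait is `slope · index(spectrum) + intercept +
N(0, σ)`, with `noise_sd_for_r2` solving σ for a requested population R².
What the generator does *not* emulate: multi-plant scenes, leaf overlap with
the pot or neighbouring plants, sensor striping and smile, temperature drift
of the SWIR detector, and any non-linear trait–reflectance link. Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical structure, not field readiness.

## Segmentation and co-registration

VNIR plant pixels: red-edge NDVI `(ρ750 − ρ705)/(ρ750 + ρ705)` on the
nearest grid bands, strictly above 0.35 (the 705/750 nm placement is the
Gitelson-style choice; pixels exactly at the threshold are excluded; NaN
pixels are background). SWIR: a 100-tree random forest on all SWIR bands,
trained on labelled cubes with per-class subsampling (5000 pixels/class) and
a held-out confusion-matrix accuracy report.

Registration is a least-squares affine fit `s′ = a·s + b·l + c`,
`l′ = d·s + e·l + f` to ≥3 non-collinear control-point pairs (chessboard
corners in a physical rig). Masks are warped by pull-back nearest-neighbour
sampling; coordinates are 0-based (sample, line) with pixel centres at
integers, and exact half-pixel ties round toward the lower index so boolean
labels stay boolean.

## Light classification

Brightness is the HSV value — the maximum of the blue (492 nm), green
(539 nm) and red (651 nm) reflectances — which for vegetation is the green
band almost everywhere. Thresholds are derived once from pooled training
brightness by nested 1-D k-means: k = 3 (low / intermediate / high), then
the low and high clusters re-split k = 2 into ex-low/low and high/ex-high.
Class boundaries are the midpoints between adjacent sorted centroids (the
1-D Voronoi edges); Lloyd's algorithm runs with 50 seeded restarts and is
checked in tests against an exhaustive dynamic-programming 1-D clustering.
The specular cut is the 99.5th percentile of the ex-high training
brightness — glint saturates far above leaf brightness, so anything beyond
the uppermost threshold is discarded as specular. Five classes need four
interior boundaries; the implementation stores exactly those plus the
specular cut.

Per plant and class, mean spectra are emitted for all classes (specular
flagged non-analysis); the pixel-count-weighted mean of the class means
equals the whole-plant mean by construction. The intermediate class is the
default analysis class. The `variance_reduction` diagnostic reports
`1 − (pixel-weighted mean within-class variance)/(whole-plant variance)`,
averaged over bands.

## Index catalog and discovery

Indices are expression trees over band references — a single wavelength
(nearest band) or an [lo, hi] range (unweighted band mean). The catalog
holds 10 published and 10 novel definitions with their printed band
placements; division by zero yields a missing value (the inverse normalized
ratio IND_715/655 genuinely does this when ρ715 ≈ ρ655).

Discovery restricts to 480–2470 nm (sensor-edge bands are noisy) and
supports two correlation kinds: ordinary Pearson and the repeated-measures
correlation (Pearson on subject-mean-centred data — the common
within-subject correlation, equal to the ANCOVA formulation and verified
against `pingouin.rm_corr`). Mixed VNIR+SWIR spectra are concatenated on one
grid, with the 970–1000 nm overlap taken from the finer VNIR sensor.

* **Exhaustive pair search** scores ρi/ρj over ordered pairs and
  (ρi−ρj)/(ρi+ρj) over unordered pairs and returns the largest |r|; exact
  ties resolve to the earliest candidate in (i, j)-lexicographic order,
  ratios before normalized differences. Verified against a brute-force
  double loop.
* **Greedy builder** starts at the best single band and at each step tries
  combining the current expression E with every unused band w through
  {E+w, E−w, w−E, E·w, E/w, w/E}, keeping the best; it stops when the |r|
  gain drops below tol = 0.01 (a stabilization tolerance; the stopping rule
  is the open design point) or four distinct wavelengths are in use. The
  trace of per-step best |r| is returned and is non-decreasing, so the final
  index never correlates worse than the best single band. Constants are not
  introduced by the search; they appear only in fixed catalog formulas
  (the factor 2 in ARGI, 0.2 in MCARI).

## Chemometrics

The 80/20 train/test split is stratified by treatment with an exact global
train size `floor(0.8·n)` allocated by largest remainder (178 → 142/36,
111 → 88/23) and a fixed seed; the split method was an open point and
stratified-random was chosen.

PLSR uses the classical orthogonal-scores (NIPALS) algorithm on
mean-centred, unscaled data; for a single response the inner loop collapses
to one pass per component. Coefficients are accumulated as
`B_k = W (PᵀW)⁻¹ q` for every component count k in one fit, which makes
exhaustive leave-one-out cross-validation affordable: n refits, each
yielding predictions for all candidate counts. The retained count minimizes
the LOOCV RMSE (PRESS), ties to the smallest. At full rank PLSR reproduces
ordinary least squares; both identities are tested, and predictions are
cross-checked against scikit-learn's `PLSRegression` (used only as a test
oracle).

VIP for band j over A retained components:

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),  SS_a = q_a² t_aᵀt_a

so the squared scores average to exactly 1. Feature selection is
single-threshold backward elimination: fit a PRESS-selected model, drop all
bands with VIP < 1, refit; stop when the LOOCV RMSE stops improving or
nothing is dropped, and return the best-RMSE round. (The cited family of
VIP-selection procedures has many members; this one is fixed here.)

Evaluation reports RMSE and R² as the squared Pearson correlation of
observed vs predicted (the `caret::postResample` convention); constant
predictions report R² = 0.

## Band statistics

* **Collinearity grouping**: greedy left-to-right along the wavelength axis —
  a band joins the current group while its correlation with the group's seed
  band is ≥ 0.80, else it opens a new group; the seed is the representative.
  Contiguity is justified by the strong correlation of adjacent wavelengths.
  Constant bands form flagged singleton groups.
* **Treatment tests**: WW-vs-WD contrast per band within each day×hour cell
  (two-sample t, the per-cell slice of the factorial fixed-effects model),
  Benjamini–Hochberg corrected across the whole report. Longitudinal
  designs like this one are often analysed with mixed-effects models; this
  package deliberately uses fixed-effects contrasts with explicit BH
  correction instead, trading some efficiency for a fully specified and
  reproducible procedure. Type-I error under the simulator's null is
  asserted with Monte-Carlo tolerance.
* **Diurnal slopes**: OLS of percent reflectance on decimal hour per
  treatment; the WW–WD slope difference is the interaction term of
  `value ~ hour × treatment`. Constant series report slope 0 and p = 1 by
  convention (the t-statistic is 0/0 otherwise).
* **Trough depth**: ρ(ridge) − ρ(valley) at the nearest bands, default
  1825/1955 nm.
* **Trait–reflectance correlations**: per treatment, Pearson or
  repeated-measures correlation per trait×band, BH-adjusted; the rmcorr p
  uses the within-subject degrees of freedom n − k − 1.

## Evaluation studies and problem sizes

Two end-to-end studies validate the pipeline against simulator truth; their
problem sizes are the package's own choices for desk-scale runs.

* **Masked drought detection**: the water-deficit arm uses drought level
  0.25 and plants differ in overall illumination level (per-scene gain
  ~N(1, 0.15²)) — the regime where the 658 nm drought shift and the
  illumination spread of whole-plant means are comparable, i.e. the regime
  light classification exists for. Scenes are 64×48 pixels with a 9-band
  VNIR grid containing the bands the pipeline needs; 8 plants per arm,
  200 replicates, fixed thresholds trained once on a pooled multi-drought
  training set. Intermediate-class means detect the effect with higher
  power than whole-plant means because class conditioning on an absolute
  brightness window removes most of the between-plant gain variance.
* **Trait recovery**: 150 plant-mean spectra on the merged 450-band grid, a
  trait generated from WPI2 at population R² 0.92 (slope −8, trait-scale
  units), both discovery methods run, and both model families fitted on a
  stratified 80/20 split with PLSR components PRESS-selected from at most 12.

The PRESS rank-recovery check uses n = 150 observations (the scale of the
emulated trait datasets); at small n the flat tail of the LOOCV curve lets
plain argmin over-select a component ~10 % of the time — an intrinsic
property of argmin-PRESS, reproduced identically by the scikit-learn
cross-check.

## Numerical conventions and degenerate inputs

Nearest-band lookup rejects requests farther than half the local band
spacing outside the grid. Mask warping rounds half-pixels toward the lower
index. Calibration, index evaluation and the searches turn division by zero
into missing values; searches skip candidates with any missing value.
Already-calibrated cubes, all-invalid references, single-class training
data, constant traits/indices/brightness, collinear control points,
sub-minimal sample sizes and empty hour grids all raise `ValueError` with a
specific message rather than propagating nonsense.

## Known limitations

The simulator's leaf template is phenomenological; absolute reflectance
levels and valley shapes are plausible but not radiative-transfer accurate.
Illumination classes are asserted against a scalar gain ground truth, not a
bidirectional reflectance model. The greedy builder's stopping tolerance
(0.01 in |r|) trades index compactness against fit and can stop before a
reachable exact expression. Mixed-model inference is deliberately out of
scope (replaced by fixed-effects models with BH correction), as are SNV/3-D
illumination corrections, thermal/RGB pipelines and multi-plant scenes.
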