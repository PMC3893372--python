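# Methods

This note records the models implemented in `fcdmap`, the numerical
choices behind them, the design of the synthetic phantoms used for all
validation, and the known limitations. Every quantitative statement here
is one the test suite or `scripts/acceptance.py` computes.

## Laplacian thickness mapping

**Model.** The cortical ribbon — the region between the traced pial
(outer) and grey/white (inner) boundaries of one 2D section — is the
domain of ∇²φ = 0 with Dirichlet data φ = +1 on the inner and φ = −1 on
the outer boundary (dimensionless potentials). Field lines follow ∇φ
from one boundary to the other; the thickness *t* at a point is the
length of the field line through it. Because field lines of a harmonic
potential never cross, *t* is single-valued throughout the ribbon. *t*
and the signed curvature κ are sampled on the φ = 0 midline.

**Discretization.** Contours are rasterized at the pixel grid (spacing
configurable; 1 px default). Cells between the contours are grey
matter; the contour polylines are burned in as boundary cells. The
Laplacian is the five-point stencil, with one refinement: a stencil arm
that leaves the grey set applies its Dirichlet value at the *sub-pixel
distance where the arm crosses the traced contour* (Shortley–Weller
unequal arms, arm length clipped to ≥ 0.1 cell). Without this, the ±1
values sit at rasterized pixel centers that jitter ±0.5 px about the
true contour, and the per-sample thickness error on the analytic
annulus phantom reaches ±2.6%; with it, the worst sample is within
0.4%. Arms that exit the domain without crossing a contour (the open
ends of a band-shaped ribbon) get a zero-flux mirror condition. The
sparse interior system is solved directly (UMFPACK via
`scipy.sparse.linalg.spsolve`); the residual check is 10⁻⁶ by default.
For interpolation and tracing, boundary-cell values are shifted from
the contour to the cell center using the local gradient magnitude and
the signed center-to-contour distance, and the field is extended a few
cells outward by linear extrapolation so finite differences at the
boundary ring see the true slope.

**Field-line integration.** Fourth-order Runge–Kutta on the bilinearly
interpolated, normalized gradient, step 0.25 px, launched from each
midline sample toward both boundaries. Integration stops when the
trace reaches |φ| ≥ 1 − ε (ε = 0.02) or leaves the grey set; the
remaining distance to the ±1 level is added as (1 − |φ|)/|∇φ|. A trace
that exits while still far from the boundary in potential (> 0.3) is
discarded as degenerate (this happens only in pathological geometry).
Thickness is computed only from midline samples, not from every grey
pixel.

**Midline and curvature.** The φ = 0 contour is extracted by marching
squares with linear interpolation and resampled at a fixed arc step
(200 μm default at slide scale). Curvature uses a Kasa least-squares
circle fit over a sliding arc window (2 mm default); the sign is
positive where the midline is convex toward the pial side (gyral
crest), determined by which side of the fitted center the local −∇φ
direction points. Collinear windows return κ = 0 exactly. On a circular
midline of radius 1 mm the estimate is within 5% of 1/mm; on the
annulus phantom within 0.3%.

**Verified accuracy** (all recomputed by the acceptance script): on the
40/70 px annulus at 10 μm/px, every midline thickness sample is within
0.4% of the true 300 μm; the midline radius is within 0.05% of the
geometric mean √(40·70); φ fits a + b·ln r with max deviation ~0.012;
on a parallel band φ is linear to machine precision. Halving the grid
spacing changes mean annulus thickness by < 1%.

## Stereotaxic positioning and matching

Slides are ordered anterior→posterior with three landmark indices:
frontal pole (y = +73 mm), anterior commissure (y = 0), occipital pole
(y = −106 mm). Intermediate slides interpolate *by index* within each
landmark segment — the anchors are the only calibrated information, so
index-linear interpolation adds no assumptions; the nominal 1.2 mm
physical spacing is used only as a consistency check (warn at > 25%
deviation). Case slides match the nearest-y control slide; pairs
farther than 1.2 mm (one slide spacing) are dropped; distance ties go
to the more anterior control so matching is deterministic.

## Dysplasia detection

**Fences.** For each matched pair, the control slide's midline
thickness sample yields quartiles (linear-interpolation, "type 7"
quantiles — stated because fence values depend on it), the medcouple
MC, and the skew-adjusted fences

    MC ≥ 0: [q1 − 1.5 e^(−4 MC) IQR, q3 + 1.5 e^(+3 MC) IQR]
    MC < 0: [q1 − 1.5 e^(−3 MC) IQR, q3 + 1.5 e^(+4 MC) IQR]

which reduce to Tukey's fences at MC = 0 (a `tukey` variant is
available for sensitivity analysis). The medcouple is computed by the
O(n²) kernel definition with the standard −1/0/+1 rule for pairs tied
at the median; it agrees with an exhaustive brute-force oracle to
machine precision and with `statsmodels`' implementation on random
samples including heavy ties. Slide-scale samples are ~10²–10³ values,
so the quadratic cost is irrelevant.

**Flagging.** Maximal contiguous midline runs with t below the lower
fence are flagged; runs shorter than 1 mm of arc (configurable) are
discarded as sampling noise; wrap-around runs on closed midlines are
merged. Flagging is invariant to the direction in which the midline was
sampled. No hypothesis test or multiplicity correction is layered on
top: the fence threshold *is* the detection rule.

**Calibration.** The fence sample must contain enough independent
thickness fluctuations for quantile/medcouple estimation — tens of
independent excursions, which real hemispheric sections provide
naturally and the phantoms provide via 2–6 mm modulation periods over a
24 mm midline. Even then, a control profile occasionally realizes a
skewed distribution with a localized dip whose own fence flags its
thinnest few percent of arc; this is the adjusted boxplot behaving as
designed (such dips are exactly what "statistical outlier" means
here), not an implementation false alarm. Measured over 50 seeded null
cohorts (case = control thickness + 1% i.i.d. sample noise): mean
flagged arc fraction 0.2%, with 98% of slides under 5%.

**Recovery.** Implanted foci (multiplier 0.7, 6 mm long, cosine taper
0.4 mm inside the interval) are detected in 100% of 50 seeded phantom
pairs with mean interval Jaccard 0.97 (minimum 0.83) against the
implanted interval.

**Cohort summaries.** Per-slide mean thickness against stereotaxic y,
and a binned (y × κ) map of mean thickness difference (case − control),
computed as the difference of per-group bin means with bins holding
fewer than a minimum sample count masked. Bin edges are configurable
(the defaults use 12 y-bins and sulcus/flat/crest κ-bins at ±0.1/mm).

## Neuron segmentation

Three stages, on dark-objects-on-light-background material (a config
flag inverts polarity):

1. **GGMRF relaxation.** Minimizes
   Σᵢ (xᵢ−yᵢ)²/2σ² + β Σ₍ᵢⱼ₎ wᵢⱼ|xᵢ−xⱼ|^p over the 8-neighborhood
   (diagonal weights 1/√2) by checkerboard coordinate descent with
   per-pixel Newton updates — the objective is strictly convex for
   p > 1. Defaults: p = 1.5, β = 1.0, σ estimated robustly as
   1.4826·MAD(Laplacian)/√20, 30 sweeps max (warn, never fail, on
   non-convergence). Output clamped to the input range. p near 1
   preserves soma edges: on a noisy step fixture the post-relaxation
   edge gradient at p = 1.1 exceeds the p = 2 result by an order of
   magnitude.
2. **Marker-based watershed.** Markers are regional minima of the
   Gaussian-smoothed (σ = 1 px) relaxed image surviving an h-minima
   depth filter (h = 10 on an 8-bit-like scale) *and* lying at least 2h
   below the background median — the contrast floor is what keeps blank
   noisy images marker-free. The background marker covers pixels near
   or above the median. Watershed regions are relabelled as 4-connected
   components.
3. **Intermeans refinement.** Each object is re-thresholded in its
   5-px-dilated bounding window at the intermeans fixed point
   t ← (mean below + mean above)/2 — the threshold at which the
   object/background mean separation is locally maximal. (The raw
   "maximize |mean_fg − mean_bg|" scan is degenerate: cutting off only
   the darkest pixel always wins, so the fixed point is the meaningful
   maximizer.) Refinement runs against the *un-relaxed* intensities:
   relaxation stabilizes markers but blurs soma boundaries, and the
   threshold should see the raw local contrast. The refined object is
   the thresholded component overlapping the initial one; an emptied
   object keeps its initial mask with a warning. Refinement is
   idempotent to ≤ 1% of pixels.

Objects below 10 μm² (far below any soma at 0.74 μm/px) are removed and
labels renumbered. The full pipeline is deterministic: identical input
and config give bit-identical label masks. On 50 disjoint disks
(radius 6 px, contrast 120, noise σ = 10) the pipeline recovers
50 ± 0 objects with mean Dice ≈ 1.0 over 10 seeds.

## Boolean germ-grain estimation

For an isotropic Boolean model with convex grains the three observable
densities determine the three parameters:

    A_A  = 1 − e^(−λ Ā)
    L_A  = λ Ū (1 − A_A)
    χ_A  = (1 − A_A)(λ − λ² Ū²/4π)

Substituting Ū from the second equation into the third gives the closed
form λ = [χ_A + L_A²/(4π(1−A_A))]/(1−A_A), then Ā = −ln(1−A_A)/λ and Ū
from L_A. A non-positive λ (pathological χ_A) raises an error carrying
the sparse-limit diagnostic λ ≈ χ_A/(1−A_A) rather than silently
clipping. The estimator identity ("densities") is recorded on the
result object.

**Density measurement — the choices that matter.** All three densities
are measured on a margin-eroded (minus-sampled) window, default margin
= the largest grain radius. Two conventions were fixed after testing
against exact-geometry oracles (shapely unions of true circles):

* *Boundary length* uses the 4-direction Crofton intercept formula,
  which is within ~0.1% on a digital disk; marching-squares contour
  length overestimates the same disk's perimeter by ~5.6%, an error
  that enters the λ formula squared.
* *Euler characteristic* uses 4-connected foreground / 8-connected
  background. The opposite convention manufactures phantom holes
  wherever two grain boundaries pass within a pixel of each other (one
  test realization: 235 raster holes where the true union has 53) and
  biases χ_A by ~−45% at the default simulation density.

Even so, a binary raster cannot represent sub-pixel gaps between
near-tangent grains, which depresses χ at native resolution. The
phantom generator therefore renders its truth mask at 4× sub-pixel
resolution for estimation experiments (`render_mask(supersample=4)`);
this is a property of how the synthetic mask is produced, not of the
estimator, which takes any binary mask. With these choices, λ, Ā and Ū
are each recovered within ~2% (mean over 10 seeds) at λ = 0.005/px²,
radius-6 disks, 1000² window — the regime where the foreground covers
43% of the window and grains overlap heavily. Estimates are invariant
under 90° rotation, and the error shrinks as the window grows.

## Granulometry

The pattern spectrum opens the mask with growing digital disks
(radius step 0.74 μm ≈ one high-res pixel by default, up to 30 μm) and
records the area removed per size bin, plus a final bin for area
surviving the largest opening — so the spectrum sums *exactly* to the
foreground area for any mask. Rasterized Euclidean disks are not an
exactly nested opening family (a digital radius-5 disk sheds its 8
corner pixels under opening by radius 2–4 disks), so successive
openings are intersected with their predecessors; this restores the
sieving axiom and non-negative spectra at the cost of a few boundary
pixels. Consequence: on ideal disk fixtures ~90% (not 100%) of the mass
lands in the bin containing the true radius, with the leakage in the
smallest bins; mode placement is unaffected, and the mode moves down
one bin between radius-6 and radius-5 grain fields. Per-lamina analysis
restricts the mask to each lamina band (bands are explicit inputs;
φ-depth quantile bands are offered only as a clearly labelled
surrogate) and averages spectra bin-wise across regions.

## Inter-rater agreement

Gwet's AC1 = (Pa − Pe)/(1 − Pe) with Pe = (1/(K−1)) Σ q_k(1 − q_k),
q_k the mean of the two raters' marginal proportions. Items are pixels
in a common window, categories {grey, not-grey}; this unit-of-agreement
choice is recorded in output metadata. With more than two raters all
pairwise coefficients and their mean are reported, labelled as such;
weighted variants and variance estimation are out of scope. AC1 is 1
under perfect agreement, invariant to rater swaps and label renaming,
robust to prevalence imbalance, and decays monotonically as simulated
rater disagreement grows.

## Synthetic phantoms: what they emulate, and what not

* **Ribbon phantoms** (annulus; offset-band "gyral" ribbons with
  sinusoidal spines) prescribe thickness exactly: contours are the
  spine offset by half the profile along its normals, with implanted
  foci scaling the profile on an interval (0.4 mm cosine taper). The
  detection study conditions: 25 μm/px, 24 mm spine, 1.5 mm baseline
  thickness modulated ±5% on 2–6 mm scales, foci 0.7× over 6 mm. The
  annulus gives closed-form potentials; the band gives exact linear
  ones.
* **Cell-field phantoms** are Boolean models with disk grains stamped
  dark (60) on light (200) with additive Gaussian noise — geometric
  primitives, not Nissl texture: no laminar gradients, no vessels, no
  staining variation, no non-convex somata. Passing recovery tests
  shows the estimators are correct for the model class, not that real
  tissue satisfies the model.
* **Rater masks** flip each pixel independently with probability p —
  spatially uncorrelated disagreement, unlike real tracing error which
  concentrates along boundaries.
* All generators draw from a single seeded `numpy` Generator per call;
  a seed is a required argument in the library API (CLI defaults to 0).
  Phantoms are written in the same contour-CSV/TIFF formats the
  pipeline reads, so file I/O is exercised by the same tests.

Problem sizes throughout (24 mm phantom slides, 1000² px Boolean
windows, 512² px cell images, 50/10-seed studies) were chosen as the
smallest at which the estimators' asymptotic behavior is visible;
statistics on them complete in minutes on one core.

## Known limitations

* Strictly 2D, per-section thickness; no 3D reconstruction across
  slides, and no image-based registration (positioning is
  landmark-only, matching the tracing-based workflow).
* No automatic grey/white segmentation: contours are inputs.
* The fence rule flags statistical outliers of a control slide's
  thickness distribution; on strongly skewed control samples it can
  flag a few percent of genuinely-thin-but-normal arc (see
  Calibration above). Interpreting flagged regions remains a
  neuroanatomical judgement.
* The Boolean inversion assumes isotropic convex grains and stationary
  germs; clustered or oriented neurons violate it and bias λ upward /
  Ā downward in ways the phantoms do not probe.
* Euler-characteristic measurement needs gaps resolved at the raster
  scale; masks from segmentation at native resolution carry the
  corresponding small-gap bias.
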