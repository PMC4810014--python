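# Methods

`sporedetect` detects primary conidia of the aphid-pathogenic fungus
*Pandora neoaphidis* in RGB photographs of spore-trap microscope slides.
This note describes the models and procedures the package implements, the
parameters that matter, what the synthetic scene generator does and does not
emulate, and the numerical choices behind the implementation.

## Spore colour model

Interior pixels of stained conidia occupy a nearly one-dimensional structure
in RGB space: the blue component spans roughly 100–250 and rises and falls
together with red and green. The model is the eigendecomposition of the
centred second-moment matrix (covariance) of labelled spore pixels: mean
`r̄`, eigenvalues `λ₁ ≥ λ₂ ≥ λ₃ > 0` and orthonormal eigenvectors
`v₁, v₂, v₃`. A pixel `p` is scored by the Mahalanobis quadratic form

    s(p) = Σᵢ cᵢ² / λᵢ ,   cᵢ = vᵢ · (p − r̄),

which is 0 at the mean and averages 3 (the dimension) over the training
pixels. A pixel is classified spore-coloured when `s < P1` (strict).

Two readings of the score were possible: an uncentred form in raw RGB
coordinates, and the centred eigenbasis form. The uncentred form scores any
dark pixel as spore-like regardless of hue (all channels small ⇒ small
quadratic form), so the centred form is implemented. Likewise the
eigenstructure is taken from the covariance rather than the correlation
matrix, so that eigenvectors live in RGB units and the score is the standard
Mahalanobis distance. Eigenvalues are floored at `1e-6·λ₁` so the score
stays finite for nearly degenerate training sets; when the floor triggers,
the mean-score-equals-3 identity no longer holds exactly.

* `P1` (default 9.0): ≈ 3σ in three dimensions. Data-product dependent, as
  are all thresholds below; pixel values are not radiometrically calibrated,
  so the defaults suit imagery resembling the synthetic scenes and should be
  re-tuned per slide-preparation protocol.
* Minimum training sample count: 50 (default); a few thousand pixels from a
  handful of spores is comfortable.

## Gradient segmentation

The score field `s` is treated as a scalar field on the pixel grid
(x = column rightward, y = row downward). Its gradient is estimated per
pixel by least squares over a square window (default 5×5): with
displacements `Δrᵢ` from the window's mean position, solve
`G ∇s = m` where `G = Σ Δrᵢ⊗Δrᵢ` and `m = Σ s(rᵢ)Δrᵢ`. Border pixels use
the truncated in-bounds window. The solve is exact on affine fields for
every window size. Windows whose Gram matrix is rank deficient (fewer than
three non-collinear pixels, e.g. single-row images) get a zero gradient and
a flag.

Smooth spore borders produce neighbourhoods of large parallel gradients.
The directional average replaces the gradient at `r` by the mean of the
gradients at `r`, `r+p`, `r−p`, where `p = a·R·n` steps the offset
`a` (= P2, default 3 px) sideways along the border (`n` the gradient
direction, `R` the 90° rotation; either rotation sign yields the same
symmetric sample pair — counter-clockwise is fixed for reproducibility).
Off-grid offsets round to the nearest pixel (the operator is already an
average; interpolation would add cost without changing its character) and
clamp at image edges. Zero-gradient pixels are copied unchanged.

The extreme-pixel rule then keeps pixels whose averaged-gradient magnitude
exceeds `P3` *and* which have strictly fewer than `top_fraction × (N−1)`
strictly-greater neighbours in an odd `neighbourhood_side`×`neighbourhood_side`
box (defaults 0.25 and 7; `N` is the in-bounds neighbourhood size, the pixel
itself excluded from the count). Strict inequalities mean plateaus pass.
The rule is rank-based, hence invariant under monotone transforms of the
magnitudes that preserve the threshold set. Because pixel values are
uncalibrated, `P3` defaults to the 99th percentile of the per-image
magnitude distribution; an absolute override is available.

## Combining colour and edge evidence

The score-gradient ridge straddles the colour-class boundary: the crest sits
where the pixel colour is midway between spore and background, which scores
above `P1`. A literal intersection of the colour mask and the extreme-pixel
mask is therefore nearly empty. The pipeline instead requires the two
evidences to agree to within a small radius: segmentation =
extreme-pixel mask ∧ (colour mask dilated by `colour_agreement_px`,
default 3 px ≈ gradient-window plus blur scale). This keeps the border
rings of spores and discards background-noise ridges and off-colour (dust)
edges.

## Blob extraction and measurement

The segmentation is closed with a disc of radius 3 µm, split into
8-connected components (4-connectivity is available), and each component is
replaced by the pixels inside the convex hull of its pixel centres and then
opened with a 2 µm disc (largest piece kept, splinters become separate
blobs). Structuring discs are discrete Euclidean discs with radius
`round(radius_um / pixel_size_um)` — 6 px and 4 px at the default
0.5063 µm/px. Closing and opening operate on padded arrays so they are
exactly extensive/anti-extensive and idempotent.

Because the detected ring is centred on the gradient crest, which lies
systematically *outside* the true region border by roughly the blur scale,
blobs inherit an outward bias (measured on synthetic truth: about +1.7 µm
in width, +0.7 µm in length — the opening partially shaves pointed tips,
which reduces the length bias). The pipeline compensates by eroding each
opened blob with a disc of radius `edge_bias_um` (default 1.0 µm) before
measurement. Residual bias after compensation is a few tenths of a
micrometre; true spores within ~1 µm of a size bound can still fall on the
wrong side of the filter, which is the dominant loss mode of the chain.

The principal axis of a blob maximises `Σ (n·rᵢ)²` over centred pixel
positions (equivalently minimises the summed squared cross products) — the
dominant eigenvector of the 2-D scatter. Blobs with equal scatter
eigenvalues are flagged isotropic and get the default axis (1, 0). Length
and width are the extents of the pixel-centre projections on the axis and
its normal, plus one pixel (area convention), times the pixel size. The
size filter accepts blobs inside 15–40 µm × 9–16 µm (primary conidia,
inclusive); a secondary-conidium preset (16–25 µm × 7–15 µm) is provided.

## Egg shapes and fitting

Opened spore profiles resemble eggs. The egg family is the image of the
unit disc under a taper `F_c:(x,y) ↦ (x, (c·x+1)·y)` followed by scaling
`G_{a,b}:(x,y) ↦ (a·x, b·y)`; the boundary is

    (a·cos t,  b·(c·cos t + 1)·sin t),  t ∈ [0, 2π).

`|c| < 1` keeps `c·x+1 > 0` over the disc and the map injective (the
source formulation states no bound; this one is imposed for
well-posedness, with the optimiser restricted to `|c| ≤ 0.95`). The family
has the symmetry `(θ, c) ↔ (θ+π, −c)`; fits are canonicalised to `c ≥ 0`,
with θ in [0, 2π) and collapsing to [0, π) when c = 0.

Goodness of fit between the sampled egg curve and the blob perimeter
(sub-pixel marching-squares contour) combines the symmetric Hausdorff
distance between vertex samples with the curve integral
`d_L2 = ∫ d(r, ∂B)² ds` over the egg (midpoint rule per segment, distance
to the nearest point of any perimeter segment). No combination weights are
given in the source; the package normalises `d_L2` by the egg perimeter and
takes the square root, making it an RMS distance in pixels commensurate
with the Hausdorff term, and combines with weight `w = 0.5` (configurable).

Fitting minimises the combined score over `(a, b, c, cx, cy, θ)` with
Nelder-Mead (derivative-free; bounds enforced by penalty), initialised from
the blob centroid, principal-axis angle and half extents. Multi-start runs
taper seeds `c₀ ∈ {0, +0.3, −0.3}`; the `(θ+π, −c)` symmetry makes separate
axis-orientation starts redundant. Each start is capped at 500 evaluations
with `xatol = 1e-2` px and `fatol = 1e-3` (tighter tolerances exhaust the
evaluation cap without improving the fit). The egg curve is sampled at 256
points during optimisation and 1024 points for the reported distances.
On blobs rasterised from known parameters in the conidium size range the
fit recovers `a` and `b` to a few percent and `c` to better than ±0.1
(median), with centres within a pixel.

## Validation checks

Two checks examine the fitted candidate against the image:

* **Gradient–normal alignment.** Points on an outer curve — the fitted egg
  offset outward along local normals by `outer_margin_um` (default 2 µm;
  the construction is not specified in the source, a fixed physical margin
  is this package's choice) — sample the averaged gradient field; the check
  returns the mean `|cos|` between gradient and outward normal. Real smooth
  borders give values near 1; random texture gives the chance level
  2/π ≈ 0.637. Candidates below `alignment_min` (default 0.7) are rejected.
  If more than half the sampled gradients vanish the check is flagged
  inconclusive and does not reject.
* **Background correlation.** Luminances on an inner curve (fitted egg
  scaled by 0.7) and the outer curve, paired at matching parameter angles,
  are correlated (Pearson). A spore's colour does not follow its
  background, so high correlation (> `correlation_max`, default 0.6) marks
  background texture continuing through the blob and rejects the candidate.
  Constant samples make the correlation undefined: flagged neutral.

Every blob that reaches size filtering becomes a candidate with exactly one
verdict: `accepted`, `rejected_size`, `rejected_fit` (non-convergence or
combined score above `max_fit_score`, default 2.0 px — the source names no
fit-quality threshold, but without one the shape stage could never reject),
`rejected_alignment`, or `rejected_correlation`.

## Spore-trap tape arithmetic

One 24 h trap rotation yields a tape cut into six 4.9 cm pieces of 4 h
each; transects are read every 2.0 mm, each representing 10 min, giving 144
transect readings per cycle. The printed tape length (345 mm) is not
exactly six 49 mm pieces and 345/144 ≈ 2.4 mm per transect; the utility
follows the 10-minutes-per-transect, 144-per-cycle arithmetic and documents
the discrepancy.

## Synthetic scenes

The generator renders slide-like scenes with ground truth: a bright
background (231, 233, 240), obovoid spores with lengths 15–40 µm, widths
9–16 µm and tapers 0.1–0.5 placed without overlap by rejection sampling,
and 10s of small (3–8 µm) saturated blue dust distractors off the spore
colour line. Spore interiors sample a colour line from (60, 75, 100) to
(210, 220, 250) — blue spanning ~100–250, channels strongly correlated, the
first principal component explaining ≳ 99 % of the variance — with
per-pixel spread along the line (σ = 0.12 of its length) and isotropic
jitter (σ = 4). Borders are anti-aliased by 4× supersampled coverage of the
exact inverse-map inside test; the image is blurred (Gaussian, σ = 1 px)
and pixel noise (σ = 2.5) added; everything is deterministic per seed.
Scenes use the microscope's 0.5063 µm/px scale.

What the generator does **not** emulate: per-spore defocus (a single global
blur stands in for one chosen focal plane), staining-chemistry colour
physics, touching or overlapping spores, and non-uniform illumination.
Passing the end-to-end tests therefore shows the chain is correct and
well-calibrated for imagery with these statistics, not that the default
thresholds transfer to any particular slide-preparation protocol — P1–P3
are explicitly data-product dependent.

## Problem sizes in the shipped tests

The end-to-end suite uses twenty 1024×1024 scenes with 0–10 spores and
10–30 dust each; parameter recovery uses 30 rasterised blobs across the
conidium size range; the oracle comparisons run thousands of randomised
cases. A full detection pass on a 1024×1024 scene takes a few seconds on
one CPU, dominated by the per-blob egg fits.

## Known limitations

* Spores within ~1 µm of a size-filter bound can be lost or gained through
  the residual measurement bias of edge-based segmentation.
* Touching spores are not declumped; they merge into one blob and are
  usually rejected by size.
* Strongly tilted spores appear rounder in projection; the fit reports the
  projected shape (no 3-D modelling).
* The basal papilla is not modelled as a separate feature; the opening step
  absorbs it.
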