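# Methods

`epsquant` quantifies residual biofilm/EPS and microbial morphometry in
scanning electron micrographs of fungal–bacterial cocultures: tubular
hyphae a few microns wide, rod-shaped bacteria around half a micron wide,
and thin curvilinear exopolymer (EPS) structures, including the
attachment structures that anchor bacteria to hyphal surfaces. This note
records the model, the estimators, the defaults and the reasoning behind
the choices that were genuinely open.

## Ridge model

A micrograph is a calibrated intensity field `I(x, y)` with a
microns-per-pixel scale obtained from a JSON sidecar as
`scale = 1 / pixels_per_micron[name]`. Bright curvilinear structures are
detected through the Hessian

    H = [[Ixx, Ixy],
         [Ixy, Iyy]],

computed by separable convolution with sampled Gaussian-derivative
kernels at scale σ (pixels). The kernels are moment-corrected so that the
discrete operator annihilates constants exactly and maps `x²` to exactly
2; plain sampling of the analytic derivatives leaves a DC gain of order
1e-4 that would contaminate flat regions. Boundaries are reflected.

With eigenvalues ordered `|λ1| ≤ |λ2|` (ties broken toward the more
positive value in `λ1`), a bright ridge is a pixel where `λ1 ≈ 0` and
`λ2 ≪ 0`, and the hard-conditioned response is

    R = |λ2|   if |λ1| ≤ α·|λ2| and λ2 < −τ,
    R = 0      otherwise.

The qualitative conditions are operationalized by `α = 0.25` (a relative
tolerance keeps the test invariant to the intensity scale) and `τ = 0`.
This piecewise form is implemented verbatim; the continuous 1998
vesselness response is deliberately not the reference behavior. `R` is
invariant under adding a constant to the image and scales linearly with
image contrast (for τ = 0).

The multi-scale response takes the per-pixel maximum of σ²-normalized
single-scale responses over 10 geometrically spaced scales in
`σ ∈ [1, 50]` px. σ is in pixels, matching the convention of the common
ridge-filter implementations; the interval is read as a sweep range, and
geometric spacing is scale-space practice. Without σ²-normalization the
maximum would always be attained at the smallest scale; normalization is
therefore on by default in the sweep and optional for a single scale. At
a Gaussian ridge profile of scale `s` the normalized response peaks at
`σ = √2·s`, so `argmax σ` tracks structure width up to that factor.

## Segmentation

The biofilm ("vessel") mask is obtained by thresholding the response.
Otsu's method (256-bin histogram) is applied to the *positive* response
support — the response is overwhelmingly zero, and a histogram dominated
by zeros would merely separate zero from nonzero — followed by hysteresis
growth at half the threshold, so that a faint strand is kept end to end
once any part of it is confidently detected. A manual threshold bypasses
both refinements (`mask = R > t`). Because a ridge response spreads
roughly one smoothing scale beyond each structure's edge, the raw support
overstates areal coverage by tens of percent for thin structures; when
the source image is available, each detected component is re-cut at half
its intensity plateau (the FWHM footprint, the unbiased boundary of a
plateau object under symmetric blur), restoring pixel-accurate areas.

Component classification is width- and shape-based, with all bounds in
microns so the rules are resolution independent:

- A three-class Otsu split of the intensity histogram separates the dark
  field, the faint EPS film, and the bright cellular plateaus. A robust
  guard (the faint threshold must clear the dark-field median by three
  MAD-based standard deviations) falls back to a single Otsu threshold
  when no faint class exists.
- Wide structures are isolated by morphological opening with a disk of
  half the minimum hyphal width (default `hypha_min_width = 1.5 µm`) and
  classed as hyphae when their curvilinear elongation `area / width²`
  is at least 3. The ellipse-axis ratio is not used: bending deflates it
  below 3 for strongly sinuous tubes while `area / width²` is unaffected.
- Among the remainder, a small opening (half the minimum bacterial
  width) removes sub-bacterial filaments; surviving candidates are
  re-cut at their half-max footprint (the faint-threshold blob can annex
  blur glow between a cell and a neighboring structure) and accepted as
  bacteria when the second-moment ellipse axes fall in
  `length ∈ [0.25, 3.0] µm`, `width ∈ [0.2, 1.0] µm`, solidity ≥ 0.8,
  and the median intensity reaches the bright-cell level.
- EPS/biofilm is residual: ridge-detected or faint-foreground material
  that is neither fungal nor bacterial. Components below 4 px are
  discarded as noise. Connectivity is 8-connected throughout so diagonal
  filaments do not fragment.

## Morphometry

Area and coverage follow the printed identities
`A_v = vessel_pixels·scale²`, `A_t = M·N·scale²`,
`P_v = 100·vessel_pixels/(M·N)`; the reported biofilm area uses the
FWHM-refined residual EPS mask.

**Rods.** Length and width are the second-moment (equivalent-ellipse)
axes of the half-max-refined region, converted to microns, with
length ≥ width enforced. For an elliptical region these axes equal the
true diameters; they are robust to boundary pixelation and rotation,
unlike Feret diameters.

**Tubes.** Width is `2·median(EDT) − 0.5` px sampled along the
morphological skeleton, where EDT is the Euclidean distance transform.
Spur branches grown by boundary roughness are pruned by iterative
endpoint deletion before sampling; the −0.5 px term removes the average
overshoot of twice the centerline distance for a band of discrete pixel
columns. Regions thinner than 2 px are quantization dominated and report
the integer pixel-count width (a one-pixel line reports one pixel) with
a warning. The width is measured on the disk-opened class mask, whose
boundary is morphologically smoothed, rather than on a re-thresholded
mask that would re-import noise raggedness.

**Attachment structures.** For every EPS component whose 1-px dilation
touches both a bacterium and a hypha, and for every bacterium it
touches, a geodesic route is found by minimum-cost path through the
component with costs inversely weighted by the ridge response, so the
route follows the filament's intensity crest rather than cutting through
faint blur glow between nearby cells. The reported length runs between
the anchors' half-maximum crossings: the route (or, when it is short or
its chord toward the nearest hyphal point is consistent with it, that
chord) is extended into both anchors, the lightly smoothed intensity is
sampled along it, and each crossing level is the anchor's half-max
raised by half the filament's mid-path excess — at the junction only the
outward half of the filament band adds to the anchor's edge profile.
Anchors are the half-max object masks opened by a small disk, which
shaves the "nose" that additive blur overlap grows where a filament or
EPS strand abuts a cell. When intensity information is unavailable the
length falls back to the smoothed pixel-chain length plus one pixel for
the two half-pixel interfaces, which is exact for crisp masks. Geodesic
(not straight-line endpoint) distance is used because the imaged
structures are curvilinear. The pipeline reports one anchoring structure
per bacterium (the sub-pixel-localized, sub-micron candidate with the
strongest ridge support), and the search is windowed to 2 µm around each
cell.

**Exclusions.** Mirroring the criterion that occluded, deformed or
partially visible organisms are not measured: border-touching bacteria
are excluded as "partial" (occlusion cannot be detected automatically
and is approximated by the border rule), bacteria with solidity < 0.8 as
"deformed". Hyphae routinely span the whole field and their transverse
width stays measurable when they do, so a hypha is "partial" only when
little more than a stub is visible (length under twice its width).
Excluded objects are retained in outputs, flagged, and omitted from
summaries.

**Summaries.** Per-sample and pooled mean ± SD per metric, population SD
(ddof = 0, configurable); SD is 0 for n = 1 and an empty metric is
flagged with n = 0 rather than silently zero. Bacterial density, where
reported, is count per total field area (whether the original analysis
normalized by hyphal surface area instead is unknowable from a
projection).

## Synthetic scenes

Real micrographs from the study are not deposited, so every stage is
validated against generated scenes with exact ground truth. Defaults are
the reported morphometry: hypha width 3.0 ± 0.5 µm in coculture
(3.4 ± 0.4 µm for monoculture controls), bacteria 1.4 ± 0.4 µm long and
0.5 ± 0.1 µm wide, attachment filaments 0.3 ± 0.1 µm long and 0.08 µm
wide, EPS coverage 18.33% of the field. All dimension distributions are
normals truncated to the reported minima/maxima (e.g. bacterial length
[0.53, 2.6] µm), honoring mean, SD, min and max simultaneously. The
raster default is 1024×1024 at 20 px/µm (≈51×51 µm), which places the
0.08 µm filaments (~1.6 px) near the detectability limit, matching the
challenge of the real data. The number of hyphae per field (default 3)
and bacteria (default 12, one filament each) are not constrained by any
reported value and are exposed as parameters.

Geometry: smooth sinusoidal tube centerlines (one per vertical band so
tubes do not collide); rods placed adjacent to tubes, axis parallel to
the local tangent, at a boundary gap drawn from the filament-length
distribution; a straight filament bridges each rod to its tube with that
gap as its exact geodesic length; additional loose EPS strands (smooth
random walks) are added until the EPS class reaches the target coverage
within ±1 percentage point or a placement budget is exhausted (then a
warning reports the achieved coverage). Loose strands carry their own
width distribution (0.25 ± 0.08 µm, range [0.12, 0.45] µm): resolvable
strands make pixel-level coverage well-posed, whereas a field covered
18% by sub-pixel lines would make the coverage target meaningless — a
±0.3 px detector footprint error would move coverage by over 3 points.
Filler strands keep a 3-px clearance from bacteria so that only true
attachment structures are ever adjacent to a rod.

Rendering: per-class intensity plateaus (background 0.05, EPS 0.55,
hypha 0.75, bacterium 0.95) composited EPS → hyphae → rods, Gaussian
blur of 0.5 px, additive Gaussian noise (σ = 0.05), clipped to [0, 1].
All layers are rasterized on a 2× supersampled grid and pooled to area
fractions: rods are rotated ellipses (their second-moment axes then equal
the nominal diameters), and anti-aliasing gives thin strands the same
mass per unit length in every direction — a 1-px Bresenham chain renders
diagonal filaments ~30% fainter than axis-aligned ones. Truth masks are
majority-coverage pixels, carved disjoint with priority
bacterium > hypha > EPS. One seeded generator stream makes every scene
bit-reproducible.

What the generator does **not** emulate: electron-optics effects
(charging, edge brightening, detector noise statistics), 3-D topography
and the resulting occlusion, dehydration artifacts, touching
binary-fission chains, or EPS films of spatially varying density.
Passing recovery tests on these scenes therefore demonstrates the
correctness and calibration of the estimators under known geometry and
additive noise — not performance on real SEM data.

## Validation results and problem sizes

The recovery battery uses 20 seeded default scenes (≈240 rods, 60 tubes,
240 filaments); unit fixtures use 512×512 fields. On the battery, pooled
recovered coverage is within 0.2 percentage points of truth, and mean
rod length, rod width and tube width are within 0.05 µm (one pixel) of
the truth means; the pooled recovered attachment length matches the
generator's 0.3 µm mean to a few percent. Attachment filaments are
detected for ~99% of rods, but only about three quarters of individual
filaments are recovered with geodesic length within 15%. That last
figure is the known weak point: at 20 px/µm an attachment is 2–12 px
long, the 15% band at the mean length is ±0.9 px (and under ±0.5 px for
the shortest gaps), while blur glow plus EPS-network clutter at the
junctions shifts individual half-max crossings by about a pixel. (The
original analysis measured attachment structures on higher-magnification
micrographs.)

## Known limitations

- All measurements are 2-D projections; no stereological correction is
  attempted even though the imaged samples are three-dimensional.
- Touching bacteria (binary-fission pairs) are measured as single
  objects if fused.
- The classification rules reconstruct, from printed size ranges, a
  separation the original analysis performed by unstated means; they are
  a reasonable but unverifiable surrogate.
- Attachment-length accuracy is pixel-limited at the default 20 px/µm,
  as quantified above.
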