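# Methods

This note documents the models and numerical choices behind polaritykit:
how a segmented image becomes per-cell polarity and shape readouts, what the
simulated-cell generator emulates, and which design decisions were genuinely
open (with the reasoning that fixed them).

## Segmentation parsing

The required inputs are an intensity image and a binary skeleton: a
1-pixel-wide boundary network separating cell interiors, as produced by
watershed segmentation tools. Cell interiors are labeled as 4-connected
regions of the skeleton's complement; the network itself is treated as
8-connected — the complementary pairing that prevents regions from leaking
through diagonal line pixels. Cells touching the image frame are flagged and
(by default) removed together with sub-threshold specks before analysis,
because frame-truncated cells have no complete junction set; adjacency is
rebuilt after filtering, so links into removed cells disappear.

A vertex (tricellular junction) is a skeleton pixel whose vertex degree
k = n₃ₓ₃ − 1 — the number of foreground pixels in its 3×3 neighborhood,
center excluded — is at least 3, i.e. a meeting point of three or more
edges. Rasterization smears one biological vertex over small pixel clusters;
8-connected clusters are merged to their mean position. Two cells are
neighbors when they share a boundary segment, operationalized as at least
two skeleton pixels seeing both cell labels in their 8-neighborhood; a
single shared pixel is vertex-only contact and does not count.

Each cell's boundary is the ordered closed loop of skeleton pixels adjacent
to its region (counter-clockwise in the y-up frame; a greedy 4-before-8
connected walk over the ring pixels). The perimeter is the loop path length
with √2 diagonal steps; the area is the pixel count of the labeled region;
the centroid is the region's area centroid. Coordinates are 0-based pixel
indices; all angles are reported in a y-up mathematical frame, so 0° is the
image x-axis and +90° points up.

## Boundary intensity profiles

Junctional intensity is sampled at every boundary pixel as the mean image
intensity over *junction* (skeleton) pixels within a disk of diameter
`thickness` (default 3 px). Restricting the disk average to the skeleton
keeps the readout free of geometry-dependent dilution by the dark cell
interior; signal from abutting cells is shared, as it is optically
inseparable. The sampling width is a free parameter: 3 px emulates the
junctional signal width of typical confocal data, while noiseless simulated
cells (whose painted junction is exactly 1 px wide) are validated at
thickness 1. No background subtraction or flat-field correction is applied.

Each sample gets a circular midpoint quadrature weight
dθᵢ = ((θᵢ₊₁ − θᵢ) + (θᵢ − θᵢ₋₁))/2 (circular wrap-around), so the weights
partition the circle exactly and dense pixel clusters (short edges near the
centroid, raster line direction effects) do not bias angular integrals.

## Polarity methods

All three methods consume the same profile and report an axial angle in
(−90°, +90°] plus a raw magnitude; per-dataset normalized magnitudes divide
by the dataset maximum (for the Ratio method, after subtracting its
unpolarized baseline of 1).

**Fourier series.** The nematic tensor components are the intensity-weighted
second circular harmonics Q₁, Q₂ normalized by N = Σ I dθ (making the
readout brightness-invariant); magnitude √(Q₁²+Q₂²), angle ½ atan2(Q₂, Q₁).
An all-zero profile is reported as degenerate, not as zero polarity.

**Ratio.** The profile is linearly interpolated onto a uniform angular grid
(default 1°, configurable), grouped into four 90° bins for each trial axis φ
(default 1° steps over the 90° fundamental domain — the asymmetry has period
90° up to pair swap), and the asymmetry at φ is the ratio of the two
opposite-pair summed bin means, oriented ≥ 1 and rounded to 10⁻³. The
magnitude is the maximum asymmetry; the angle is the circular axial mean of
all maximizing axes. The rounding deliberately groups numerically-tied trial
axes: for sector-like patterns the asymmetry has an exactly flat plateau of
maximizers (e.g. ±15° for a pattern whose 90° bin sits inside a 120° peak
sector), and the tie-group average recovers the pattern center. Bin means —
not sums — make the method independent of junction length. A uniform
profile yields asymmetry 1 everywhere; its maximizers cancel and the angle
is undefined.

**PCA.** Four steps per cell:

1. *Compression.* A direct least-squares ellipse (the ellipse-constrained
   algebraic fit, which cannot return a hyperbola on noisy rasters) gives
   semi-axes a ≥ b and orientation θ_c. The boundary is rotated by −θ_c,
   compressed by α = b/a along the major axis, rotated back, and the angles
   and weights are recomputed from the transformed coordinates. α = b/a
   realizes "compress the cell's own ellipse to a circle"; α = 1 for a
   circular cell. Recomputing dθᵢ after compression is deliberate: the
   compression changes angular density, and the weights must describe the
   coordinates actually used.
2. *Intensity normalization.* I′ᵢ = k·Iᵢ/⟨I⟩_dθ with k = 10³ by default.
   This removes image brightness and bit depth from the readout; k sets the
   baseline radius of the embedded cloud (see below) and 10³ keeps the
   log-radius baseline (ln k ≈ 6.9) large against the per-point variation,
   which is what makes the magnitude scale cleanly.
3. *Radial embedding.* Each sample becomes the point
   (Rᵢ cos θᵢ, Rᵢ sin θᵢ) with radius Rᵢ = ln(max(I′ᵢ, 1)). The logarithm is
   a reconstruction choice (the original formulation is not fully published)
   fixed by the method's documented behavior, all of which it reproduces
   simultaneously and none of which a linear radius satisfies:
   complementary coverage patterns polarize equally; the magnitude grows
   linearly in the log of the peak-to-base ratio over the tested range
   (R² > 0.999) instead of saturating; the coverage optimum falls near
   half-coverage; and the normalization factor k matters at all (an
   eigenvalue *ratio* would be scale-free and make step 2 pointless).
4. *Weighted covariance.* σ_ab = Σ dθᵢ (aᵢ−ā)(bᵢ−b̄)/Σ dθᵢ with weighted
   means; p = λ₁ − λ₂ and θ = ½ atan2(2σ_xy, σ_xx − σ_yy) (the principal
   axis). A homogeneous profile puts the points on a circle, λ₁ = λ₂ and
   p = 0 (angle reported as missing); the greater the bipolar asymmetry the
   greater the eigenvalue split.

## Tissue statistics

Polarity axes are nematic, so all vector operations run on the doubled-angle
circle: cell i contributes (pᵢ cos 2θᵢ, pᵢ sin 2θᵢ). The vector-average
magnitude is the norm of the mean vector and never exceeds the plain mean of
magnitudes, with equality exactly at perfect alignment. Coarse-graining
partitions cells into contiguous equal-count groups by rank-tiling their
centroids (the tissue is split along its longer extent first); neighbor
vector polarity averages each cell with its adjacency neighbors and then
averages those values across the tissue. The circular angle variance is
1 − |⟨e^{2iθ}⟩| (0 = aligned, 1 = fully misaligned); the mean angle
difference between two methods is the mean per-cell axial difference
min(|Δ|, 180° − |Δ|), bounded by 90°. Weighted circular histograms double
each axis to θ and θ+180°, bin 0–360° into 20 left-closed bins, and weight
each bin's count by its mean magnitude.

## Simulated cells

The generator builds what the validation studies need: single rasterized
polygonal cells with known ground truth.

*Geometry.* A regular n-gon (default hexagon, vertex on the +x axis) sized
to a target perimeter or interior area; optional vertex jitter for shape
regularity targets; area-preserving anisotropic scaling (x·s, y/s) with
s = (1−ε²)^(−1/4) for eccentricity targets. The polygon outline is drawn as
a 1-px 8-connected boundary on a canvas with an 8-px margin. A closed
calibration loop re-rasterizes and re-measures up to six times, adjusting
the scale (the 1-px ring eats roughly one perimeter of interior pixels) and,
for ε > 0, the stretch factor against the fitted-ellipse readout; achieved
areas land within ±1% and eccentricities within ±0.01 for targets ≥ 0.2.
Below ε ≈ 0.2 the fitted eccentricity of a raster polygon has a noise floor
of ~0.02–0.04 (an ε near 0 is an ill-conditioned function of sub-pixel axis
differences), and at ε = 0 no calibration is attempted: the regular polygon
is itself the ground truth and deforming it to cancel oracle noise would
corrupt the profile. Regularity targets are met by seeded rejection sampling
of radial+angular vertex jitter (tolerance ±0.02); each candidate is first
"circularized" by its own fitted ellipse so that regularity varies at
near-constant eccentricity — a controlled single-factor sweep (uncontrolled
jitter-induced elongation of up to ε ≈ 0.5 would otherwise confound the
regularity sweep through the PCA compression step).

*Intensity.* Two-level patterns paint peak (255 a.u.) on a placement defined
in *material* angle ψ (the pre-elongation angle of each boundary point), so
the same junctions carry peak protein at every eccentricity: vertical
junctions (|ψ| within 60° of either x-pole — exactly the two
vertical-junction edge pairs of the vertex-at-0° hexagon), their complement,
an explicit ±d° sector, or coverage (u perimeter units of peak grown
symmetrically along the loop from the two θ = 0°/180° poles, with u on the
nominal polygon-perimeter scale so that u = perimeter means fully covered).
Sector and coverage edges are anti-aliased: a pixel straddling the boundary
gets the covered fraction of its angular (or arc) footprint, which removes
most of the raster quantization from the sweep profiles. Punctate patterns
place Gaussian puncta every 15° of material angle with amplitude given by a
two-level envelope evaluated analytically at each punctum center (a punctum
exactly on a sector edge counts as peak — deterministic at every raster
scale), relaxing to the 40 a.u. floor between puncta:
I = 40 + (A−40)·exp(−Δ²/2σ²). σ = 4.47 is interpreted in *degrees* by
default (arc-pixel units are an option): degree units make the angular
profile independent of cell size, which is what keeps the integral methods
stable on the puncta area sweep and leaves raster discretization as the only
fluctuation source. Images are stored as 8-bit by default (12/16-bit
options) with 255 a.u. mapping to full scale.

*Noise.* Zero-mean Gaussian noise with sd = (mean boundary signal)/SNR,
seeded, added to the whole image and clipped to the bit range. The noise
study grid is SNR ∈ {4, 8, 16, 32} with 20 seeds per level — the realistic
live-confocal range, with the lowest level visibly degraded (at SNR ≈ 3 the
clipping bias alone already exceeds 10% of the two-level contrast).

*What the generator does not emulate.* Multicellular mechanics, point-spread
optics, photobleaching, cytoplasmic background and segmentation errors are
absent; passing validation on these fixtures demonstrates the methods'
geometric and photometric behavior, not performance on real tissue.

## Validation studies and known limitations

`polaritykit.studies` runs the canonical characterization experiments
(asserted in `tests/test_acceptance.py`, re-computed by
`scripts/acceptance.py`). Headline behavior: on the perimeter-440 coverage
sweep the Ratio magnitude peaks at 200 px, Fourier at 160 px and PCA at
200 px (half-coverage, with complementary coverages equally polarized); on
the eccentricity sweep PCA is flat within 1% while Fourier and Ratio grow
with elongation along the polarity axis; all methods hold their angle
readouts within 0.5° of ground truth on noiseless fixtures; puncta
fluctuations stay below 1%; PCA magnitude is log-linear in peak-to-base
ratio with R² > 0.999.

Three honest limitations, visible as failing assertions rather than hidden:

- *Ratio eccentricity optimum.* The rotating-quadrant asymmetry is monotone
  in eccentricity here (maximum at the sweep end, 0.8) rather than peaked at
  an intermediate value; an extensive reconstruction search (angular vs
  arc-length weighting, hexagon orientation, elongation axis, material vs
  angular painting) found no faithful variant with an interior optimum, so
  this readout should be treated as implementation-sensitive.
- *Ratio angle plateau.* For patterns whose peak sectors exceed the 90° bin,
  the asymmetry is exactly flat over a ±15° range of trial axes; noise
  collapses the rounded tie-group to a single maximizer, so noisy ratio
  angles wander deterministically up to 14°. This is structural, not a
  numerical artifact.
- *Noise worst case.* Maximum (over 80 noisy draws) relative magnitude
  errors are typically 6–13%, occasionally ~15% for PCA at SNR 4, where
  clipping at zero and the log embedding amplify base-level noise; means per
  SNR level stay below 6%.

Magnitude-fluctuation metrics are reported as the maximum relative deviation
from the sweep mean on each method's raw magnitude scale (the Ratio
magnitude being the asymmetry itself, which starts at 1). Shape regularity
values are method-internal: the deviation score
D = Σ|lᵢ−l_med|/Σlᵢ + (1/n)Σ|φᵢ−φ_reg|/φ_reg, μ = max(0, 1−D) (chord lengths
and interior angles at merged vertices) satisfies the defining fixed point
(μ = 1 iff equilateral and equiangular) but is a reconstruction; μ values
should not be compared across software.
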