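# Methods

## Problem and model

In intestinal anastomosis the surgeon rejoins two bowel ends with a ring of
sutures. Good placements avoid blood vessels (bleeding, stricture), sit on
mechanically strong double-layered tissue, and keep the recommended bite
depth of 1.5 tissue thicknesses from the cut edge. This package turns a
co-registered multiband cross-polarized reflectance stack (bands at 470,
600 and 770 nm) into three per-pixel score maps in [0, 1] and fuses them
multiplicatively into a suture map

    J(u, v) = V(u, v) · T(u, v) · B(u, v),

so that J = 0 wherever any single factor forbids a suture and J ≈ 1 only
where all three agree. Recommendations are strict 8-neighbor local maxima
of J above a threshold, thinned to an equidistant subset along the cut
edge.

### Vessel-possibility map V

Vessels are dark tubular structures, most pronounced at 470 nm where
hemoglobin absorption is strong. The 470 nm band is filtered with a
multiscale Hessian (Frangi) vesselness: at each scale *s* the band is
Gaussian-smoothed, the scale-normalized Hessian is formed with explicit
3-point second-difference stencils (s² normalization), its eigenvalues are
ordered |λ₁| ≤ |λ₂|, and the response is

    v = exp(−R_b²/2β²) · (1 − exp(−S²/2c²)),   R_b = λ₁/λ₂,  S = √(λ₁²+λ₂²),

zero where λ₂ ≤ 0 (wrong polarity for a dark ridge), maximized over scales.
Defaults: scales {1, 2, 3, 4} px, β = 0.5, c = half the maximum Hessian
Frobenius norm per scale — the standard published defaults of the filter.
The vesselness is binarized (default: 0.5 of the map maximum; Otsu
optional), negated (vessels 0, background 1), Gaussian-smoothed with
σ = 0.3 mm to grade the pixels next to a vessel, and the exact zeros are
re-imposed inside the binarized vessels: plain smoothing would leak
positive values into them, and a confident vessel must stay at V = 0.

### Thickness map T

Thick/thin differentiation uses the spectral angle mapper: every pixel is
assigned the endmember reference minimizing the angle between spectrum
vectors, which is invariant to positive scaling and hence to illumination.
References are means over five disjoint patches per tissue type (thick
non-incised serosa, thin serosa, incised single-layer tissue). Pixels whose
best angle exceeds 0.10 rad stay unclassified — loose enough to absorb
sensor noise on tissue, tight enough to reject background. Mesentery
(from the discriminant class map) and segmented vessels are excluded before
the thickness analysis, since neither is suturable bowel wall. The binary
thick map (thick = 1) is smoothed with the same 0.3 mm Gaussian as V.
Thickness is categorical (thick vs thin endmembers), not a continuous mm
estimate.

### Class map and bite-depth map B

The full stack is classified into background, inner lumen
(mucosa/submucosa), outer lumen (serosa) and mesentery by a Gaussian
maximum-likelihood (quadratic) discriminant trained on user-designated
rectangles: per-class means and covariances, diagonal loading
ε = 10⁻⁶ × mean variance with an absolute floor of 10⁻¹² so that noise-free
(zero-variance) training data still yields a positive-definite covariance;
equal priors; ties break to the lowest class index. The cut edge is the
intersection of disk-dilated (radius 2 px) inner- and outer-lumen masks.
With d(u, v) the Euclidean distance (mm) to the nearest edge pixel, serosal
pixels score

    B = exp(−(d − 1.5τ)² / 2σ²),   σ = (1.5τ − δ)/3,

and B = 0 for d < δ and outside the serosa. τ is the tissue thickness
(per-sample input; 1 mm in the worked example), δ ≥ 0.5 mm the clearance
floor; the 3σ rule places 99.7% of the response between δ and
1.5τ + (1.5τ − δ). At τ = 1 mm, δ = 0.5 mm this gives σ = 0.33 mm. The
Gaussian is evaluated analytically on the distance transform rather than by
convolving the edge with a kernel: the two are equivalent for a band around
a curve, and the explicit form makes the peak at d = 1.5τ exact. The band
is one-sided (serosa only): sutures are placed on non-incised tissue.

### Candidate extraction and equidistant refinement

Maximizing J has no useful global optimum; the approximate local scheme
first discards pixels below a threshold (default 0.5) and keeps each pixel
strictly greater than all of its existing 8 neighbors. Strictness means
exact plateaus yield no candidate — acceptable on real imagery, and the
phantom's curved cut edge guarantees genuine maxima there.

The equidistance constraint is enforced greedily (a declared design choice;
no canonical algorithm exists): candidates are projected onto the
skeletonized cut edge, parameterized by arc length (longest geodesic
through the skeleton, Dijkstra on the 8-connected pixel graph); the plan
seeds at the best-scoring candidate and extends in both directions, each
step accepting the best-scoring candidate whose arc gap to the last
accepted point lies within 1.5τ × (1 ± 0.25), stopping when none qualifies.
Ties break to the smaller arc position, making the output deterministic.

## Synthetic phantom

No imaging data accompanies the method, so a seeded phantom supplies the
study conditions: 256×256 px at 0.05 mm/px (20 px/mm, resolving a 1 mm
thickness; the original optics' pixel pitch is unknown, scale bars only), a
tissue block with a mesentery band, a gently sinusoidal cut edge (amplitude
6 px, period 96 px) separating exposed inner lumen from serosa, a thin
serosa strip distally, and two radius-3 px vessels in the serosa, one
crossing the suture band. Class spectra at (470, 600, 770) nm: background
(0.02, 0.02, 0.02), inner lumen (0.45, 0.55, 0.60), thick serosa
(0.55, 0.60, 0.70), thin serosa (0.40, 0.50, 0.65), mesentery
(0.60, 0.40, 0.35) — distinct spectral angles so both classifiers are
exercised non-trivially. Vessels multiply the underlying reflectance by
(0.3, 0.6, 0.85), monotone in wavelength so vessels are darkest at 470 nm.
Additive Gaussian noise, default sd 0.01, clipped to [0, 1]; shot noise is
deliberately omitted. The sinusoidal edge matters: a perfectly straight
edge makes the bite-depth ridge an exact plateau, and the strict
local-maximum rule would return no candidates.

What the phantom does **not** emulate: specular glare (cross-polarization
is represented only by its absence), depth-dependent scattering and
penetration, spatial texture within a tissue class, vessel branching and
caliber variation, and deformation of real bowel. Tests passing on the
phantom therefore validate the pipeline's logic and numerics, not its
performance on real tissue.

## Numerical choices and edge cases

- All physical parameters are in mm and convert to pixels only at the map
  boundary via the pixel pitch; coordinates are 0-based (row, col) with
  half-open rectangles.
- Hessian discretization: Gaussian smoothing (`mode="nearest"`) followed by
  3-point second differences on an edge-padded image; eigenvalues by the
  closed 2×2 form. Verified against a per-pixel `eigvalsh` oracle to 1e-12
  and rotation-equivariant to 1e-6 in the interior.
- Degenerate inputs are legal where physically meaningful: an all-zero
  vesselness gives V ≡ 1; an all-thick label map gives T ≡ 1; an empty
  candidate list gives an empty plan. An empty cut edge or a missing lumen
  class is an error.
- Angle computations clip cosines into [−1, 1]; arccos conditioning limits
  near-parallel spectra to ~1e-8 absolute angle accuracy.
- δ < 0.5 mm and δ ≥ 1.5τ (σ ≤ 0) are rejected at parameter construction,
  so an infeasible clearance aborts before any map is built.

## Known limitations

- At sensor noise sd 0.01 the per-pixel SAM partition of the phantom is
  ~98.5% correct, not higher: the inner-lumen and thick-serosa default
  spectra are only 0.044 rad apart while the noise induces ~0.011 rad of
  angular jitter, so ~1.5% of those pixels swap. All other class pairs are
  ≥ 0.09 rad apart and classify cleanly. The smoothing in T suppresses the
  scattered errors, and end-to-end recommendations are unaffected.
- The quadratic discriminant assumes per-class Gaussian spectra; the serosa
  class is deliberately bimodal (thick + thin training fields) and relies
  on the broad fitted covariance absorbing both modes.
- Arc-length parameterization uses the longest geodesic of the edge
  skeleton; a branching or fragmented cut edge keeps only its largest
  connected piece.
- Thickness is binary (thick vs thin); no continuous mm regression and no
  perfusion analysis.
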