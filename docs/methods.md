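# Methods

## Force transduction and the constitutive model

The device suspends a planar tissue strip between two cylindrical
elastomeric cantilever posts. The posts are the force transducers: for a
point load at the free tip of a cantilevered circular beam,
`k = 3EI/L³` with `I = πd⁴/64`, so the tissue tension is `F = k·v` from the
measured tip deflection `v`. The tissue is mounted at the post tips, so tip
loading is the assumed load height; an effective length can be substituted
in `PostGeometry` if the mounting sits lower. With the standard posts
(d = 2 mm, L = 6 mm, E = 1 MPa elastomer) k ≈ 10.91 N/m, which resolves
micro- to milli-newton forces from micron-scale deflections.

Stress is nominal (first Piola): force over the *undeformed* cross-section,
because thickness under load is not measured. Stretch is `λ = s/s₀` from
tip-to-tip separation; separations below rest are flagged as compression
and excluded from tensile analysis.

The constitutive model is the one-dimensional exponential Fung law
`σ = α(e^{βε} − 1)` with engineering strain `ε = λ − 1`. The strain measure
inside the exponent is a convention, not a measurement; Green strain
`(λ² − 1)/2` is available via `fit_fung(..., strain_measure="green")`, and
all comparative statistics use a single convention so group conclusions are
convention-invariant. Fitting is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) initialized from
the data itself: β₀ is the log-stress slope over the upper-strain third of
the curve and α₀ matches the peak stress; on non-convergence the fit
restarts from geometrically perturbed β₀ (×½, ×2, ×¼, ×4, ×8). Constant or
monotonically decreasing stress records are rejected as data-quality
errors rather than fit failures.

The effective modulus is the tangent `dσ/dε = αβe^{βε_ref}` at a reference
strain, default ε_ref = 0.3 (the midpoint of the λ ≤ 1.6 protocol). The
published provenance of this scalar is a citation rather than a printed
formula, so the tangent-modulus convention is documented here as this
package's definition; any fixed ε_ref preserves group orderings.

## Two-post equilibrium simulation

At each grip displacement `d` (each post carried outward by `d`), the posts
deflect inward by `v` until tissue tension balances both cantilevers:

    k·v = F_tissue(λ),   λ = (s₀ + 2d − 2v) / L₀.

The residual `k·v − F(λ(v))` is strictly increasing in `v` on the physical
bracket [0, d] (the left term grows, the right shrinks), so the root is
unique; it is found by Brent bracketing at near-machine tolerance and
polished with Newton steps, holding the force balance below 10⁻⁹ N at every
step. Tension is zero for λ < 1 (no compressive load path through a thin
strip). An impossible balance (e.g. a pre-tensioned tissue shorter than the
rest separation whose tension exceeds what the posts can supply anywhere in
the bracket) raises an equilibrium-failure error.

## Cell circularity and tracking

Circularity is CI = 4π·Area/Perimeter² on the outline polygon: area by the
shoelace formula, perimeter by summed edge lengths; 1 for a circle, π/4 for
a square, →0 for slivers. Outlines from rasters are marching-squares
contours of each labeled region, smoothed by a small circular Gaussian
(σ = 2 samples) along the contour: raw marching-squares vertices carry
staircase noise that biases the perimeter high and hence CI low by a few
percent; after smoothing a rasterized circle of typical cell size measures
CI ≥ 0.996. External tracings are ingested as vertex CSVs and used as-is.

Segmentation of synthetic rasters is deliberately simple (global Otsu,
connected components, area filter); overlapping cells merge into one
component and are not split. Tracking across stretch levels is
nearest-centroid assignment, greedy by distance with ties broken by lowest
label, injective per frame pair, under a gating radius (default 40 px);
only chains spanning every frame enter the trajectory. The headline slope
is ordinary least squares of the per-frame *mean* CI on λ (one curve per
test); the per-cell CI table is retained in the output for pooled or
per-cell analyses.

Fiducial markers are tracked by normalized cross-correlation of the
frame-0 template inside a search window around the previous position, with
3-point parabolic subpixel refinement per axis. A peak correlation below
the floor (default 0.5), or a window leaving the raster, marks the track
lost from that frame onward; lost tracks are truncated, never
interpolated. Local stretch is the marker-pair separation projected on the
loading axis divided by its frame-0 projection, averaged over pairs; pairs
with initial projected separation under 2 px are rejected as unstable.

## Fiber alignment index

The image is mean-subtracted, apodized with a separable Hann window, and
Fourier transformed. Power is accumulated over a radial annulus (default
0.1–0.8 of Nyquist; DC and corner frequencies excluded) into 1° angular
bins covering [0°, 180°), with spectral angles rotated +90° so bins index
fiber orientation rather than stripe normals. Because the Cartesian FFT
grid is anisotropic in angle (exact-axis and diagonal samples pile into
single bins), each bin reports the mean power per spectral sample — an
angular power *density* — rather than the raw sum; a flat spectrum is then
exactly flat. FAI(axis, w) sums bins whose center lies within axial
distance w of the axis and divides by total power, so a flat spectrum gives
exactly 20/180 at the default ±10° window and FAI(axis, 90°) = 1 for any
spectrum. The ±10° reading of "within ten degrees" (a 20° window) is the
default; ±5° is a parameter away.

FAI is a normalized fraction by construction. Published alignment indices
on other scales are not directly comparable; only signs and orderings of
FAI–stretch slopes are treated as portable.

## Synthetic data: what it emulates, what it does not

All generators are deterministic per seed (identical spec + seed gives
bit-identical output) and every stage's input can be generated with known
ground truth.

**Fiber scenes.** Fiber axis angles follow a wrapped axial von-Mises-type
law: θ = φ/2 with φ ~ von Mises(0, κ), isotropic at κ = 0 and concentrated
on the loading axis as κ → ∞. The paper-level observable this emulates is
the un-crimping and re-orientation of matrix fibers with stretch. Crimp is
a sinusoidal perturbation perpendicular to each fiber axis (default
amplitude 1.5 px, wavelength 64 px — a crimp angle of ~8°, gentle enough
that a strongly concentrated population at κ = 50 keeps an alignment index
above 0.6). Stretch acts as the affine map (x, y) → (λx, λ^{−ν}y) about the
frame center; the transverse exponent ν (default 0.5) mimics the necking of
a thin strip and is configurable because in-plane transverse contraction is
not measured. Under this map every off-axis orientation rotates toward the
axis (tan θ′ = λ^{−(1+ν)} tan θ) and crimp amplitude shrinks, so FAI rises
with stretch by construction. Polylines are rendered by bilinear splatting
and isotropic Gaussian blur (fiber width); `analytic_fai` computes the
length-weighted angle fraction of the same polylines and serves as the
generator-side oracle for the FFT estimate. Single-scene FAI fluctuates
with sd ≈ 0.03 at the default 150 fibers (finite-population sampling);
expectations are therefore checked as means over ≥ 20–25 seeds.

**Cell scenes.** Cells are ellipses whose exact (continuous) circularity
equals `base_ci + ci_slope·(λ − 1)` plus per-cell, per-frame Gaussian
noise; the axis ratio for a target CI is solved from the exact elliptic
perimeter (complete elliptic integral). Centroids sit on a jittered grid
sized so the population stays disjoint and in-frame up to λ = 1.6 and are
advected by the same affine map; labels are stable across stretch. The
generator controls the *statistic* (CI trend), not cell mechanics: it does
not emulate cytoskeletal remodeling, cell–cell contact, or out-of-plane
shape.

**Mechanical records.** Stress–stretch records are the Fung law plus
additive Gaussian noise at evenly spaced stretches on [1, 1.6], or full
two-post simulations as above.

**Histology slides.** Constituents are painted in each stain's canonical
colors inside an elliptical leaflet mask, with pixel assignment following
level sets of a smooth random field (blob-like compartments, realized
fractions exact to one pixel), plus optional Gaussian color noise. Movat:
collagen yellow via the CMYK yellow channel, GAGs blue via B − R;
trichrome: connective tissue via B − R; VVG: elastin via inverted
luminance. These channel rules live in an editable `StainProfile` (YAML)
because published workflows name the channel splitter but not the
per-constituent rules. A channel whose robust range (0.5th–99.5th
percentile) is below 0.15 is treated as signal-free rather than
Otsu-thresholded, so blank slides and absent constituents yield empty
masks; the corollary is that an absent constituent under heavy color noise
can defeat the guard. Synthetic slides have sharp color classes; real
stains vary in hue, intensity, and co-localization, so passing recovery
tests here demonstrates the bookkeeping (channel → threshold → leaflet
normalization → ratio), not robustness to staining variability.

## Statistics

Group comparisons follow the study design: one-way ANOVA with Tukey–Kramer
all-pairs post-hoc (unequal group sizes allowed) summarized as a compact
letter display, and two-sided pooled-variance Student's t-tests for
two-condition contrasts (Welch by flag). The letter display uses the
insert-and-absorb algorithm with groups processed in descending mean (ties
by label), which makes letters deterministic and guarantees that two
groups share a letter iff their adjusted p ≥ α. An optional natural-log
transform (off by default) is available for variance stabilization. Zero
pooled variance is handled explicitly: equal means give t = 0, p = 1;
unequal means set a degenerate-variance flag instead of a spurious
statistic. Trend fitting everywhere is ordinary least squares; a constant
response has slope 0 and r² defined as 1 (the fit is exact).

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-(stage, group, specimen) seeds from the run seed via
`numpy.random.SeedSequence`, and a run's outputs are a pure function of the
config hash and seed (re-runs are byte-identical). Default analysis sizes —
256 px fiber scenes with 150 fibers, 768 px cell scenes with 50 cells,
256–512 px slides, 6 specimens per group, 7 stretch levels — are chosen so
that sampling error sits well inside the tolerances quoted above while a
full cohort runs in seconds on one core.

## Known limitations

- Uniaxial, isotropic, elastic-only constitutive description: no biaxial
  anisotropy, viscoelasticity, or failure.
- Segmentation does not split touching cells; circularity of merged
  components is reported as one object.
- Fiducial templates are taken from frame 0; large accumulated deformation
  degrades correlation and truncates tracks rather than re-anchoring.
- FAI absolute values depend on the annulus and window conventions fixed
  here; cross-study comparisons should use signs and orderings.
- Histology rules assume stains close to their canonical colors; no
  stain-vector deconvolution is attempted.
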