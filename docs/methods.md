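# Methods

## The generation model

The generator treats downscaling as a regularized inverse problem. Let α
be a vector of i.i.d. draws from U(min, max) over the n = n_rows·n_cols
cells of the subgrid, and let B be the first-difference matrix over
cardinal neighbour pairs (one +1/−1 row per horizontal pair in row-major
order, then per vertical pair; free boundaries, no wraparound). The
smoothed draw is

    s = (I + γ BᵀB)⁻¹ α

and the delivered field is the affine rescaling

    α′ = √(σ²/Ψ) · (s − μ_α) + μ,    Ψ = var(s),  μ_α = mean(s),

which enforces the target sample mean μ and population variance σ²
(divisor N throughout) to machine precision on every single realization.
Ψ is the per-realization empirical variance, not an ensemble expectation:
this makes single-field statistics exactly reproducible and is what the
normalization term is defined as. Because B annihilates constants, S is
symmetric positive definite with unit row sums; at γ = 0 it is the
identity (the field is an affine rescaling of pure noise), and as γ → ∞
the field approaches a constant at μ (guarded: a draw smoothed to numeric
constancy raises rather than dividing by a rounding-noise variance).

**Convention for γ.** The smoothness multiplier enters the operator
*linearly* (γ BᵀB). Under this convention the ensemble variogram
statistics of the generator reproduce the published reference table for
this parameterization (mean fitted ranges ≈ 10.4, 17.7, 52.5, 144 m at
γ = 0.1, 1, 10, 100 on a 62×62 grid of 4 m pixels) and the calibrated
multiplier 10^0.85 corresponds to a ~44–48 m range. A squared-multiplier
convention (γ²BᵀB) is algebraically equivalent up to reparameterization
but does not line up with those reference values of γ. First differences
are taken at unit lattice spacing; the pixel size (default 4 m, the
characteristic tundra patch scale) only converts lags and ranges to
metres.

**Implementation.** The system I + γ BᵀB is sparse, banded and SPD; it is
factorized once (sparse LU) and cached, so an ensemble costs one
triangular solve per field. A dense inverse is available for grids up to
10⁴ cells for inspection and oracle testing. The default grid is 62×62
(248 m, the nearest whole-pixel cover of a nominal 250 m coarse cell;
the domain size is immaterial to the statistics). The U(0, 1) draw bounds
span plausible terrestrial NDVI; generated values are *not* clipped to
[0, 1] — clipping would break the exact normalization, and at σ = 0.095
around 0.54 excursions are rare and harmless downstream.

## Spatial statistics

*Semivariogram.* Classical isotropic Matheron estimator,
γ̂(h) = Σ(z_i−z_j)²/(2N(h)), computed by lattice-offset enumeration (exact
equivalent of the all-pairs sum, verified against a brute-force oracle).
Lags are binned one pixel wide with nominal centres at k·pixel_size; the
reported lag is the pair-weighted mean separation in the bin. Default
maximum lag: half the longer grid side.

*Spherical fit.* γ(h) = c₀ + c·(1.5h/a − 0.5(h/a)³) below the range a,
c₀ + c above. Two modes:

- **free** (default): 3-parameter weighted nonlinear least squares,
  non-negative bounds, exact (residual < 1e−8) on noise-free model curves.
  Initial values: nugget = first-bin γ̂, partial sill = plateau − nugget,
  range = first lag reaching 95% of the plateau.
- **sill-constrained**: c₀ + c pinned to a known total sill, fitting only
  (c₀, a). Ensemble statistics of generated fields use this mode with the
  field's population variance — which the generator enforces exactly — and
  Cressie-type weights (σ_bin ∝ h/√N). The constraint is what keeps the
  range identifiable when the variogram has not plateaued inside the
  maximum lag (strong smoothing): a free pair-count-weighted fit then
  chases ranges an order of magnitude past the domain, while the
  constrained fit recovers the reference statistics including their
  spread. Fitted ranges may exceed the maximum lag (bounded at 20× to
  declare anything beyond unidentifiable rather than report it).

Flat (zero-structure) variograms either raise or return a flagged fit,
caller's choice.

*Radial spectrum.* Mean-removed 2D DFT power |F|²/N², averaged in annuli
one fundamental frequency wide; summed over all nonzero frequencies it
equals the field variance exactly (Parseval), which the tests check by
direct summation. No taper is applied by default.

*Calibration.* For each point of a log₁₀γ grid, an ensemble of fields is
generated and the mean and sd of fitted range recorded (unidentifiable
fits dropped, with a warning past 50% loss). A 5-parameter Richards curve
R(x) = A + (K−A)/(1+e^{−g(x−m)})^{1/ν} is fitted to mean range vs
x = log₁₀γ, falling back to ν = 1 if ill-conditioned, and inverted in
closed form to map a target range to γ. The target must lie strictly
between the fitted asymptotes; the error message reports the achievable
interval.

## Flux model

LAI = 0.00067·exp(9.237·NDVI) (tundra transfer function; defined for all
reals, so unclipped NDVI passes through). PLIRTLE gives the canopy GPP
rate (P_max/k)·ln[(P_max + E₀·PPFD)/(P_max + E₀·PPFD·e^{−k·LAI})] with
pan-arctic defaults P_max = 15.831 µmol m⁻² leaf s⁻¹, E₀ = 0.036
µmol CO₂/µmol photons, k = 0.5. The model's leading minus sign in the
micrometeorological convention (uptake negative) is dropped: the package
returns uptake magnitudes. Seasonal integration is a left-Riemann sum at
the forcing timestep (default 1800 s, the half-hourly flux convention),
with LAI static over the season (no phenology), converted at
12.011×10⁻⁶ g C per µmol CO₂ and the pixel area (16 m² at 4 m pixels);
landscape totals are reported in kg C. Because the chain is convex in
NDVI over the relevant range, `landscape_vs_mean_gpp` exposes both the
per-pixel total and the total from the field-mean NDVI; their gap is the
aggregation bias that motivates downscaling.

## Edge effects

Edges (ecotones) between vegetation patches carry ~20–40% less GPP per
unit LAI than patch centres and occupy roughly 30% of the tundra
landscape; the package collapses this to a single factor 0.7 applied to
edge pixels. Four placement heuristics:

1. pixels with NDVI nearest the field mean, up to ⌊0.3N⌋;
2. the ⌊0.3N⌋ pixels of steepest NDVI gradient (central differences,
   one-sided at borders, per metre);
3. the ⌊0.3N⌋ pixels where the gradient magnitude of the slope field is
   steepest (chosen over a Laplacian as the literal "rate of change of
   the slope"; the alternatives rank different pixels highest);
4. threshold NDVI at 0.5 (clamped to [0, 1] first, 0.5 rounding up, for
   classification only) and mark every pixel with a 4-connected neighbour
   of the opposite class — both sides of the boundary are edge and the
   fraction is emergent rather than quota-driven. At γ = 10^0.85 it
   averages ≈ 39% over ensembles, i.e. "about 30%" only loosely; the
   both-sides adjacency choice roughly doubles a one-sided count.

Quota ties are broken by stable row-major order, so masks are
deterministic. On a uniform landscape a random 30% mask at factor 0.7
cuts the total by exactly 9%; gradient methods (2, 3) cut more than
methods 1 and 4 on smoothed ensembles because they land on productive
pixels.

## Synthetic forcing

The PPFD series stands in for unavailable station meteorology: each day a
truncated half-sine, amplitude 800 µmol m⁻² s⁻¹ over 20 h of daylight
centred at solar noon, for 61 days — a plausible subarctic June–July, and
explicitly *not* any particular year's record, so absolute seasonal GPP
totals are internally consistent rather than comparable to station-driven
values. Optional Gaussian noise is clipped at zero. A noise-free day
integrates to peak·daylight·2/π within 0.5% at half-hourly resolution.

## What the synthetic tests do and do not show

The generator and forcing emulate the *statistics* of a tundra scene: a
single-mode spatial correlation structure, exact first and second
moments, and a smooth diel light cycle. Real NDVI maps carry multiple
modes of spatial variability, anisotropy, skewness and water bodies;
real forcing has weather. Passing tests therefore demonstrate the
correctness and internal consistency of the method and its statistics,
not agreement with any particular observed landscape. Ensemble sizes in
tests (10–100 fields, grids 16×16 to 62×62) were chosen to give stable
statistics at interactive runtimes.

## Known limitations

- Single γ per field: multi-scale (multi-γ composite) landscapes are out
  of scope, as are non-uniform priors and anisotropic or higher-order
  difference penalties.
- Spherical variograms only; no kriging; no robust estimators.
- Raster I/O is plain-text (ESRI ASCII, headerless CSV) with a bare pixel
  size — no CRS or projection handling.
- No ecosystem respiration or NEE; PLIRTLE parameters are fixed, not
  refit.
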