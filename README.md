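# tikscape

Tikhonov-regularized neutral landscapes for subgrid NDVI, LAI and GPP
estimation.

## The problem

A coarse remote-sensing pixel (say, a 250 m MODIS cell over tundra) reports
only summary statistics of the surface beneath it — typically a mean NDVI,
sometimes a variance. Downscaling that single value to a plausible
fine-scale (4 m) surface is ill-posed: infinitely many subgrid fields share
the same mean. Yet the choice matters, because fluxes like gross primary
productivity (GPP) depend nonlinearly on NDVI, so the GPP of the mean pixel
is not the mean of the subpixel GPP (Jensen's inequality).

`tikscape` regularizes the problem with a smoothness prior. Starting from a
uniform random draw α over the subgrid, it applies the operator

    S = (I + γ BᵀB)⁻¹

where B takes first differences between cardinal neighbour pixels and γ is
a Lagrange multiplier weighting the assumption that adjacent pixels are
similar. The smoothed draw is then rescaled,

    α′ = √(σ² / Ψ) · (Sα − mean(Sα)) + μ,

with Ψ the empirical variance of Sα, so that every realization has
*exactly* the target mean μ and population variance σ². γ interpolates
between pure noise (γ = 0) and a uniform field at μ (γ → ∞), and maps
monotonically onto the range of the field's semivariogram — so a known or
assumed correlation length can be dialed in by calibrating γ.

The package provides, for landscape ecologists and flux modellers:

- **field_generator** — the difference operator, cached smoother, and
  exactly-normalized random field generation;
- **spatial_stats** — Matheron semivariograms, spherical-model fits,
  radially averaged power spectra, and γ↔range calibration through a
  generalized logistic (Richards) fit;
- **flux_model** — the tundra NDVI→LAI transfer
  `LAI = 0.00067·exp(9.237·NDVI)` and the PLIRTLE aggregated canopy model
  `GPP = (P_max/k)·ln[(P_max + E₀·PPFD)/(P_max + E₀·PPFD·e^(−k·LAI))]`
  with pan-arctic parameters (P_max = 15.831 µmol m⁻² s⁻¹, E₀ = 0.036,
  k = 0.5), integrated to seasonal per-pixel and landscape totals;
- **edge_effects** — four heuristics for locating vegetation-patch edges
  (ecotones) and the ~30% GPP-per-LAI edge reduction (factor 0.7);
- **forcing_synth** — a synthetic half-sine subarctic PPFD forcing series;
- a **CLI** (`tikscape`) and a YAML-driven end-to-end **pipeline**.

## Worked example

```python
import tikscape as tk

# a 62x62 grid of 4 m pixels with the observed tundra statistics,
# at the range-calibrated multiplier 10^0.85
spec = tk.FieldSpec(62, 62, pixel_size=4.0, mu_target=0.54,
                    sigma2_target=0.009, gamma=10**0.85, seed=42)
ndvi, _ = tk.generate_field(spec)
print(ndvi.mean(), ndvi.var())          # 0.54, 0.009  (exact by construction)

sv = tk.empirical_semivariogram(ndvi)
fit = tk.fit_spherical(sv, total_sill=ndvi.var())
print(fit.range_m)                       # 36.4 m for this seed

forcing = tk.synthesize_ppfd()           # 61 synthetic subarctic days
gpp = tk.integrate_gpp(ndvi, forcing)
print(gpp.landscape_total)               # 3513.4 kg C / season
print(gpp.mean_flux_density(61))         # 0.936 g C m^-2 day^-1

mask = tk.classify_edges(ndvi, method=2)          # steepest-gradient 30%
reduced = tk.apply_edge_reduction(gpp, mask, 0.7)
print(reduced.landscape_total)           # 3208.3 kg C  (-8.7%)
```

The landscape total (3513 kg C here) is the sum of per-pixel seasonal GPP;
computing GPP from the field's *mean* NDVI instead gives 2467 kg C for the
same field — a 30% aggregation bias, which is the motivation for
downscaling at all. The gradient-based edge methods (2, 3) cut more GPP
(8.7%, 9.7% for this seed) than the near-mean and class-boundary methods
(1, 4: 6.5%, 6.7%), because they concentrate the reduction on productive
pixels.

The same workflow runs from the shell:

```sh
tikscape generate --rows 62 --cols 62 --gamma 7.08 --seed 42 --out-dir out
tikscape variogram --in out/ndvi_0000.asc --out out/sv.csv
tikscape calibrate --target-range 47.7 --n-iter 100 --seed 1
tikscape pipeline --config config.yaml
```

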