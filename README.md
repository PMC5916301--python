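# trapstat

Occupancy and spatially explicit capture–recapture (SCR) estimation for
camera-trap surveys of elusive carnivores, built around the analysis design
of a nationwide clouded leopard (*Neofelis nebulosa*) survey in Bhutan:
sparse detections (~13% of 849 stations), strong spatial autocorrelation,
and only 19 identified individuals for density estimation.

The package implements the full inference chain as a reusable library
(`src/trapstat`) with numbered analysis drivers (`analysis/`), so every
stage is testable against simulated data with known truth — the original
survey's coordinates are not public.

## What it computes

**Site use under imperfect detection.** Detection histories `y_ik` (station
*i*, 15-day occasion *k*) follow the single-season occupancy model

    z_i ~ Bernoulli(ψ_i),   y_ik | z_i ~ Bernoulli(z_i p_ik),

with ψ modelled on site covariates (elevation, forest cover, distance to
river) and p on survey covariates (survey area, per-occasion effort).
Maximum-likelihood fits use logit links with AICc ranking, Akaike-weight
model averaging and the parametric-bootstrap (MacKenzie–Bailey) ĉ test.

**Restricted spatial regression (RSR).** The Bayesian model adds a spatial
random effect on the probit scale,

    probit(ψ_i) = x_i'β + η_i,   η = Kα,   α | τ ~ N(0, (τ K'QK)⁻¹),
    τ ~ Gamma(0.5, 0.0005),

where K holds the top-q eigenvectors (Moran cut q = 10% of stations) of the
residual-projected Moran operator built from the 8.7-km neighbourhood graph
and Q is the ICAR precision. The effect is orthogonal to the fixed effects
by construction, so spatial clustering cannot masquerade as covariate
signal. A Gibbs sampler with truncated-normal augmentation handles both
probit layers exactly; spatial and nonspatial fits are compared by the
posterior predictive loss criterion (PPLC).

**Density by SCR.** Each animal has a latent activity centre s on a habitat
mask (25-km buffer, 0.25-km² pixels); encounters decline with distance as
the half-normal g₀·exp(−d²/2σ²). Density is estimated both by maximizing
the integrated Poisson point-process likelihood and by Bayesian data
augmentation (M = n + 10n all-zero histories, Metropolis-within-Gibbs with
a joint σ–centre rescaling move), with Geweke diagnostics, a Freeman–Tukey
Bayesian p-value and HPD intervals.

## Worked example

```python
import trapstat as ts
from trapstat.synthetic import fixture_daily

stations, daily = fixture_daily()          # bundled synthetic survey
occ = ts.collapse_occasions(daily, 15)     # 849 x 8 occasion matrix
print(round(ts.naive_occupancy(occ), 3))   # 0.134  (114 of 849 stations)

covs, std = ts.zscore(stations, ["elevation", "forest", "dist_river"])
fit = ts.fit_occupancy(
    ts.OccupancyModelSpec(psi_terms=["elevation", "forest", "dist_river"],
                          p_terms=["effort"]),
    occ, covs, seed=1)
print(round(fit.aicc, 2))                  # AICc of the fitted model
```

The numbered drivers reproduce the full analysis on simulated data and
print their findings; e.g. `python analysis/04_scr_density.py` simulates a
population at density 0.40/100 km² with σ = 8,698 m and prints

```
ML:    D = 0.546/100 km^2 (SE 0.180, CI 0.287-1.041), g0 = 0.0022, sigma = 8683 m
Bayes: D = 0.588/100 km^2 (SD 0.199, HPDI 0.279-0.947), lambda0 = 0.0022, sigma = 9251 m
```

— the two estimators agree within each other's intervals and both recover
the generating σ, the pattern the method is designed to deliver at this
sparsity (here 14 detected individuals, 1–5 captures each). `analysis/03`
prints the spatial-vs-nonspatial comparison: on clustered detections the
RSR model yields a lower, better-calibrated landscape mean ψ.

## Layout

- `src/trapstat/` — library: `synthetic` (generators), `detections`
  (histories, occasions, covariates), `occupancy_ml`, `occupancy_rsr`,
  `scr`, `diagnostics`, `io`, `cli`
- `analysis/` — numbered drivers: simulate → ML occupancy → RSR → SCR
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — model details, defaults, numerical choices

A thin `trapstat` command-line interface (`simulate`, `prep`, `scr-ml`,
`scr-bayes`, `pipeline`) wraps the same functions for shell use.
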