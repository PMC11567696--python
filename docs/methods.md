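# Methods

Scope: the model equations, unit conventions, numerical choices and
open design decisions behind `diffrate`. SI everywhere internally;
bench units (nM, nm, nm², nm³, µs) only at the I/O boundary.

## Model family

All rates are per-target pseudo-first-order rates `r` (1/s) at probe
number density `C` (1/m³) and relative diffusion coefficient `D`
(m²/s). The discrete models share one scaffold: probes are on average
`L = C^(-1/3)` apart; a probe traverses `L` in the reshuffle time
`t_c = L²/(2D)` (so `√(2 D t_c) = L` exactly, a tested identity);
each reshuffle gives the target one nearest-neighbour attempt that
succeeds with effective fraction `a`; an empirical coarse-graining
factor 2 converts attempts to the rate `r = 2a/t_c = 4 a D C^(2/3)`.

The fraction `a` is either fitted directly (`discrete_0d`), taken as
the area fraction of the first-neighbour shell
`a = 4A/(4πL²)` → `r = (4/π) A D C^(4/3)` (`discrete_2d`), or as the
volume fraction `a = C V₀` → `r = 4 V₀ D C^(5/3)` (`discrete_3d`).
Continuum baselines: Smoluchowski's steady-state flux `r = 4π r₀ C D`;
the Langmuir–Schaefer transient flux `r = 2AC√(D/(πt))`, whose value at
`t = t_c` is the time-free `discrete_2d_tc` law `r = 2√(2/π) A D C^(4/3)`;
and the deliberately naive `r = C V₀ / t` kept as a cautionary example
(dimensionally fine, physically wrong — it ignores `D`).

Every model carries a dimensional signature (exact `Fraction`
exponents); an audit test checks each law reduces to SI units of 1/s,
and a fitted log-log slope test checks each implementation actually
scales with its declared concentration exponent.

### Coefficient conventions (open decisions)

* **`discrete_2d` coefficient is `4/π`, not `4π`.** Substituting the
  area fraction into the 0D law gives
  `2·(4A/(4πL²))/t_c = (4/π)·A·D·C^(4/3)`. The published presentation
  of this law is typographically ambiguous (a flattened fraction);
  the composition identity `discrete_2d ≡ area-fraction ∘ discrete_0d`
  is enforced at 1e-12, which pins the coefficient.
* **`discrete_2d_tc` coefficient is `2√(2/π)`.** Evaluating
  Langmuir–Schaefer at `t_c` gives `2AC√(D/(π t_c)) = 2√(2/π)·A·D·C^(4/3)`;
  the ratio to `discrete_2d` is `√(π/2) ≈ 1.2533` (a remark in the
  source material suggests `√2`; the algebra does not support it, and
  we follow the algebra — tested).
* **Cylinder-radius conventions.** For a cylindrical target of length
  `ℓ` (default 1 µm), areas and volumes convert to equivalent radii as
  `r₀ = A/ℓ` and `r₀ = √(V₀/ℓ)`. These are the conventions that
  reproduce the published derived columns; they omit factors of 2 and π
  a literal side-area/volume reading would add.
* **Reshuffle-time column discrepancy.** The published derived table's
  `t_c` column is a factor ≈10 smaller than `t_c = L²/(2D)` evaluated
  with the published `D = 2.9e-10 m²/s` (computed 2.4 ms vs printed
  240 µs at 1 nM), while all other columns are consistent with the
  definitions. We follow the definitions, report the computed column,
  annotate the ×10 ratio in the `table2` output, and take no
  reproduction target from that column.

## Embedded reference dataset

Six (concentration, rate) pairs — (1, 0.63), (3, 1.49), (5, 2.85),
(10, 4), (50, 10), (100, 15) in (nM, 1/s) — with `D = 2.9e-10 m²/s`
and target length 1 µm, plus the published derived cells used as
regression oracles at 10% relative (2-significant-figure roundings).
A SHA-256 checksum over the canonical JSON serialization of the
fixture is frozen in `datasets.FROZEN_FIXTURE_SHA256` and tested, so
silent edits to the reference numbers fail loudly. Maximum observed
cell deviation: 5.3%; fitted order 0.672 ± 0.045.

## Fitting

* **Apparent order** (`PowerLawModel` / `fit_power_law`): OLS of
  `log r` on `log C` via statsmodels; returns slope, its standard
  error, `R²`, and an optional seeded bootstrap (Philox-resampled
  rows). All-equal-rate input degenerates to slope 0 with infinite
  standard error rather than an exception.
* **Constant-geometry fits** (`ConstantGeometryModel`): for each
  time-independent model, the single geometry parameter minimizing the
  sum of squared log-residuals has the closed form "geometric mean of
  per-point inversions"; no iterative optimizer is used. `compare_models`
  ranks models by residual norm with registry order as the
  deterministic tiebreak.
* **Synthetic generator**: `r_i = model(C_i)·exp(ε_i)`,
  `ε_i ~ N(0, σ_log)` — multiplicative lognormal noise, the natural
  error model across decades of concentration. Restricted to
  time-independent models (a synthetic spec carries no evaluation
  time). Seeded with Philox; bitwise reproducible.

## Brownian-dynamics Monte Carlo

Design choices (made a priori from bias/variance estimates, then
spot-checked; sizes were *not* tuned against test outcomes):

* **RNG**: numpy `Philox` keyed by the config seed — counter-based,
  platform-stable, bitwise reproducible; every stochastic function
  takes an explicit seed.
* **Stepping**: independent per-axis Gaussian steps of variance
  `2DΔt`. Absorption is endpoint-crossing detection, which misses
  intra-step excursions; the resulting negative bias scales with the
  step length, so the engine refuses `√(2DΔt) > r₀/3` with actionable
  guidance (`Δt ≤ r₀²/(18D)`), and a step-halving test bounds the
  residual bias. No Green's-function bridge correction is applied.
* **Absorbing sphere**: periodic cubic box, target at the origin,
  minimum-image distances; side `(n/C)^(1/3)` fixes the concentration
  exactly. Absorbed walkers are re-injected uniformly outside the
  sphere so `C` stays constant; the steady-state rate is counted over
  the second half of the run with a Poisson standard error. The
  periodic sink array raises the rate by a few percent at the default
  box (≈80 r₀) relative to the isolated-sphere closed form `4π r₀ D C`;
  validation runs at 10⁴ walkers land within 3 standard errors.
* **Capture from the neighbour distance**: trajectories start at
  sphere-contact scale, so the endpoint-miss bias is largest here;
  the default step is `r₀²/(288D)` (σ = r₀/12) and the validation
  tests use `r₀²/(1152D)` (σ = r₀/24), at which the estimate is
  statistically indistinguishable from
  `(r₀/L)·erfc((L−r₀)/√(4Dt))` at n = 8000.
* **1D first passage**: default step σ = L/50; validated against
  `erfc(L/√(4Dt))` at five horizons spanning 0.5–8× `L²/(4D)`.
* **Coarse-graining factor**: renewal protocol — a counter fires at
  first exit from a cell of half-width `L` centred on the last firing
  position; the analytic mean exit time is exactly `t_c = L²/(2D)`, so
  observed transitions per `total_time/t_c` have analytic value 1. The
  estimator enforces scale separation (`Δt ≤ t_c/20`,
  `total_time ≥ 20 t_c`); at `Δt = t_c/400` the discretization bias on
  the exit time is ≲3% (it is ≈ +16% at `t_c/100` — first-exit times
  are discretization-sensitive). Under this convention the empirical
  factor ≈2 used in the rate laws is *not* reproduced (measured ratio
  ≈0.93–0.94, CI excluding 2): the factor 2 belongs to a different,
  sub-`t_c` counting convention and is surfaced as an exploratory
  output, not asserted.
* **Mirror-plane mode**: reflecting substrate at z = 0 with the target
  hemisphere on it — the surface-immobilized-target configuration. It
  runs, is reproducible and is exercised by tests, but no quantitative
  factor (such as the reported ×2 surface enhancement) is asserted;
  it is exploratory.

## Acceptance surface

`scripts/acceptance.py --seed <int> --out <path>` recomputes the
headline numbers from the embedded rates at runtime (nothing read from
disk) and writes `{"t1": {"value": …, "n": …}, …}`: t1–t2 mean
separations (µm), t3–t4 effective fractions (×10⁻³), t5–t6 collision
radii (nm), t7 collision area (nm²), t8–t9 collision volumes
(×10⁴ nm³), t10 cylinder radius (nm), t11 fitted order. All are
deterministic; the seed is accepted for interface uniformity and does
not influence them. `tests/test_acceptance.py` holds one test per
criterion: table reproduction at 10%, order 0.67 ± 0.05, identities at
1e-12, transport quadrature at 1e-9/1e-6, Monte Carlo at 3 standard
errors with bitwise seed reproducibility, and fitting recovery
(noiseless 1e-9; noisy σ_log = 0.1, n = 20, within ±0.1 in ≥95% of 200
replicates).
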