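# diffrate

Dimensional analysis of diffusive association rates: a small library,
CLI and Brownian-dynamics simulator for the family of rate laws that
describe how fast a diffusing probe finds a dilute target.

## The science

In a dilute solution the probes around a target are, on average, a
distance `L = C^(-1/3)` apart (`C` is the probe number density). A probe
diffuses across that distance in the *reshuffle time*
`t_c = L² / (2D)`, after which the neighbourhood is statistically
renewed and the target gets a fresh nearest-neighbour "attempt". A
per-target association rate then follows from one attempt per `t_c`
succeeding with some effective fraction `a`:

| model id          | rate law (per target, 1/s)     | geometry parameter | order in C |
|-------------------|--------------------------------|--------------------|------------|
| `naive_continuous`| `r = C·V₀ / t`                 | volume `V₀` (m³)   | 1          |
| `discrete_0d`     | `r = 4 a D C^(2/3)`            | fraction `a`       | 2/3        |
| `smoluchowski_1d` | `r = 4π r₀ C D`                | radius `r₀` (m)    | 1          |
| `discrete_2d`     | `r = (4/π) A D C^(4/3)`        | area `A` (m²)      | 4/3        |
| `discrete_2d_tc`  | `r = 2√(2/π) A D C^(4/3)`      | area `A` (m²)      | 4/3        |
| `langmuir_schaefer`| `r = 2 A C √(D/(π t))`        | area `A` (m²)      | 1          |
| `discrete_3d`     | `r = 4 V₀ D C^(5/3)`           | volume `V₀` (m³)   | 5/3        |

The models differ in how much of the neighbour shell the collision
geometry occupies (a point fraction, a cross-section area, or an
overlap volume), which changes the *apparent reaction order* — the
slope of log(rate) vs log(concentration). Measuring that slope is
therefore a geometry probe: classical Smoluchowski kinetics is first
order, while nearest-neighbour attempt counting gives fractional
orders 2/3, 4/3 or 5/3.

The package ships an embedded reference dataset — per-target binding
rates of a fluorescent intercalating dye onto a single stretched DNA
molecule at 1–100 nM, with probe diffusion coefficient
`D = 2.9e-10 m²/s` — whose measured order is ≈ 2/3. Every model can be
run forward (geometry → rate) and inverted (measured rate → geometry),
so the same data yields the effective fraction, collision radius, area
and volume each model would need, plus equivalent cylinder radii
(`r₀ = A/ℓ`, `r₀ = √(V₀/ℓ)` with target contour length `ℓ = 1 µm`).

A Monte Carlo module validates the transport closed forms
(mean-squared displacement `6Dt`, the Gaussian propagator, 1D
first-passage `erfc(L/√(4Dt))`, Smoluchowski's `4π r₀ D C` onto an
absorbing sphere, capture probability `(r₀/L)·erfc((L−r₀)/√(4Dt))`)
with seeded, bitwise-reproducible random walks.

## Worked example

Fit the apparent order of the embedded dataset and invert every model
row by row:

```python
from diffrate import datasets
from diffrate.fitting import (fit_power_law, invert_dataset,
                              inversion_table_bench_units)

ds = datasets.binding_rate_dataset()
print(fit_power_law(ds).summary())

table = inversion_table_bench_units(
    invert_dataset(ds, datasets.PROBE_DIFFUSION_M2_S,
                   datasets.CYLINDER_LENGTH_M))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

Output:

```
Apparent reaction order (log-log OLS)
  n observations : 6
  order          : 0.6719 +/- 0.0454
  log prefactor  : -27.7933
  R^2            : 0.9821

 conc_nM  rate_per_s  L_um   t_c_us  a_e3  r0_1d_nm    A_nm2  r0_2d_nm  V_e4nm3  r0_3d_nm
       1        0.63  1.18 2.42e+03 0.762     0.287 3.36e+03      3.36      126      35.6
       3        1.49 0.821 1.16e+03 0.866     0.226 1.83e+03      1.83     47.9      21.9
       5        2.85 0.693      827  1.18      0.26 1.78e+03      1.78     39.1      19.8
      10           4  0.55      521  1.04     0.182      989     0.989     17.3      13.2
      50          10 0.321      178 0.891    0.0911      289     0.289     2.96      5.44
     100          15 0.255      112 0.842    0.0683      172     0.172      1.4      3.74
```

The fitted order 0.67 ± 0.05 matches the 0D/discrete reading of the
experiment, and the inverted 0D fraction `a ≈ 1e-3` is roughly constant
across two decades of concentration while the first-order Smoluchowski
radius `r₀` drifts by 4× — the dimensional argument in one table.

The same operations are available on the command line:

```console
$ diffrate predict --model 0d --a 0.76e-3 --conc-nm 1 --d 2.9e-10
discrete_0d: rate = 0.628693 /s at 1 nM
$ diffrate invert --model 1d --rate 4 --conc-nm 10 --d 2.9e-10
smoluchowski_1d: r0_nm = 0.182264
```

plus `diffrate fit` (CSV in, order + per-model fits out),
`diffrate simulate` (JSON config in, encounter statistics out),
`diffrate synth` (seeded synthetic power-law datasets) and
`diffrate table2` (the reference-table regression check below).

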