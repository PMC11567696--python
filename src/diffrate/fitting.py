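"""Dataset-level analysis: apparent reaction order, per-concentration
model inversion, and single-parameter global fits.

Two small statsmodels-style model classes form the surface:

* :class:`PowerLawModel` — OLS of ln(rate) on ln(concentration); its
  ``fit()`` returns a :class:`PowerLawFit` whose slope is the apparent
  reaction order.
* :class:`ConstantGeometryModel` — fits the single geometry parameter of
  one rate law to a whole dataset by least squares in log space (closed
  form: the geometric mean of the per-point inversions, since every
  time-independent law is linear in its parameter).

Module-level functions (:func:`fit_power_law`, :func:`invert_dataset`,
:func:`fit_constant_geometry`, :func:`compare_models`) delegate to them.

All fits are done in log space with equal weights: the reference data
span a ~25-fold range of rates, and multiplicative (lognormal) noise is
the natural error model for a power law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import RateDataset, number_density_to_nanomolar
from .models import (
    INVERTIBLE_MODELS,
    GeometryParams,
    ModelId,
    _GEOMETRY_FIELD,
    cylinder_radius_from_area,
    cylinder_radius_from_volume,
    dimensional_signature,
    invert_model,
    predict_rate,
)
from .transport import critical_time, mean_separation

__all__ = [
    "PowerLawFit",
    "GlobalFitResult",
    "PowerLawModel",
    "ConstantGeometryModel",
    "fit_power_law",
    "invert_dataset",
    "inversion_table_bench_units",
    "fit_constant_geometry",
    "compare_models",
]


# ---------------------------------------------------------------------------
# apparent reaction order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log OLS fit ``ln r = order * ln C + log_prefactor``.

    ``order`` is the apparent reaction order; ``order_stderr`` its OLS
    standard error (infinite when the fit is degenerate, e.g. all rates
    equal); ``r_squared`` in [0, 1]. ``bootstrap_stderr`` is filled only
    when a bootstrap was requested.
    """

    order: float
    log_prefactor: float
    order_stderr: float
    r_squared: float
    n_obs: int = 0
    bootstrap_stderr: Optional[float] = None

    def summary(self) -> str:
        lines = [
            "Apparent reaction order (log-log OLS)",
            f"  n observations : {self.n_obs}",
            f"  order          : {self.order:.4f} +/- {self.order_stderr:.4f}",
            f"  log prefactor  : {self.log_prefactor:.4f}",
            f"  R^2            : {self.r_squared:.4f}",
        ]
        if self.bootstrap_stderr is not None:
            lines.append(f"  bootstrap s.e. : {self.bootstrap_stderr:.4f}")
        return "\n".join(lines)


class PowerLawModel:
    """OLS power-law model ``r = k * C^order`` for a rate dataset.

    Parameters
    ----------
    dataset : RateDataset
        At least two points, all rates strictly positive.
    """

    def __init__(self, dataset: RateDataset):
        if len(dataset) < 2:
            raise ValueError("power-law fit needs at least two measurements")
        if np.any(dataset.rates <= 0):
            raise ValueError("power-law fit requires strictly positive rates")
        self.dataset = dataset
        self._x = np.log(dataset.concentrations)
        self._y = np.log(dataset.rates)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PowerLawModel":
        """Build from a DataFrame with ``conc_nM`` and ``rate_per_s`` columns."""
        from .core import nanomolar_to_number_density

        ds = RateDataset.from_arrays(
            np.asarray(nanomolar_to_number_density(df["conc_nM"].to_numpy())),
            df["rate_per_s"].to_numpy(),
        )
        return cls(ds)

    def fit(self, bootstrap: Optional[int] = None, seed: Optional[int] = None) -> PowerLawFit:
        """OLS in log space; optional case-resampling bootstrap of the order.

        ``bootstrap`` is the number of resamples and requires an explicit
        ``seed``.
        """
        x, y = self._x, self._y
        n = len(x)
        slope, intercept, stderr, r2 = _ols_line(x, y)
        boot_se = None
        if bootstrap:
            if seed is None:
                raise ValueError("bootstrap requires an explicit seed")
            rng = np.random.Generator(np.random.Philox(key=seed))
            slopes = np.empty(bootstrap)
            for b in range(bootstrap):
                idx = rng.integers(0, n, size=n)
                # resampled set may be degenerate in x; guard
                if np.ptp(x[idx]) == 0:
                    slopes[b] = np.nan
                    continue
                slopes[b] = _ols_line(x[idx], y[idx])[0]
            boot_se = float(np.nanstd(slopes, ddof=1))
        return PowerLawFit(
            order=slope,
            log_prefactor=intercept,
            order_stderr=stderr,
            r_squared=r2,
            n_obs=n,
            bootstrap_stderr=boot_se,
        )


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope, intercept, slope s.e., R^2 of a straight-line OLS fit.

    Degenerate inputs (zero spread in y) return slope 0 with infinite
    standard error rather than raising.
    """
    n = len(x)
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), math.inf, 0.0
    import statsmodels.api as sm

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    stderr = float(res.bse[1]) if n > 2 else math.inf
    r2 = float(res.rsquared)
    # two points fit exactly; report a zero-residual fit with inf stderr
    if n == 2:
        r2 = 1.0
    return slope, intercept, stderr, min(max(r2, 0.0), 1.0)


def fit_power_law(
    ds: RateDataset, bootstrap: Optional[int] = None, seed: Optional[int] = None
) -> PowerLawFit:
    """Apparent reaction order of a dataset (see :class:`PowerLawModel`)."""
    return PowerLawModel(ds).fit(bootstrap=bootstrap, seed=seed)


# ---------------------------------------------------------------------------
# per-concentration inversion (reference-table reproduction)
# ---------------------------------------------------------------------------

def invert_dataset(ds: RateDataset, D: float, ell: float = 1.0e-6) -> pd.DataFrame:
    """Invert every measurement under each time-independent model.

    For each (C, r) row computes the mean separation L, the reshuffle
    time t_c, and the geometry parameter of the 0D/1D/2D/3D models, plus
    the equivalent cylinder radii of the 2D area (``A/ell``) and 3D
    volume (``sqrt(V0/ell)``) for a target cylinder of length ``ell``.

    Returns a DataFrame in SI units with columns ``concentration``,
    ``rate``, ``L_m``, ``t_c_s``, ``a``, ``r0_1d_m``, ``A_m2``,
    ``r0_2d_m``, ``V0_m3``, ``r0_3d_m``; rows follow dataset order.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    rows = []
    for m in ds.measurements:
        C, r = m.concentration, m.rate
        rows.append(
            {
                "concentration": C,
                "rate": r,
                "L_m": mean_separation(C),
                "t_c_s": critical_time(D, C),
                "a": invert_model(ModelId.DISCRETE_0D, r, C, D).effective_fraction_a,
                "r0_1d_m": invert_model(
                    ModelId.SMOLUCHOWSKI_1D, r, C, D
                ).collision_radius_r0,
                "A_m2": invert_model(ModelId.DISCRETE_2D, r, C, D).collision_area_A,
                "V0_m3": invert_model(ModelId.DISCRETE_3D, r, C, D).collision_volume_V0,
            }
        )
    df = pd.DataFrame(rows, columns=[
        "concentration", "rate", "L_m", "t_c_s", "a", "r0_1d_m", "A_m2", "V0_m3",
    ])
    if len(df):
        df["r0_2d_m"] = df["A_m2"] / ell
        df["r0_3d_m"] = np.sqrt(df["V0_m3"] / ell)
    else:
        df["r0_2d_m"] = pd.Series(dtype=float)
        df["r0_3d_m"] = pd.Series(dtype=float)
    return df


def inversion_table_bench_units(table: pd.DataFrame) -> pd.DataFrame:
    """Convert an SI inversion table to bench units (nM, µm, µs, nm...)."""
    out = pd.DataFrame(
        {
            "conc_nM": number_density_to_nanomolar(table["concentration"].to_numpy()),
            "rate_per_s": table["rate"],
            "L_um": table["L_m"] * 1e6,
            "t_c_us": table["t_c_s"] * 1e6,
            "a_e3": table["a"] * 1e3,
            "r0_1d_nm": table["r0_1d_m"] * 1e9,
            "A_nm2": table["A_m2"] * 1e18,
            "r0_2d_nm": table["r0_2d_m"] * 1e9,
            "V_e4nm3": table["V0_m3"] * 1e27 / 1e4,
            "r0_3d_nm": table["r0_3d_m"] * 1e9,
        }
    )
    return out


# ---------------------------------------------------------------------------
# single-parameter global fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalFitResult:
    """Best single geometry parameter of one model for a whole dataset.

    ``best_parameter`` is in the model's own geometry unit (a is
    dimensionless, r0 in m, A in m^2, V0 in m^3); ``residual_norm`` is
    the root-sum-square of log residuals ``log(pred) - log(obs)``.
    """

    model: ModelId
    best_parameter: float
    residual_norm: float
    per_point_residuals: tuple

    @property
    def geometry(self) -> GeometryParams:
        return GeometryParams(**{_GEOMETRY_FIELD[self.model]: self.best_parameter})

    def predict(self, C, D: float):
        """Predicted rate at concentration(s) C with diffusion D."""
        return predict_rate(self.model, self.geometry, D, C)

    def summary(self) -> str:
        sig = dimensional_signature(self.model)
        return "\n".join(
            [
                f"Constant-geometry fit: {self.model.value}",
                f"  geometry symbol   : {sig.geometry_symbol}",
                f"  best parameter    : {self.best_parameter:.6g} (SI)",
                f"  residual norm     : {self.residual_norm:.6g} (log space)",
                f"  n points          : {len(self.per_point_residuals)}",
            ]
        )


class ConstantGeometryModel:
    """Single-parameter fit of one rate law to a dataset.

    Every time-independent law is linear in its geometry parameter, so
    the least-squares solution in log space is closed form: the
    geometric mean of the per-point inverted parameters.
    """

    def __init__(self, dataset: RateDataset, model: ModelId, D: float):
        if D <= 0:
            raise ValueError("diffusion coefficient must be > 0")
        model = ModelId(model)
        if model not in INVERTIBLE_MODELS:
            raise LookupError(
                f"{model.value} is time-dependent; constant-geometry fitting "
                "covers the time-independent models only"
            )
        if np.any(dataset.rates <= 0):
            raise ValueError("constant-geometry fit requires positive rates")
        self.dataset = dataset
        self.model = model
        self.D = D

    def fit(self) -> GlobalFitResult:
        ds, D, model = self.dataset, self.D, self.model
        params = np.array(
            [
                invert_model(model, m.rate, m.concentration, D).parameter_for(model)
                for m in ds.measurements
            ]
        )
        best = float(np.exp(np.mean(np.log(params))))
        geometry = GeometryParams(**{_GEOMETRY_FIELD[model]: best})
        pred = predict_rate(model, geometry, D, ds.concentrations)
        resid = np.log(np.asarray(pred)) - np.log(ds.rates)
        return GlobalFitResult(
            model=model,
            best_parameter=best,
            residual_norm=float(np.sqrt(np.sum(resid**2))),
            per_point_residuals=tuple(float(v) for v in resid),
        )


def fit_constant_geometry(ds: RateDataset, D: float, model: ModelId) -> GlobalFitResult:
    """Fit one model's single geometry parameter to a dataset."""
    return ConstantGeometryModel(ds, model, D).fit()


def compare_models(ds: RateDataset, D: float) -> list:
    """Rank all time-independent models by log-space residual norm.

    Returns :class:`GlobalFitResult` objects sorted ascending by
    residual norm; exact ties keep the registry's model order.
    """
    if len(ds) < 3:
        raise ValueError("model comparison needs at least three measurements")
    results = [fit_constant_geometry(ds, D, model) for model in INVERTIBLE_MODELS]
    order = {m: i for i, m in enumerate(INVERTIBLE_MODELS)}
    return sorted(results, key=lambda r: (r.residual_norm, order[r.model]))
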