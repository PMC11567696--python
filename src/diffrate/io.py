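"""File I/O and synthetic dataset generation.

CSV datasets use bench units (``conc_nM``, ``rate_per_s`` columns,
``#`` comment lines, RFC-4180, UTF-8); JSON configs use explicitly
unit-suffixed keys. Everything is converted to SI at this boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    RateDataset,
    nanomolar_to_number_density,
    number_density_to_nanomolar,
)
from .models import (
    TIME_INDEPENDENT_MODELS,
    GeometryParams,
    ModelId,
    predict_rate,
)
from .simulate import SimConfig

__all__ = [
    "read_rate_csv",
    "write_rate_csv",
    "SyntheticSpec",
    "generate_synthetic",
    "synthetic_spec_from_json",
    "sim_config_from_json",
    "sim_config_to_json",
]

PathLike = Union[str, Path]


class RateCsvError(ValueError):
    """Parse error in a rate CSV; the message names the offending line."""


def read_rate_csv(path: PathLike) -> RateDataset:
    """Read a rate-vs-concentration CSV into a :class:`RateDataset`.

    Requires a header with ``conc_nM`` and ``rate_per_s`` columns
    (extra columns are ignored); ``#`` lines and blank lines are
    skipped; rows are sorted by concentration. Missing columns,
    non-numeric cells and duplicate concentrations raise
    :class:`RateCsvError` naming the file line.
    """
    path = Path(path)
    header: Optional[list] = None
    col_idx = {}
    conc, rates, line_of = [], [], {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            cells = [c.strip() for c in row]
            if header is None:
                header = cells
                for col in ("conc_nM", "rate_per_s"):
                    if col not in header:
                        raise RateCsvError(
                            f"{path}: line {lineno}: missing required column {col!r}"
                        )
                col_idx = {c: header.index(c) for c in ("conc_nM", "rate_per_s")}
                continue
            try:
                c = float(cells[col_idx["conc_nM"]])
                r = float(cells[col_idx["rate_per_s"]])
            except (ValueError, IndexError):
                raise RateCsvError(
                    f"{path}: line {lineno}: non-numeric or missing cell in {row!r}"
                ) from None
            if c in line_of:
                raise RateCsvError(
                    f"{path}: line {lineno}: duplicate concentration {c} nM "
                    f"(first seen on line {line_of[c]})"
                )
            line_of[c] = lineno
            conc.append(c)
            rates.append(r)
    if header is None:
        raise RateCsvError(f"{path}: empty file (header required)")
    if not conc:
        raise RateCsvError(f"{path}: no data rows")
    return RateDataset.from_arrays(
        np.asarray(nanomolar_to_number_density(np.array(conc))),
        rates,
        label=path.stem,
    )


def write_rate_csv(ds: RateDataset, path: PathLike) -> None:
    """Write a dataset as ``conc_nM, rate_per_s`` (12 significant digits)."""
    df = pd.DataFrame(
        {
            "conc_nM": number_density_to_nanomolar(ds.concentrations),
            "rate_per_s": ds.rates,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic rate-vs-concentration dataset.

    Rates follow ``r_i = model(geometry, D, C_i) * exp(eps_i)`` with
    ``eps_i ~ N(0, noise_sigma_log)`` — multiplicative lognormal noise,
    the natural error model for rates measured over decades of
    concentration. Only time-independent models are allowed (the spec
    carries no evaluation time). The default grid and noise emulate the
    reference experiment: 1-100 nM and ~10% scatter.
    """

    true_model: ModelId
    geometry: GeometryParams
    diffusion_coefficient: float
    concentration_grid: tuple  # 1/m^3, strictly increasing
    noise_sigma_log: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        model = ModelId(self.true_model)
        object.__setattr__(self, "true_model", model)
        if model not in TIME_INDEPENDENT_MODELS:
            raise ValueError(
                f"synthetic generation supports time-independent models only, "
                f"got {model.value}"
            )
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be >= 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        grid = tuple(float(c) for c in self.concentration_grid)
        if len(grid) < 1 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("concentration_grid must be non-empty, strictly increasing")
        object.__setattr__(self, "concentration_grid", grid)


def generate_synthetic(spec: SyntheticSpec) -> RateDataset:
    """Generate the dataset a :class:`SyntheticSpec` describes (seeded)."""
    C = np.array(spec.concentration_grid)
    clean = predict_rate(
        spec.true_model, spec.geometry, spec.diffusion_coefficient, C
    )
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    eps = rng.normal(0.0, spec.noise_sigma_log, size=C.size) if spec.noise_sigma_log else 0.0
    rates = np.asarray(clean) * np.exp(eps)
    return RateDataset.from_arrays(C, rates, label=f"synthetic:{spec.true_model.value}")


# ---------------------------------------------------------------------------
# JSON configs (bench-unit keys at the boundary)
# ---------------------------------------------------------------------------

def _geometry_from_json(obj: dict) -> GeometryParams:
    kwargs = {}
    if "a" in obj:
        kwargs["effective_fraction_a"] = float(obj["a"])
    if "r0_nm" in obj:
        kwargs["collision_radius_r0"] = float(obj["r0_nm"]) * 1e-9
    if "A_nm2" in obj:
        kwargs["collision_area_A"] = float(obj["A_nm2"]) * 1e-18
    if "V0_nm3" in obj:
        kwargs["collision_volume_V0"] = float(obj["V0_nm3"]) * 1e-27
    if "cylinder_length_nm" in obj:
        kwargs["cylinder_length"] = float(obj["cylinder_length_nm"]) * 1e-9
    if not kwargs:
        raise ValueError(
            "geometry object needs at least one of a, r0_nm, A_nm2, V0_nm3"
        )
    return GeometryParams(**kwargs)


def synthetic_spec_from_json(path: PathLike) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from JSON.

    Keys: ``model``, ``geometry`` (object with ``a`` | ``r0_nm`` |
    ``A_nm2`` | ``V0_nm3``), ``D_m2_per_s``, ``conc_grid_nM`` (list),
    ``noise_sigma_log``, ``seed``.
    """
    obj = json.loads(Path(path).read_text())
    grid = tuple(
        float(nanomolar_to_number_density(c)) for c in obj["conc_grid_nM"]
    )
    return SyntheticSpec(
        true_model=ModelId(obj["model"]),
        geometry=_geometry_from_json(obj["geometry"]),
        diffusion_coefficient=float(obj["D_m2_per_s"]),
        concentration_grid=grid,
        noise_sigma_log=float(obj.get("noise_sigma_log", 0.0)),
        seed=int(obj.get("seed", 0)),
    )


def sim_config_from_json(path: PathLike) -> SimConfig:
    """Load a :class:`SimConfig` from JSON.

    Keys: ``D_m2_per_s``, ``conc_nM``, ``target_radius_nm``,
    ``walker_count``, ``time_step_s``, ``total_time_s``, ``seed``,
    optional ``box_side_nm`` and ``boundary_mode``.
    """
    obj = json.loads(Path(path).read_text())
    return SimConfig(
        diffusion_coefficient=float(obj["D_m2_per_s"]),
        number_concentration=float(nanomolar_to_number_density(obj["conc_nM"])),
        target_radius=float(obj["target_radius_nm"]) * 1e-9,
        walker_count=int(obj["walker_count"]),
        time_step=float(obj["time_step_s"]),
        total_time=float(obj["total_time_s"]),
        seed=int(obj["seed"]),
        box_side=(float(obj["box_side_nm"]) * 1e-9 if "box_side_nm" in obj else None),
        boundary_mode=obj.get("boundary_mode", "periodic"),
    )


def sim_config_to_json(cfg: SimConfig) -> dict:
    """Bench-unit JSON view of a config (echoed into every output)."""
    return {
        "D_m2_per_s": cfg.diffusion_coefficient,
        "conc_nM": float(number_density_to_nanomolar(cfg.number_concentration)),
        "target_radius_nm": cfg.target_radius * 1e9,
        "walker_count": cfg.walker_count,
        "time_step_s": cfg.time_step,
        "total_time_s": cfg.total_time,
        "seed": cfg.seed,
        "box_side_nm": cfg.box_side * 1e9,
        "boundary_mode": cfg.boundary_mode,
    }
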