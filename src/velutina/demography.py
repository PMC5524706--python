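"""Annual reproduction of nests: expected successful daughter queens.

Each nest produces a Poisson-distributed number of daughter queens that
survive hibernation and found a nest the following spring.  The Poisson mean
is a product of

* a baseline (``R_A``, the low-density mean at the Andernos-les-Bains
  reference latitude in south-west France),
* a linear latitude scaling that reaches zero at a northern "zero cline"
  (colder climate reduces reproductive success),
* a density-dependent competition factor driven by the number of other
  active nests within the competition radius,
* a global scaling multiplier ``scaling_sigma`` used for sensitivity analysis.

Habitat affects reproduction only through the hard constraint that water
cells host no nests; habitat *preference* acts at settlement (dispersal
module), so suitability is not double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._neighbors import crowding_counts
from .landscape import HabitatClass, LandscapeGrid, latitude_of

__all__ = [
    "DemographyParams",
    "PosteriorDraws",
    "latitude_scaling",
    "local_crowding",
    "crowding_counts",
    "expected_queens",
    "expected_queens_field",
    "sample_offspring",
    "sample_params",
    "load_posterior_draws",
]


@dataclass(frozen=True)
class DemographyParams:
    """Reproduction parameters.

    Defaults: ``R_A`` = 8.7 daughter queens per low-density nest at the
    Andernos-les-Bains latitude (44.74 N), and a zero cline at 55.9 N; at the
    latitude of the Tetbury founder nest (51.64 N) these give 38% of baseline
    reproduction, i.e. 3.3 expected daughters.  ``K_half`` is the number of
    competing nests within ``r_c_km`` at which reproduction halves.
    """

    R_A: float = 8.7
    lat_A_deg: float = 44.74
    lat_zero_deg: float = 55.9
    K_half: float = 2.0
    r_c_km: float = 2.0
    scaling_sigma: float = 1.0
    density_form: str = "hyperbolic"  # or "exponential"

    def __post_init__(self) -> None:
        if self.R_A <= 0 or self.K_half <= 0 or self.r_c_km <= 0:
            raise ValueError("R_A, K_half and r_c_km must be positive")
        if self.lat_zero_deg <= self.lat_A_deg:
            raise ValueError("lat_zero_deg must exceed lat_A_deg")
        if self.scaling_sigma < 0:
            raise ValueError("scaling_sigma must be non-negative")
        if self.density_form not in ("hyperbolic", "exponential"):
            raise ValueError("density_form must be 'hyperbolic' or 'exponential'")

    def with_(self, **kwargs) -> "DemographyParams":
        return replace(self, **kwargs)


def latitude_scaling(lat_deg, params: DemographyParams) -> np.ndarray:
    """Linear latitude scaling of reproduction, clamped to [0, 1].

    1 at (and south of) the Andernos baseline latitude, 0 at (and north of)
    the zero cline; piecewise-linear and continuous in between.
    """
    lat = np.asarray(lat_deg, dtype=float)
    frac = (params.lat_zero_deg - lat) / (params.lat_zero_deg - params.lat_A_deg)
    return np.clip(frac, 0.0, 1.0)


def _density_factor(crowding, params: DemographyParams) -> np.ndarray:
    c = np.asarray(crowding, dtype=float)
    if np.any(c < 0):
        raise ValueError("crowding must be non-negative")
    if params.density_form == "hyperbolic":
        return 1.0 / (1.0 + c / params.K_half)
    return np.exp(-c / params.K_half)


def local_crowding(
    nests: Iterable,
    x_km: float,
    y_km: float,
    r_c_km: float,
    exclude_id=None,
) -> int:
    """Count active nests within ``r_c_km`` (inclusive) of (x, y), excluding
    the focal nest identified by ``exclude_id``.

    ``nests`` may hold engine ``Nest`` objects or plain (x, y) pairs.
    """
    if r_c_km <= 0:
        raise ValueError("r_c_km must be positive")
    count = 0
    r2 = r_c_km * r_c_km
    for nest in nests:
        if hasattr(nest, "x_km"):
            if getattr(nest, "status", "active") != "active":
                continue
            if exclude_id is not None and getattr(nest, "id", None) == exclude_id:
                continue
            nx, ny = nest.x_km, nest.y_km
        else:
            nx, ny = nest
        dx = nx - x_km
        dy = ny - y_km
        if dx * dx + dy * dy <= r2:
            count += 1
    return count


def expected_queens(
    x_km,
    y_km,
    crowding,
    grid: LandscapeGrid,
    params: DemographyParams,
) -> np.ndarray:
    """Poisson mean of successful daughter queens for a nest at (x, y).

    mu = scaling_sigma * R_A * latitude_scaling * density_factor, and 0 for a
    nest whose cell is water (no nest can exist there).
    """
    lat = latitude_of(grid, y_km)
    mu = (
        params.scaling_sigma
        * params.R_A
        * latitude_scaling(lat, params)
        * _density_factor(crowding, params)
    )
    water = grid.class_at(x_km, y_km) == HabitatClass.WATER
    return np.where(water, 0.0, mu)


def expected_queens_field(grid: LandscapeGrid, params: DemographyParams) -> np.ndarray:
    """Low-density (crowding 0) expected queens per grid cell."""
    latsc = latitude_scaling(grid.row_latitudes(), params)[:, None]
    mu = params.scaling_sigma * params.R_A * latsc * np.ones((1, grid.n_cols))
    mu[grid.classes == HabitatClass.WATER] = 0.0
    return mu


def sample_offspring(mu, rng: np.random.Generator) -> np.ndarray:
    """Poisson draw of daughter-queen counts."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("Poisson mean must be non-negative")
    return rng.poisson(mu)


# ---------------------------------------------------------------------------
# Posterior parameter draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorDraws:
    """Table of posterior parameter draws, one row per draw; columns are a
    subset of :class:`DemographyParams` field names."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("posterior draw table must be non-empty")
        valid = set(DemographyParams.__dataclass_fields__)
        unknown = set(self.table.columns) - valid
        if unknown:
            raise ValueError(f"unknown parameter columns: {sorted(unknown)}")
        # every row must yield a valid parameter set
        for _, row in self.table.iterrows():
            DemographyParams().with_(**row.to_dict())

    def __len__(self) -> int:
        return len(self.table)


def load_posterior_draws(path) -> PosteriorDraws:
    return PosteriorDraws(pd.read_csv(path))


def sample_params(
    draws: PosteriorDraws,
    rng: np.random.Generator,
    base: DemographyParams | None = None,
) -> DemographyParams:
    """Uniformly sample one posterior row, merged over the defaults."""
    base = base or DemographyParams()
    idx = int(rng.integers(len(draws)))
    row = draws.table.iloc[idx].to_dict()
    return base.with_(**row)
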