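"""Deterministic (simulation-free) risk mapping.

All quantities here are computed from the probabilistic rates of the model
rather than Monte-Carlo simulation:

* the posterior over the location of a common founder nest, given the
  sightings that revealed the invasion (product of the 2-D dispersal point
  density at each sighting, restricted to settleable cells);
* expected-nest intensity fields for subsequent years, obtained by linear
  propagation of an intensity through reproduction and the settlement kernel
  (a Poisson process pushed through independent thinning and displacement
  stays Poisson, so expected intensities propagate linearly);
* the high-risk contour: the smallest set of highest-intensity cells holding
  all but a budget (default one nest) of the expected total;
* the branching-process extinction probability in the low-density
  approximation (no density dependence), solved as a spatial fixed point.

Because nest destruction is an independent thinning of a Poisson offspring
set, destroying a discovered nest does not change the predicted distribution
of the remaining, undiscovered nests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .demography import DemographyParams, expected_queens_field, latitude_scaling
from .dispersal import (
    CellKernel,
    DispersalParams,
    acceptance_field,
    retry_factor,
    single_draw_acceptance,
)
from .landscape import LandscapeGrid, SuitabilityWeights, latitude_of

__all__ = [
    "Observation",
    "IntensityField",
    "founder_posterior",
    "propagate",
    "undiscovered_nests",
    "next_year_nests",
    "high_risk_region",
    "HighRiskRegion",
    "extinction_field",
    "extinction_probability",
    "extinction_threshold",
    "sensitivity_curves",
    "default_observations",
    "field_mode",
]


@dataclass(frozen=True)
class Observation:
    """A record revealing a nest: either the nest itself or a foraging worker
    hornet (treated as evidence of a nest at the sighting location, since
    workers forage near their nest)."""

    x_km: float
    y_km: float
    year: int
    type: str = "nest"  # "nest" | "hornet"

    def __post_init__(self) -> None:
        if self.type not in ("nest", "hornet"):
            raise ValueError("observation type must be 'nest' or 'hornet'")


@dataclass
class IntensityField:
    """Grid of expected nest counts per cell for one year."""

    values: np.ndarray
    grid: LandscapeGrid
    year: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.classes.shape:
            raise ValueError("field shape must match the grid")
        if np.any(self.values < 0):
            raise ValueError("intensity must be non-negative")

    def total(self) -> float:
        return float(self.values.sum())


def field_mode(field: IntensityField) -> tuple[float, float]:
    """(x, y) of the centre of the highest-intensity cell."""
    row, col = np.unravel_index(np.argmax(field.values), field.values.shape)
    h = field.grid.cell_size_km
    return (
        field.grid.origin_x_km + (col + 0.5) * h,
        field.grid.origin_y_km + (row + 0.5) * h,
    )


def _dispersal_probability_from_point(
    grid: LandscapeGrid, x0: float, y0: float, delta_km: float
) -> np.ndarray:
    """Per-cell probability that a displacement from (x0, y0) lands in the
    cell: midpoint rule with sub-cell refinement near the source and the exact
    radial CDF for the containing cell (handles the d -> 0 singularity)."""
    h = grid.cell_size_km
    ys, xs = grid.cell_centers()
    dy = ys[:, None] - y0
    dx = xs[None, :] - x0
    d = np.hypot(dy, dx)

    def point_density(dist):
        dist = np.maximum(dist, 1e-9)
        return np.exp(-dist / delta_km) / (2.0 * np.pi * dist * delta_km)

    prob = h * h * point_density(d)

    near = d <= 4.0 * h
    if near.any():
        s = 9
        sub = ((np.arange(s) + 0.5) / s - 0.5) * h
        sy, sx = np.meshgrid(sub, sub)
        rows, cols = np.nonzero(near)
        dist = np.hypot(
            dy[rows, 0][:, None] + sy.ravel()[None, :],
            dx[0, cols][:, None] + sx.ravel()[None, :],
        )
        prob[near] = h * h * point_density(np.maximum(dist, h / (2 * s))).mean(axis=1)

    inside = grid.contains(np.array([x0]), np.array([y0]))
    if inside[0]:
        row, col = grid.cell_of(x0, y0)
        r_eq = h / np.sqrt(np.pi)
        prob[int(row), int(col)] = 1.0 - np.exp(-r_eq / delta_km)
    return prob


def founder_posterior(
    observations: Sequence[Observation],
    grid: LandscapeGrid,
    weights: SuitabilityWeights,
    disp_params: DispersalParams,
) -> IntensityField:
    """Posterior probability field for the location of the common founder
    nest, one dispersal event before the observations.

    posterior(x) proportional to settleable(x) * product over observations of
    the cell-integrated dispersal density from x to the observation.  The
    likelihood uses settleability and dispersal only (no reproduction
    weighting); by symmetry of the radial kernel, dispersal from x to the
    observation equals dispersal from the observation to x.
    """
    if len(observations) == 0:
        raise ValueError("at least one observation is required")
    for obs in observations:
        if not np.all(grid.contains(obs.x_km, obs.y_km)):
            raise ValueError(f"observation at ({obs.x_km}, {obs.y_km}) outside grid")
    settleable = acceptance_field(grid, weights) > 0
    log_post = np.where(settleable, 0.0, -np.inf)
    for obs in observations:
        p = _dispersal_probability_from_point(grid, obs.x_km, obs.y_km, disp_params.delta_km)
        with np.errstate(divide="ignore"):
            log_post = log_post + np.log(p)
    post = np.exp(log_post - np.nanmax(log_post[np.isfinite(log_post)]))
    post[~np.isfinite(log_post)] = 0.0
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior is identically zero: observations unreachable")
    return IntensityField(values=post / total, grid=grid, year=min(o.year for o in observations) - 1)


@dataclass
class _Propagator:
    """Cached pieces of the linear intensity-propagation operator."""

    kernel: CellKernel
    alpha: np.ndarray
    a: np.ndarray        # single-draw acceptance per origin cell
    retry: np.ndarray    # settlement amplification over max_attempts draws
    fail: np.ndarray     # per-origin settlement failure mass


def make_propagator(
    grid: LandscapeGrid,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    kernel: CellKernel | None = None,
) -> _Propagator:
    kernel = kernel or CellKernel(grid.cell_size_km, disp_params.delta_km)
    alpha = acceptance_field(grid, weights)
    a = single_draw_acceptance(alpha, kernel)
    return _Propagator(
        kernel=kernel,
        alpha=alpha,
        a=a,
        retry=retry_factor(a, disp_params.max_attempts),
        fail=(1.0 - a) ** disp_params.max_attempts,
    )


def propagate(
    field: IntensityField,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    propagator: _Propagator | None = None,
) -> IntensityField:
    """One year of expected-intensity propagation.

    lambda'(y) = sum_x lambda(x) mu0(x) T(x -> y), with mu0 the low-density
    expected queens and T the settlement kernel (failure mass dropped).
    Linear in lambda.
    """
    grid = field.grid
    prop = propagator or make_propagator(grid, disp_params, weights)
    mu0 = expected_queens_field(grid, dem_params)
    source = field.values * mu0 * prop.retry
    out = prop.alpha * prop.kernel.convolve(source)
    return IntensityField(values=out, grid=grid, year=field.year + 1)


def undiscovered_nests(
    founder: IntensityField,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    propagator: _Propagator | None = None,
) -> IntensityField:
    """Expected intensity of daughter nests in the year after founding.

    Because detection-and-destruction is an independent thinning of the
    Poisson offspring set, the destroyed discovered nest requires no
    correction: the undiscovered nests remain Poisson with this intensity.
    ``total()`` is the expected number of daughter nests dispersed into the
    wider environment.
    """
    if not np.isclose(founder.total(), 1.0, atol=1e-6):
        raise ValueError("founder field must be normalised")
    return propagate(founder, dem_params, disp_params, weights, propagator)


def next_year_nests(
    field: IntensityField,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    observed_nests: Optional[Sequence[Observation]] = None,
    propagator: _Propagator | None = None,
) -> IntensityField:
    """Expected nest intensity one further year on.

    ``observed_nests`` are nests known to have existed in ``field``'s year on
    top of the predicted undiscovered intensity (the observations are extra
    conditioning information, independent of the undiscovered Poisson count by
    the thinning property).  Each is added as a unit point mass before
    propagation; this includes a destroyed nest whose queens had already
    dispersed before destruction, as for a nest destroyed at the end of the
    season.
    """
    values = field.values.copy()
    if observed_nests:
        for obs in observed_nests:
            if not np.all(field.grid.contains(obs.x_km, obs.y_km)):
                raise ValueError("observed nest outside the grid")
            row, col = field.grid.cell_of(obs.x_km, obs.y_km)
            values[int(row), int(col)] += 1.0
    staged = IntensityField(values=values, grid=field.grid, year=field.year)
    return propagate(staged, dem_params, disp_params, weights, propagator)


@dataclass
class HighRiskRegion:
    """Smallest set of highest-intensity cells with < budget expected nests
    outside it."""

    mask: np.ndarray
    area_km2: float
    level: float  # lowest included intensity (inf for an empty region)
    budget: float


def high_risk_region(field: IntensityField, budget: float = 1.0) -> HighRiskRegion:
    """Cells sorted by intensity descending; keep the smallest prefix such
    that the expected number of nests outside is below ``budget``."""
    if budget <= 0:
        raise ValueError("budget must be positive")
    vals = field.values.ravel()
    total = vals.sum()
    mask = np.zeros(vals.size, dtype=bool)
    if total >= budget:
        order = np.argsort(vals, kind="stable")[::-1]
        outside = total - np.cumsum(vals[order])
        # smallest prefix with strictly fewer than `budget` expected nests outside
        k = int(np.searchsorted(-outside, -budget, side="right")) + 1
        k = min(k, vals.size)
        mask[order[:k]] = True
        level = float(vals[order[k - 1]])
    else:
        level = float("inf")
    h = field.grid.cell_size_km
    return HighRiskRegion(
        mask=mask.reshape(field.values.shape),
        area_km2=float(mask.sum()) * h * h,
        level=level,
        budget=budget,
    )


# ---------------------------------------------------------------------------
# Branching-process extinction probability
# ---------------------------------------------------------------------------


def extinction_field(
    grid: LandscapeGrid,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    tol: float = 1e-9,
    max_iter: int = 5000,
    propagator: _Propagator | None = None,
) -> np.ndarray:
    """Probability q(x) that the lineage of a single nest at x dies out.

    With Poisson offspring, q solves the spatial fixed point
        q(x) = exp( mu0(x) * [ sum_y T(x->y) q(y) + fail(x) - 1 ] )
    in the low-density approximation (no density dependence, which is valid
    near the extinction threshold where nest densities are minimal).  Iterated
    from q = 0; the iteration is monotone non-decreasing and converges to the
    minimal fixed point (the true extinction probability).
    """
    prop = propagator or make_propagator(grid, disp_params, weights)
    mu0 = expected_queens_field(grid, dem_params)
    q = np.zeros_like(mu0)
    for _ in range(max_iter):
        spread = prop.retry * prop.kernel.convolve(prop.alpha * q)
        q_new = np.exp(mu0 * (spread + prop.fail - 1.0))
        change = np.max(np.abs(q_new - q))
        q = q_new
        if change < tol:
            return q
    raise RuntimeError(
        f"extinction fixed point did not converge within {max_iter} iterations "
        f"(last sup-norm change {change:.3g})"
    )


def extinction_probability(
    grid: LandscapeGrid,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    scaling_sigma: float,
    location: tuple[float, float],
    **solver_kwargs,
) -> float:
    """Extinction probability for a founder nest at ``location`` under the
    given global reproductive scaling."""
    if scaling_sigma < 0:
        raise ValueError("scaling must be >= 0")
    dem = dem_params.with_(scaling_sigma=scaling_sigma)
    q = extinction_field(grid, dem, disp_params, weights, **solver_kwargs)
    row, col = grid.cell_of(location[0], location[1])
    return float(q[int(row), int(col)])


def realised_ratio(
    grid: LandscapeGrid,
    dem_params: DemographyParams,
    scaling_sigma: float,
    location: tuple[float, float],
) -> float:
    """Reproductive potential at ``location`` as a fraction of the Andernos
    baseline: scaling_sigma x latitude_scaling(latitude)."""
    lat = float(latitude_of(grid, location[1]))
    return scaling_sigma * float(latitude_scaling(lat, dem_params))


def extinction_threshold(
    grid: LandscapeGrid,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    location: tuple[float, float],
    target_q: float = 0.99,
    lo_realised: float = 0.01,
    hi_realised: float = 0.30,
    resolution: float = 0.002,
    **solver_kwargs,
) -> float:
    """Largest realised reproductive ratio at ``location`` for which the
    extinction probability there is still >= ``target_q``.

    Uses bisection over the global scaling (extinction probability is monotone
    non-increasing in the scaling), to ``resolution`` in realised-ratio units.
    """
    latsc = float(latitude_scaling(float(latitude_of(grid, location[1])), dem_params))
    if latsc <= 0:
        raise ValueError("location has zero reproductive potential")

    def q_at(realised: float) -> float:
        return extinction_probability(
            grid, dem_params, disp_params, weights, realised / latsc, location,
            **solver_kwargs,
        )

    if q_at(lo_realised) < target_q:
        raise ValueError("lower bound of the sweep already falls below target")
    if q_at(hi_realised) >= target_q:
        return hi_realised
    lo, hi = lo_realised, hi_realised
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if q_at(mid) >= target_q:
            lo = mid
        else:
            hi = mid
    return lo


def sensitivity_curves(
    scalings: Sequence[float],
    grid: LandscapeGrid,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    weights: SuitabilityWeights,
    observations: Sequence[Observation],
    budget: float = 1.0,
) -> pd.DataFrame:
    """Sensitivity of the year-1/year-2 risk map to the reproductive scaling.

    For each global scaling sigma: expected nests one and two years after
    founding, the extinction probability at the founder-posterior mode, and
    the high-risk areas.  ``realised_ratio`` is the reproductive potential at
    the founder mode relative to the Andernos baseline (the natural x-axis).
    """
    post = founder_posterior(observations, grid, weights, disp_params)
    prop = make_propagator(grid, disp_params, weights)
    mode = field_mode(post)
    rows = []
    for sigma in scalings:
        if sigma < 0:
            raise ValueError("scalings must be >= 0")
        dem = dem_params.with_(scaling_sigma=sigma)
        f1 = undiscovered_nests(post, dem, disp_params, weights, propagator=prop)
        f2 = next_year_nests(
            f1, dem, disp_params, weights,
            observed_nests=[o for o in observations if o.year == f1.year],
            propagator=prop,
        )
        q = extinction_probability(
            grid, dem_params, disp_params, weights, sigma, mode
        )
        rows.append(
            {
                "sigma": sigma,
                "realised_ratio": realised_ratio(grid, dem_params, sigma, mode),
                "nests_year1": f1.total(),
                "nests_year2": f2.total(),
                "extinction_prob": q,
                "risk_area_yr1_km2": high_risk_region(f1, budget).area_km2,
                "risk_area_yr2_km2": high_risk_region(f2, budget).area_km2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default sighting records for the Great-Britain-like landscape
# ---------------------------------------------------------------------------


def default_observations(grid: LandscapeGrid) -> list[Observation]:
    """The two 2016 records that revealed the invasion, placed on the
    GB-like landscape at their true latitudes: the Tetbury nest (51.64 N,
    found and destroyed in late September) and the North Somerset worker
    hornet (~51.40 N, whose nest was never found), ~48 km apart."""
    kmdeg = grid.km_per_degree_lat

    def y_of(lat):
        return grid.origin_y_km + (lat - grid.lat_at_origin_deg) * kmdeg

    mid_x = grid.origin_x_km + grid.width_km / 2.0
    return [
        Observation(x_km=mid_x, y_km=y_of(51.64), year=2016, type="nest"),
        Observation(x_km=mid_x - 40.0, y_km=y_of(51.40), year=2016, type="hornet"),
    ]
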