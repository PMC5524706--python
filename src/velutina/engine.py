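"""Annual-cycle stochastic simulation of nest spread.

Each simulated year: every *active* nest produces a Poisson number of
successful daughter queens (mean from :mod:`velutina.demography`, with
crowding measured among the same year's active nests, simultaneously for all
nests so results are order-independent); each queen disperses and settles via
:mod:`velutina.dispersal`; settled queens become next year's active nests and
all current-year nests die (annual colony lifecycle).  Nests destroyed by
control (see :mod:`velutina.control`) produce no queens.

Replicate seeds are derived from the master seed by a counter-based
``SeedSequence`` split, so replicate k is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import demography as dem_mod
from .demography import DemographyParams, PosteriorDraws, sample_params
from .dispersal import DispersalParams, settle_many
from .landscape import LandscapeGrid, SuitabilityWeights, homogeneous_landscape

__all__ = [
    "Nest",
    "YearState",
    "Scenario",
    "Trajectory",
    "step_year",
    "run",
    "run_replicate",
    "nest_density",
    "wave_speed",
    "mean_wave_speed",
    "calibrate_delta",
    "summarize",
    "trajectories_to_frame",
]

ACTIVE = "active"
DESTROYED = "destroyed"


@dataclass(frozen=True)
class Nest:
    """A single colony: one year of life, optionally destroyed by control."""

    id: int
    x_km: float
    y_km: float
    year_founded: int
    parent_id: Optional[int] = None
    status: str = ACTIVE


@dataclass
class YearState:
    """Struct-of-arrays for all nests founded in one year."""

    year: int
    x: np.ndarray
    y: np.ndarray
    id: np.ndarray
    parent: np.ndarray
    active: np.ndarray  # False = destroyed by control this year

    @classmethod
    def empty(cls, year: int) -> "YearState":
        z = np.zeros(0)
        return cls(year, z, z, np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, bool))

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def n_destroyed(self) -> int:
        return self.n - self.n_active

    def nests(self) -> list[Nest]:
        return [
            Nest(
                id=int(self.id[i]),
                x_km=float(self.x[i]),
                y_km=float(self.y[i]),
                year_founded=self.year,
                parent_id=int(self.parent[i]) if self.parent[i] >= 0 else None,
                status=ACTIVE if self.active[i] else DESTROYED,
            )
            for i in range(self.n)
        ]


@dataclass
class Trajectory:
    """Per-year nest record of one stochastic replicate."""

    states: list[YearState]
    replicate: int = 0

    @property
    def years(self) -> int:
        return len(self.states)

    def counts(self) -> np.ndarray:
        """Nests founded per year (index 0 = year 1)."""
        return np.array([s.n for s in self.states], dtype=np.int64)

    def destroyed_counts(self) -> np.ndarray:
        return np.array([s.n_destroyed for s in self.states], dtype=np.int64)

    @property
    def extinct_year(self) -> Optional[int]:
        """First year with no active nest; None if the invasion survived."""
        for s in self.states:
            if s.n_active == 0:
                return s.year
        return None

    @property
    def survived(self) -> bool:
        return self.extinct_year is None

    def positions(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        s = self.states[year - 1]
        return s.x, s.y


@dataclass
class Scenario:
    """Full specification of a simulation experiment."""

    grid: LandscapeGrid
    seeds: Sequence[tuple[float, float]] | None = None
    founder_field: Optional[np.ndarray] = None  # grid-shaped seeding weights
    years: int = 25
    n_replicates: int = 1
    demography: DemographyParams = field(default_factory=DemographyParams)
    posterior: Optional[PosteriorDraws] = None
    dispersal: DispersalParams = field(default_factory=DispersalParams)
    weights: SuitabilityWeights = field(default_factory=SuitabilityWeights)
    control: Optional["ControlPolicy"] = None  # noqa: F821 - velutina.control
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seeds is None and self.founder_field is None:
            raise ValueError("scenario needs seed nests or a founder field")


def step_year(
    state: YearState,
    grid: LandscapeGrid,
    dem_params: DemographyParams,
    disp_params: DispersalParams,
    rng: np.random.Generator,
    weights: SuitabilityWeights | None = None,
    id_start: int | None = None,
) -> YearState:
    """Advance one year: reproduction of active nests, dispersal, settlement."""
    weights = weights or SuitabilityWeights()
    if id_start is None:
        id_start = int(state.id.max()) + 1 if state.n else 0
    if state.n_active == 0:
        return YearState.empty(state.year + 1)

    xs = state.x[state.active]
    ys = state.y[state.active]
    ids = state.id[state.active]

    crowd = dem_mod.crowding_counts(xs, ys, dem_params.r_c_km)
    mu = dem_mod.expected_queens(xs, ys, crowd, grid, dem_params)
    n_off = rng.poisson(mu)

    src = np.repeat(np.arange(xs.size), n_off)
    if src.size == 0:
        return YearState.empty(state.year + 1)
    sx, sy, ok = settle_many(xs[src], ys[src], grid, weights, disp_params, rng)
    src = src[ok]
    n_new = src.size
    return YearState(
        year=state.year + 1,
        x=sx[ok],
        y=sy[ok],
        id=id_start + np.arange(n_new, dtype=np.int64),
        parent=ids[src],
        active=np.ones(n_new, dtype=bool),
    )


def _seed_state(scenario: Scenario, rng: np.random.Generator) -> YearState:
    if scenario.seeds is not None:
        pts = np.asarray(scenario.seeds, dtype=float).reshape(-1, 2)
    else:
        w = np.asarray(scenario.founder_field, dtype=float).ravel()
        if w.sum() <= 0:
            raise ValueError("founder field has no mass")
        cell = rng.choice(w.size, p=w / w.sum())
        grid = scenario.grid
        row, col = divmod(int(cell), grid.n_cols)
        h = grid.cell_size_km
        pts = np.array(
            [[grid.origin_x_km + (col + rng.random()) * h,
              grid.origin_y_km + (row + rng.random()) * h]]
        )
    if not np.all(scenario.grid.contains(pts[:, 0], pts[:, 1])):
        raise ValueError("seed nest outside the landscape")
    n = pts.shape[0]
    return YearState(
        year=1,
        x=pts[:, 0].copy(),
        y=pts[:, 1].copy(),
        id=np.arange(n, dtype=np.int64),
        parent=np.full(n, -1, dtype=np.int64),
        active=np.ones(n, dtype=bool),
    )


def replicate_rng(master_seed: int, k: int) -> np.random.Generator:
    """Deterministic, independent stream for replicate ``k``."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(k,)))


def run_replicate(scenario: Scenario, k: int = 0) -> Trajectory:
    """Run replicate ``k`` of the scenario (reproducible in isolation)."""
    from .control import apply_control  # deferred: control builds on engine

    rng = replicate_rng(scenario.master_seed, k)
    dem = (
        sample_params(scenario.posterior, rng, base=scenario.demography)
        if scenario.posterior is not None
        else scenario.demography
    )
    state = _seed_state(scenario, rng)
    next_id = state.n
    states = []
    for _ in range(scenario.years):
        if scenario.control is not None:
            state = apply_control(state, scenario.control, state.year, rng)
        states.append(state)
        if state.year >= scenario.years:
            break
        state = step_year(
            state, scenario.grid, dem, scenario.dispersal, rng,
            weights=scenario.weights, id_start=next_id,
        )
        next_id += state.n
    return Trajectory(states=states, replicate=k)


def run(scenario: Scenario) -> list[Trajectory]:
    """Run all replicates; a pure function of (scenario, master seed)."""
    return [run_replicate(scenario, k) for k in range(scenario.n_replicates)]


# ---------------------------------------------------------------------------
# Summaries and statistics
# ---------------------------------------------------------------------------


def summarize(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Per-year nest-count summary across replicates: mean, median and the
    50% / 95% prediction bands."""
    counts = np.vstack([t.counts() for t in trajectories]).astype(float)
    years = np.arange(1, counts.shape[1] + 1)
    q = np.percentile(counts, [2.5, 25, 50, 75, 97.5], axis=0)
    return pd.DataFrame(
        {
            "year": years,
            "mean": counts.mean(axis=0),
            "median": q[2],
            "q025": q[0],
            "q25": q[1],
            "q75": q[3],
            "q975": q[4],
        }
    )


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Tidy nest table: replicate, year, nest_id, parent_id, x, y, status."""
    rows = []
    for t in trajectories:
        for s in t.states:
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": t.replicate,
                        "year": s.year,
                        "nest_id": s.id,
                        "parent_id": s.parent,
                        "x_km": s.x,
                        "y_km": s.y,
                        "status": np.where(s.active, ACTIVE, DESTROYED),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["replicate", "year", "nest_id", "parent_id", "x_km", "y_km", "status"]
        )
    return pd.concat(rows, ignore_index=True)


def nest_density(
    trajectory: Trajectory,
    year: int,
    grid: LandscapeGrid,
    cell_km: float = 1.0,
) -> np.ndarray:
    """Raster of nests per square km in ``cell_km`` squares (row 0 = south)."""
    if not (1 <= year <= trajectory.years):
        raise ValueError("year outside the simulated horizon")
    x, y = trajectory.positions(year)
    nx = int(np.ceil(grid.width_km / cell_km))
    ny = int(np.ceil(grid.height_km / cell_km))
    counts, _, _ = np.histogram2d(
        y,
        x,
        bins=[ny, nx],
        range=[
            [grid.origin_y_km, grid.origin_y_km + ny * cell_km],
            [grid.origin_x_km, grid.origin_x_km + nx * cell_km],
        ],
    )
    return counts / (cell_km * cell_km)


def wave_speed(
    trajectory: Trajectory,
    seed_location: tuple[float, float],
    min_nests: int = 10,
    fit_years: int = 4,
) -> float:
    """Invasion-front speed (km/year).

    The front statistic is the 97.5th percentile of nest distance from the
    seeding point (robust to single long-distance outliers while tracking the
    front); the speed is the OLS slope of that radius against year.  Years
    with fewer than ``min_nests`` nests are excluded, and the fit uses only
    the last ``fit_years`` qualifying years: during establishment the
    population is concentrated in the founding core, so the percentile radius
    lags the true front until the core has filled in, and including that
    transient biases the slope low.
    """
    sx, sy = seed_location
    years, radii = [], []
    for s in trajectory.states:
        if s.n >= min_nests:
            r = np.hypot(s.x - sx, s.y - sy)
            years.append(s.year)
            radii.append(np.percentile(r, 97.5))
    if len(years) < 3:
        raise ValueError(
            f"need >= 3 years with >= {min_nests} nests to estimate a front speed"
        )
    k = max(3, fit_years)
    years, radii = years[-k:], radii[-k:]
    slope = np.polyfit(np.asarray(years, float), np.asarray(radii, float), 1)[0]
    return float(slope)


def mean_wave_speed(
    dem_params: DemographyParams | None = None,
    disp_params: DispersalParams | None = None,
    n_reps: int = 10,
    years: int = 10,
    seed: int = 0,
    grid: LandscapeGrid | None = None,
) -> tuple[float, list[float]]:
    """Replicate-mean front speed on the calibration landscape.

    Default setting emulates the French invasion baseline: a homogeneous
    fully-suitable 1200 x 1200 km landscape at 4-km cells, constant latitude
    at the Andernos baseline (latitude scaling = 1), one central founder.
    Replicates are simulated one at a time and discarded to bound memory.
    """
    dem_params = dem_params or DemographyParams()
    disp_params = disp_params or DispersalParams()
    grid = grid if grid is not None else homogeneous_landscape()
    cx = grid.origin_x_km + grid.width_km / 2.0
    cy = grid.origin_y_km + grid.height_km / 2.0
    scenario = Scenario(
        grid=grid,
        seeds=[(cx, cy)],
        years=years,
        n_replicates=n_reps,
        demography=dem_params,
        dispersal=disp_params,
        master_seed=seed,
    )
    speeds = []
    for k in range(n_reps):
        traj = run_replicate(scenario, k)
        speeds.append(wave_speed(traj, (cx, cy)))
    return float(np.mean(speeds)), speeds


def calibrate_delta(
    target_speed_km_yr: float,
    dem_params: DemographyParams | None = None,
    grid: LandscapeGrid | None = None,
    n_reps: int = 5,
    seed: int = 0,
    years: int = 8,
    lo_km: float = 7.0,
    hi_km: float = 90.0,
    tol_km_yr: float = 3.0,
    max_iter: int = 12,
) -> float:
    """Bisect the mean dispersal distance so the simulated front speed matches
    ``target_speed_km_yr`` (within ``tol_km_yr``).

    Front speed is assumed (and asserted) monotone increasing in delta; common
    random numbers (the same master seed per evaluation) keep the evaluated
    speed function smooth in delta.
    """
    if target_speed_km_yr <= 0:
        raise ValueError("target speed must be positive")

    def speed(delta: float) -> float:
        m, _ = mean_wave_speed(
            dem_params, DispersalParams(delta_km=delta), n_reps=n_reps,
            years=years, seed=seed, grid=grid,
        )
        return m

    s_lo, s_hi = speed(lo_km), speed(hi_km)
    if not (s_lo < target_speed_km_yr < s_hi):
        raise ValueError(
            f"initial interval does not bracket the target: speed({lo_km}) = "
            f"{s_lo:.1f}, speed({hi_km}) = {s_hi:.1f}, target {target_speed_km_yr}"
        )
    lo, hi = lo_km, hi_km
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s_mid = speed(mid)
        if abs(s_mid - target_speed_km_yr) <= tol_km_yr:
            return mid
        if s_mid < target_speed_km_yr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
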