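"""Detection-and-destruction control policies and policy experiments.

Each year from ``start_year`` onward, every active nest is independently
detected with probability ``p_detect`` (in practice the product of spotting
foraging hornets at an apiary and back-tracing the flight path to the nest).
Optionally, each primarily-detected nest triggers one radial search: every
other active nest within ``search_radius_km`` is found with probability
``search_efficiency`` (searches triggered by radially-found nests do not
chain unless ``chain_searches`` is set).  Detected nests are destroyed before
queen production, so they contribute no foundresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .dispersal import acceptance_field
from .engine import Scenario, YearState, run_replicate
from .landscape import LandscapeGrid

__all__ = [
    "ControlPolicy",
    "InvasionPressure",
    "apply_control",
    "eradication_probability",
    "time_to_colonisation",
    "ColonisationResult",
]


@dataclass(frozen=True)
class ControlPolicy:
    """p_detect: annual per-nest detection probability; start_year: 1 if
    surveillance begins in the invasion year, 2 if the founder nest went
    unnoticed for a year; search_radius_km: 0 disables radial searches;
    search_efficiency: per-nest detection probability within a search."""

    p_detect: float
    start_year: int = 1
    search_radius_km: float = 0.0
    search_efficiency: float = 0.99
    chain_searches: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_detect <= 1.0):
            raise ValueError("p_detect must be in [0, 1]")
        if not (0.0 <= self.search_efficiency <= 1.0):
            raise ValueError("search_efficiency must be in [0, 1]")
        if self.search_radius_km < 0:
            raise ValueError("search_radius_km must be >= 0")
        if self.start_year < 1:
            raise ValueError("start_year must be >= 1")


def apply_control(
    state: YearState,
    policy: ControlPolicy,
    year: int,
    rng: np.random.Generator,
) -> YearState:
    """Mark nests detected this year as destroyed (before reproduction)."""
    if year < policy.start_year or state.n_active == 0 or policy.p_detect == 0.0:
        return state

    act_idx = np.flatnonzero(state.active)
    m = act_idx.size
    primary = rng.random(m) < policy.p_detect
    detected = primary.copy()

    if policy.search_radius_km > 0 and policy.search_efficiency > 0:
        frontier = primary
        # one search round per primarily-detected nest; optional chaining
        while frontier.any():
            sx = state.x[act_idx[frontier]]
            sy = state.y[act_idx[frontier]]
            targets = np.flatnonzero(~detected)
            if targets.size == 0:
                break
            tx = state.x[act_idx[targets]]
            ty = state.y[act_idx[targets]]
            # number of searching nests covering each target
            d2 = (tx[:, None] - sx[None, :]) ** 2 + (ty[:, None] - sy[None, :]) ** 2
            k = (d2 <= policy.search_radius_km**2).sum(axis=1)
            p_found = 1.0 - (1.0 - policy.search_efficiency) ** k
            found = rng.random(targets.size) < p_found
            newly = np.zeros(m, dtype=bool)
            newly[targets[found]] = True
            detected |= newly
            frontier = newly if policy.chain_searches else np.zeros(m, dtype=bool)

    if not detected.any():
        return state
    active = state.active.copy()
    active[act_idx[detected]] = False
    return replace_state_active(state, active)


def replace_state_active(state: YearState, active: np.ndarray) -> YearState:
    return YearState(
        year=state.year, x=state.x, y=state.y, id=state.id,
        parent=state.parent, active=active,
    )


def eradication_probability(
    scenario: Scenario,
    policy: Optional[ControlPolicy],
    n_reps: int,
) -> float:
    """Fraction of replicates with zero active nests at or before the horizon."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scen = replace(scenario, control=policy, n_replicates=n_reps)
    extinct = 0
    for k in range(n_reps):
        traj = run_replicate(scen, k)
        if not traj.survived:
            extinct += 1
    return extinct / n_reps


@dataclass(frozen=True)
class InvasionPressure:
    """Constant Poisson rate of new, independent founder-nest arrivals;
    arrival locations are suitability-weighted over the landscape."""

    rate_per_year: float

    def __post_init__(self) -> None:
        if self.rate_per_year < 0:
            raise ValueError("invasion rate must be >= 0")


@dataclass
class ColonisationResult:
    """Mean waiting time until the first invasion that control fails to
    eradicate, right-censored at the observation window."""

    mean_years: float
    censored_fraction: float
    times: np.ndarray
    censored: np.ndarray

    @property
    def permanent_exclusion(self) -> bool:
        """All replicates censored: no invasion ever colonised."""
        return bool(self.censored.all())


def _suitability_seed(grid: LandscapeGrid, weights, rng: np.random.Generator):
    alpha = acceptance_field(grid, weights).ravel()
    cell = rng.choice(alpha.size, p=alpha / alpha.sum())
    row, col = divmod(int(cell), grid.n_cols)
    h = grid.cell_size_km
    return (
        grid.origin_x_km + (col + rng.random()) * h,
        grid.origin_y_km + (row + rng.random()) * h,
    )


def time_to_colonisation(
    pressure: InvasionPressure,
    policy: Optional[ControlPolicy],
    scenario_template: Scenario,
    n_reps: int,
    rng: np.random.Generator,
    window_years: float = 200.0,
) -> ColonisationResult:
    """Expected time to successful colonisation under repeated invasions.

    Invasions arrive as a Poisson process; each is simulated independently
    under the control policy (control of concurrent invasions is treated
    independently).  Colonisation is the first arriving invasion whose lineage
    is not eradicated by the horizon; its arrival time is the colonisation
    time, right-censored at ``window_years``.
    """
    times = np.empty(n_reps)
    censored = np.zeros(n_reps, dtype=bool)
    for i in range(n_reps):
        t = 0.0
        while True:
            if pressure.rate_per_year == 0.0:
                t, is_censored = window_years, True
                break
            t += rng.exponential(1.0 / pressure.rate_per_year)
            if t > window_years:
                t, is_censored = window_years, True
                break
            seed_xy = _suitability_seed(
                scenario_template.grid, scenario_template.weights, rng
            )
            scen = replace(
                scenario_template,
                seeds=[seed_xy],
                founder_field=None,
                control=policy,
                n_replicates=1,
                master_seed=int(rng.integers(2**31)),
            )
            traj = run_replicate(scen, 0)
            if traj.survived:
                is_censored = False
                break
        times[i] = t
        censored[i] = is_censored
    return ColonisationResult(
        mean_years=float(times.mean()),
        censored_fraction=float(censored.mean()),
        times=times,
        censored=censored,
    )
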