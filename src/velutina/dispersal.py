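"""Queen dispersal and habitat-weighted settlement.

A dispersing queen draws a distance from an exponential distribution (mean
``delta_km``, calibrated so the simulated invasion front matches reported
European wave speeds) and a uniform direction.  She accepts the destination
cell with probability weight(class)/max(weight); water, off-grid destinations
and rejected habitat cause a complete re-draw of the displacement, up to
``max_attempts`` attempts, after which she founds no nest.  Re-drawing the
full displacement (rather than snapping to the nearest suitable cell)
preserves the exponential marginal distance distribution on homogeneous
landscapes.

The analytic counterpart, :func:`settlement_kernel`, integrates the 2-D
displacement density f(d) / (2 pi d) cell-wise and applies the same acceptance
model, giving a discrete distribution over destination cells plus an explicit
failure mass.  The deterministic risk-map calculations are built on top of it
via FFT convolution (see :mod:`velutina.riskmap`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .landscape import LandscapeGrid, SuitabilityWeights

__all__ = [
    "DispersalParams",
    "CellKernel",
    "sample_displacement",
    "settle",
    "settle_many",
    "settlement_kernel",
    "SettlementKernel",
    "acceptance_field",
    "single_draw_acceptance",
    "retry_factor",
]


@dataclass(frozen=True)
class DispersalParams:
    """delta_km: mean dispersal distance; max_attempts: settlement re-draws."""

    delta_km: float = 28.0
    max_attempts: int = 20

    def __post_init__(self) -> None:
        if self.delta_km <= 0:
            raise ValueError("delta_km must be positive")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def sample_displacement(
    params: DispersalParams, rng: np.random.Generator, size: int | None = None
):
    """Random displacement(s): exponential distance, uniform angle."""
    n = 1 if size is None else size
    d = rng.exponential(params.delta_km, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dx = d * np.cos(theta)
    dy = d * np.sin(theta)
    if size is None:
        return float(dx[0]), float(dy[0])
    return dx, dy


def settle_many(
    origin_x,
    origin_y,
    grid: LandscapeGrid,
    weights: SuitabilityWeights,
    params: DispersalParams,
    rng: np.random.Generator,
):
    """Vectorised settlement of many queens.

    Returns (x, y, settled) where ``settled`` marks queens that founded a
    nest within ``max_attempts`` displacement draws from their origin.
    """
    ox = np.asarray(origin_x, dtype=float)
    oy = np.asarray(origin_y, dtype=float)
    n = ox.size
    out_x = np.full(n, np.nan)
    out_y = np.full(n, np.nan)
    settled = np.zeros(n, dtype=bool)
    accept_lut = weights.acceptance_lookup()

    pending = np.arange(n)
    for _ in range(params.max_attempts):
        m = pending.size
        if m == 0:
            break
        dx, dy = sample_displacement(params, rng, size=m)
        tx = ox[pending] + dx
        ty = oy[pending] + dy
        ok = np.zeros(m, dtype=bool)
        inside = grid.contains(tx, ty)
        if inside.any():
            codes = grid.class_at(tx[inside], ty[inside])
            accept_p = accept_lut[codes]
            ok[inside] = rng.random(int(inside.sum())) < accept_p
        idx = pending[ok]
        out_x[idx] = tx[ok]
        out_y[idx] = ty[ok]
        settled[idx] = True
        pending = pending[~ok]
    return out_x, out_y, settled


def settle(
    origin,
    grid: LandscapeGrid,
    weights: SuitabilityWeights,
    params: DispersalParams,
    rng: np.random.Generator,
) -> Optional[tuple[float, float]]:
    """Settle a single queen from ``origin``; None means settlement failed."""
    if not np.all(grid.contains(origin[0], origin[1])):
        raise ValueError("origin must lie inside the grid")
    x, y, ok = settle_many(
        np.array([origin[0]]), np.array([origin[1]]), grid, weights, params, rng
    )
    return (float(x[0]), float(y[0])) if ok[0] else None


# ---------------------------------------------------------------------------
# Analytic cell-integrated kernel
# ---------------------------------------------------------------------------


class CellKernel:
    """Cell-integrated probability of a single displacement draw.

    ``prob[i, j]`` is the probability that a queen's displacement lands in the
    cell offset (i - R, j - R) rows/cols from her origin cell's centre.  The
    2-D point density f(d)/(2 pi d) is integrated by the midpoint rule, with a
    sub-cell refinement near the origin and an exact radial CDF over the
    origin cell's equivalent radius (which removes the d -> 0 singularity).
    The kernel is truncated at ``trunc_factor`` mean dispersal distances; the
    analytic tail mass beyond the truncation is carried as automatic rejection
    so all probabilities remain exact up to discretisation.
    """

    def __init__(
        self,
        cell_km: float,
        delta_km: float,
        trunc_factor: float = 6.0,
        near_subsample: int = 9,
    ):
        if cell_km <= 0 or delta_km <= 0:
            raise ValueError("cell size and delta must be positive")
        self.cell_km = cell_km
        self.delta_km = delta_km
        h = cell_km
        R = max(1, int(np.ceil(trunc_factor * delta_km / h)))
        self.radius_cells = R
        offs = np.arange(-R, R + 1)
        jj, ii = np.meshgrid(offs, offs)  # ii: row (y) offset, jj: col (x)
        d = np.hypot(ii, jj) * h

        def point_density(dist):
            dist = np.maximum(dist, 1e-12)
            return np.exp(-dist / delta_km) / (2.0 * np.pi * dist * delta_km)

        prob = h * h * point_density(d)

        # refine cells near the origin where the density varies strongly
        near = (d <= 4.0 * h) & (d > 0)
        if near.any():
            s = near_subsample
            sub = (np.arange(s) + 0.5) / s - 0.5  # sub-cell midpoints in cell units
            sy, sx = np.meshgrid(sub, sub)
            ni, nj = ii[near], jj[near]
            dist = np.hypot(
                (ni[:, None] + sy.ravel()[None, :]) * h,
                (nj[:, None] + sx.ravel()[None, :]) * h,
            )
            prob[near] = h * h * point_density(dist).mean(axis=1)

        # origin cell: exact CDF over the equal-area radius
        r_eq = h / np.sqrt(np.pi)
        prob[R, R] = 1.0 - np.exp(-r_eq / delta_km)

        disc = np.hypot(ii, jj) * h <= R * h
        prob[~disc] = 0.0
        self.support_mass = 1.0 - np.exp(-R * h / delta_km)
        prob *= self.support_mass / prob.sum()
        self.prob = prob
        self.tail_mass = 1.0 - self.support_mass

    def convolve(self, field: np.ndarray) -> np.ndarray:
        """Probability-weighted spread of ``field`` (same-shape convolution;
        mass crossing the grid boundary is dropped, i.e. off-grid)."""
        out = signal.oaconvolve(field, self.prob, mode="same")
        return np.clip(out, 0.0, None)


def acceptance_field(grid: LandscapeGrid, weights: SuitabilityWeights) -> np.ndarray:
    """Per-cell acceptance probability of a single settlement draw."""
    return weights.acceptance_lookup()[grid.classes]


def single_draw_acceptance(
    alpha: np.ndarray, kernel: CellKernel
) -> np.ndarray:
    """Probability that one displacement draw from each cell is accepted."""
    return np.clip(kernel.convolve(alpha), 0.0, 1.0)


def retry_factor(a: np.ndarray, max_attempts: int) -> np.ndarray:
    """Expected amplification of per-draw settlement probability over up to
    ``max_attempts`` re-draws: (1 - (1-a)^m) / a, with the a -> 0 limit m."""
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 - (1.0 - a) ** max_attempts) / a
    return np.where(a > 1e-12, out, float(max_attempts))


@dataclass
class SettlementKernel:
    """Discrete settlement distribution from one origin cell: ``probs`` is a
    grid-shaped array of per-cell settlement probabilities and ``fail`` the
    probability that the queen founds no nest; together they sum to 1."""

    probs: np.ndarray
    fail: float

    def total(self) -> float:
        return float(self.probs.sum() + self.fail)


def settlement_kernel(
    origin_cell: tuple[int, int],
    grid: LandscapeGrid,
    weights: SuitabilityWeights,
    params: DispersalParams,
    kernel: CellKernel | None = None,
) -> SettlementKernel:
    """Analytic settlement distribution for a queen leaving ``origin_cell``.

    Probability of settling in cell y from origin x:
        T(x -> y) = alpha(y) f(y - x) * (1 - (1 - a(x))^m) / a(x)
    where f is the cell-integrated displacement kernel, alpha the habitat
    acceptance probability, a(x) = sum_y f(y-x) alpha(y) the single-draw
    acceptance, and m the attempt cap.  The failure mass is (1 - a(x))^m.
    """
    row, col = origin_cell
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise ValueError("origin cell outside grid")
    kernel = kernel or CellKernel(grid.cell_size_km, params.delta_km)
    alpha = acceptance_field(grid, weights)

    R = kernel.radius_cells
    r0, r1 = max(0, row - R), min(grid.n_rows, row + R + 1)
    c0, c1 = max(0, col - R), min(grid.n_cols, col + R + 1)
    win = kernel.prob[
        (r0 - row + R) : (r1 - row + R), (c0 - col + R) : (c1 - col + R)
    ]
    f = np.zeros_like(alpha, dtype=float)
    f[r0:r1, c0:c1] = win

    a = float((f * alpha).sum())
    fail = (1.0 - a) ** params.max_attempts
    probs = alpha * f * retry_factor(np.array(a), params.max_attempts)
    return SettlementKernel(probs=probs, fail=float(fail))
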