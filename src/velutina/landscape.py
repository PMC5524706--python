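"""Landscape representation, ESRI ASCII raster I/O and synthetic landscape generation.

Coordinates are projected kilometres with y = northing.  Internally the class
matrix is stored row-major with row 0 the *southernmost* row; ESRI ASCII files
store the northernmost row first, so I/O flips the matrix.  Latitude is an
affine function of northing (default 111 km per degree), which preserves the
one geographic property the model uses: a linear north-south gradient in
reproductive success.

Nests carry continuous coordinates; cells only classify habitat.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage


class HabitatClass(enum.IntEnum):
    """Minimal habitat classification: urban and agricultural terrain is
    preferred by nesting queens, water can never host a nest.  Real land-cover
    rasters (e.g. Corine) must be re-mapped to these five codes by the user."""

    URBAN = 1
    AGRICULTURAL = 2
    WOODLAND = 3
    OTHER = 4
    WATER = 5


_VALID_CODES = frozenset(int(c) for c in HabitatClass)

DEFAULT_KM_PER_DEGREE_LAT = 111.0


@dataclass(frozen=True)
class SuitabilityWeights:
    """Relative settlement preference per habitat class.

    Weights are relative preferences (rescaled by the maximum weight when used
    as acceptance probabilities), not absolute survival probabilities.  Water
    must have weight 0; at least one class must be settleable.
    """

    urban: float = 1.0
    agricultural: float = 1.0
    woodland: float = 0.5
    other: float = 0.25
    water: float = 0.0

    def __post_init__(self) -> None:
        if self.water != 0.0:
            raise ValueError("water must have settlement weight 0")
        w = self.as_array()
        if np.any(w < 0):
            raise ValueError("suitability weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("at least one habitat class must have weight > 0")

    def as_array(self) -> np.ndarray:
        """Weights indexed by habitat code (index 0 unused)."""
        out = np.zeros(max(_VALID_CODES) + 1)
        out[HabitatClass.URBAN] = self.urban
        out[HabitatClass.AGRICULTURAL] = self.agricultural
        out[HabitatClass.WOODLAND] = self.woodland
        out[HabitatClass.OTHER] = self.other
        out[HabitatClass.WATER] = self.water
        return out

    @property
    def max_weight(self) -> float:
        return float(self.as_array().max())

    def acceptance_lookup(self) -> np.ndarray:
        """Per-code settlement acceptance probability weight/max(weight)."""
        w = self.as_array()
        return w / w.max()


@dataclass
class LandscapeGrid:
    """Raster of habitat classes on a projected-km frame.

    ``classes`` is (n_rows, n_cols) with row 0 the southernmost row;
    ``origin_x_km``/``origin_y_km`` locate the lower-left (south-west) corner.
    """

    classes: np.ndarray
    cell_size_km: float
    origin_x_km: float = 0.0
    origin_y_km: float = 0.0
    lat_at_origin_deg: float = 49.5
    km_per_degree_lat: float = DEFAULT_KM_PER_DEGREE_LAT
    nodata_value: int = -9999

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.ndim != 2 or self.classes.size == 0:
            raise ValueError("classes must be a non-empty 2-D matrix")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.km_per_degree_lat <= 0:
            raise ValueError("km_per_degree_lat must be positive")
        bad = ~np.isin(self.classes, list(_VALID_CODES))
        if bad.any():
            raise ValueError(
                f"invalid habitat codes in grid: {np.unique(self.classes[bad])!r}"
            )

    # --- shape / frame -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.classes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    @property
    def width_km(self) -> float:
        return self.n_cols * self.cell_size_km

    @property
    def height_km(self) -> float:
        return self.n_rows * self.cell_size_km

    def contains(self, x_km, y_km) -> np.ndarray:
        """Vectorised point-in-raster test."""
        x = np.asarray(x_km)
        y = np.asarray(y_km)
        return (
            (x >= self.origin_x_km)
            & (x < self.origin_x_km + self.width_km)
            & (y >= self.origin_y_km)
            & (y < self.origin_y_km + self.height_km)
        )

    def cell_of(self, x_km, y_km) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; caller must ensure
        the points are inside the grid (see :meth:`contains`)."""
        col = np.floor((np.asarray(x_km) - self.origin_x_km) / self.cell_size_km)
        row = np.floor((np.asarray(y_km) - self.origin_y_km) / self.cell_size_km)
        return row.astype(np.int64), col.astype(np.int64)

    def class_at(self, x_km, y_km) -> np.ndarray:
        row, col = self.cell_of(x_km, y_km)
        return self.classes[row, col]

    def is_water(self, x_km, y_km) -> np.ndarray:
        return self.class_at(x_km, y_km) == HabitatClass.WATER

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(y_km of row centres, x_km of column centres)."""
        h = self.cell_size_km
        ys = self.origin_y_km + (np.arange(self.n_rows) + 0.5) * h
        xs = self.origin_x_km + (np.arange(self.n_cols) + 0.5) * h
        return ys, xs

    def row_latitudes(self) -> np.ndarray:
        """Latitude (degrees N) of each row's cell centres."""
        ys, _ = self.cell_centers()
        return self.latitude_of(ys)

    def latitude_of(self, y_km) -> np.ndarray:
        return latitude_of(self, y_km)

    def proportions(self) -> dict[str, float]:
        """Realised class proportions."""
        n = self.classes.size
        return {
            c.name.lower(): float(np.count_nonzero(self.classes == c)) / n
            for c in HabitatClass
        }


def latitude_of(grid: LandscapeGrid, y_km) -> np.ndarray:
    """Latitude (degrees north) at northing ``y_km``: affine in y."""
    y = np.asarray(y_km, dtype=float)
    return grid.lat_at_origin_deg + (y - grid.origin_y_km) / grid.km_per_degree_lat


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def read_grid(
    path,
    lat_at_origin_deg: float = 49.5,
    km_per_degree_lat: float = DEFAULT_KM_PER_DEGREE_LAT,
) -> LandscapeGrid:
    """Read an ESRI ASCII grid of habitat codes.

    The first file row is the northernmost; internally row 0 is the
    southernmost, so rows are flipped on read.  NODATA cells map to water.
    The latitude frame is not part of the .asc dialect and is supplied by the
    caller.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    header: dict[str, float] = {}
    pos = 0
    for key in _HEADER_KEYS:
        if pos + 1 >= len(tokens) or tokens[pos].lower() != key.lower():
            raise ValueError(
                f"malformed ESRI ASCII header in {path!s}: expected key "
                f"{key!r}, found {tokens[pos] if pos < len(tokens) else '<eof>'!r}"
            )
        try:
            header[key] = float(tokens[pos + 1])
        except ValueError as exc:
            raise ValueError(f"non-numeric header value for {key!r} in {path!s}") from exc
        pos += 2
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = int(header["NODATA_value"])
    data = tokens[pos:]
    if len(data) != nrows * ncols:
        raise ValueError(
            f"{path!s}: expected {nrows * ncols} data values "
            f"({nrows} rows x {ncols} cols), found {len(data)}"
        )
    try:
        values = np.array([int(t) for t in data], dtype=np.int16).reshape(nrows, ncols)
    except ValueError as exc:
        raise ValueError(f"{path!s}: non-integer habitat code in data block") from exc
    values[values == nodata] = HabitatClass.WATER
    unknown = ~np.isin(values, list(_VALID_CODES))
    if unknown.any():
        raise ValueError(
            f"{path!s}: unknown habitat class codes {np.unique(values[unknown])!r}"
        )
    return LandscapeGrid(
        classes=values[::-1],  # file order: north first
        cell_size_km=header["cellsize"],
        origin_x_km=header["xllcorner"],
        origin_y_km=header["yllcorner"],
        lat_at_origin_deg=lat_at_origin_deg,
        km_per_degree_lat=km_per_degree_lat,
        nodata_value=nodata,
    )


def write_grid(grid: LandscapeGrid, path) -> None:
    """Write ``grid`` as an ESRI ASCII file readable by :func:`read_grid`."""

    def fmt(v: float) -> str:
        return repr(int(v)) if float(v).is_integer() else repr(float(v))

    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {fmt(grid.origin_x_km)}",
        f"yllcorner {fmt(grid.origin_y_km)}",
        f"cellsize {fmt(grid.cell_size_km)}",
        f"NODATA_value {grid.nodata_value}",
    ]
    for row in grid.classes[::-1]:  # northernmost row first
        lines.append(" ".join(str(int(v)) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_field(values: np.ndarray, grid: LandscapeGrid, path) -> None:
    """Write an arbitrary grid-shaped real field (e.g. an intensity field) as
    ESRI ASCII, sharing ``grid``'s frame."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.classes.shape:
        raise ValueError("field shape does not match grid")
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.origin_x_km!r}",
        f"yllcorner {grid.origin_y_km!r}",
        f"cellsize {grid.cell_size_km!r}",
        "NODATA_value -9999",
    ]
    for row in values[::-1]:
        lines.append(" ".join(f"{v:.8g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic landscape generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeSpec:
    """Target composition for a synthetic coastal landscape.

    ``proportions`` gives the target fraction of cells per class name
    (lower-case); classes left out default to 0 and any remainder becomes
    "other".  Water forms a contiguous coastline margin whose raggedness is
    set by ``coastline_irregularity`` (0 = straight margin).  ``patch_scale_km``
    is the correlation length of the habitat patches.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    proportions: Mapping[str, float] = field(default_factory=dict)
    patch_scale_km: float = 10.0
    coastline_irregularity: float = 0.5
    origin_x_km: float = 0.0
    origin_y_km: float = 0.0
    lat_at_origin_deg: float = 49.5
    km_per_degree_lat: float = DEFAULT_KM_PER_DEGREE_LAT

    def __post_init__(self) -> None:
        names = {c.name.lower() for c in HabitatClass}
        for key, val in self.proportions.items():
            if key not in names:
                raise ValueError(f"unknown habitat class {key!r}")
            if val < 0:
                raise ValueError(f"proportion for {key!r} must be non-negative")
        total = sum(self.proportions.values())
        if total > 1.0 + 1e-12:
            raise ValueError(f"class proportions sum to {total} > 1")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")


def _smooth_noise(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Standardised smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(sigma_cells, 1e-9))
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(spec: LandscapeSpec, seed: int) -> LandscapeGrid:
    """Generate a synthetic coastal landscape.

    Deterministic in (spec, seed).  Water occupies the cells with the lowest
    "inland score" (distance from the raster edge plus smooth noise), which
    produces a contiguous coastal margin; the remaining land is partitioned
    into patches by quantile-thresholding a second smooth field, so realised
    proportions match the spec up to cell rounding.
    """
    rng = np.random.default_rng(seed)
    shape = (spec.n_rows, spec.n_cols)
    n = spec.n_rows * spec.n_cols
    sigma = spec.patch_scale_km / spec.cell_size_km

    props = dict(spec.proportions)
    water_frac = props.pop("water", 0.0)

    classes = np.full(shape, int(HabitatClass.OTHER), dtype=np.int16)

    # Coastline: rank cells by distance-from-edge perturbed by smooth noise.
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    edge = np.minimum(
        np.minimum(rows, spec.n_rows - 1 - rows),
        np.minimum(cols, spec.n_cols - 1 - cols),
    ).astype(float)
    edge /= max(edge.max(), 1.0)
    score = edge + spec.coastline_irregularity * 0.15 * _smooth_noise(rng, shape, sigma)
    n_water = int(round(water_frac * n))
    if n_water > 0:
        flat = np.argsort(score, axis=None, kind="stable")
        classes.flat[flat[:n_water]] = HabitatClass.WATER

    # Land classes: quantile bands of an independent smooth field.
    land = np.flatnonzero(classes.flat != HabitatClass.WATER)
    if land.size:
        field_vals = _smooth_noise(rng, shape, sigma).flat[land]
        order = land[np.argsort(field_vals, kind="stable")]
        start = 0
        for name in ("urban", "agricultural", "woodland"):
            frac = props.get(name, 0.0)
            k = int(round(frac * n))
            classes.flat[order[start : start + k]] = HabitatClass[name.upper()]
            start += k
        # remainder stays OTHER

    return LandscapeGrid(
        classes=classes,
        cell_size_km=spec.cell_size_km,
        origin_x_km=spec.origin_x_km,
        origin_y_km=spec.origin_y_km,
        lat_at_origin_deg=spec.lat_at_origin_deg,
        km_per_degree_lat=spec.km_per_degree_lat,
    )


def homogeneous_landscape(
    width_km: float = 1200.0,
    height_km: float | None = None,
    cell_km: float = 4.0,
    habitat: HabitatClass = HabitatClass.AGRICULTURAL,
    lat_deg: float = 44.74,
) -> LandscapeGrid:
    """Uniform fully-suitable landscape at (numerically) constant latitude.

    Used for dispersal calibration against the French invasion wave: constant
    latitude is realised by a near-infinite km-per-degree scale, keeping
    latitude strictly increasing in y while varying by < 1e-6 degrees across
    the grid.
    """
    height_km = width_km if height_km is None else height_km
    n_cols = int(round(width_km / cell_km))
    n_rows = int(round(height_km / cell_km))
    classes = np.full((n_rows, n_cols), int(habitat), dtype=np.int16)
    return LandscapeGrid(
        classes=classes,
        cell_size_km=cell_km,
        lat_at_origin_deg=lat_deg,
        km_per_degree_lat=1e12,
    )


# Fixed geography used for the Great-Britain-like experiments: a ~560 x 740 km
# island with a ~50 km coastal water margin, spanning ~50.0-55.8 deg N of land
# so that the reproduction cline (zero at 55.9 N) covers the island.  The seed
# is part of the geography definition, not a per-run random choice.
_GB_SEED = 20160917
_GB_WIDTH_KM = 560.0
_GB_HEIGHT_KM = 740.0
GB_LAT_AT_ORIGIN = 49.55


def gb_like_landscape(cell_km: float = 2.0, seed: int = _GB_SEED) -> LandscapeGrid:
    """Synthetic Great-Britain-like island used by the risk-map experiments."""
    spec = LandscapeSpec(
        n_rows=int(round(_GB_HEIGHT_KM / cell_km)),
        n_cols=int(round(_GB_WIDTH_KM / cell_km)),
        cell_size_km=cell_km,
        proportions={
            "water": 0.30,
            "urban": 0.07,
            "agricultural": 0.38,
            "woodland": 0.12,
        },
        patch_scale_km=15.0,
        coastline_irregularity=0.6,
        lat_at_origin_deg=GB_LAT_AT_ORIGIN,
    )
    return generate_landscape(spec, seed)
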