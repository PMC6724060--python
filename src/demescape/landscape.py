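"""Landscape rasters, suitability lattices and sampling localities.

The habitat model is deliberately minimal: a raster of elevations (meters
a.s.l.) is thresholded once — cells at or above ``threshold_m`` (default
1400 m, the lower limit of the species' alpine habitat) are suitable demes,
everything else (including NODATA cells) is permanently unsuitable.  Suitable
cells are enumerated row-major into contiguous deme ids, and a von Neumann
(4-cell) stepping-stone neighbourhood connects them; an 8-cell Moore
neighbourhood is available as an option.

Coordinate convention: 0-based ``(row, col)`` with row 0 the top line of the
raster, matching ESRI ASCII reading order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, PlacementError

__all__ = [
    "Landscape",
    "DemeGrid",
    "SamplingConfig",
    "read_ascii_grid",
    "write_ascii_grid",
    "make_deme_grid",
    "neighbors",
    "read_locality_csv",
    "write_locality_csv",
    "validate_locality_table",
    "map_localities",
]

#: Column order of a locality table CSV.
LOCALITY_COLUMNS = ["name", "acronym", "sample_size", "group", "row", "col", "is_origin"]

# Deterministic neighbour offsets: N, S, W, E first, diagonals after.
_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class Landscape:
    """An elevation raster with ESRI ASCII grid metadata.

    ``cell_size_km2`` is the deme area used by the demographic model
    (0.1 km^2 by default); it is independent of the file's ``cellsize``
    header, which is kept verbatim for faithful round-tripping.
    """

    n_rows: int
    n_cols: int
    elevation: np.ndarray
    nodata_value: float = -9999.0
    cell_size_km2: float = 0.1
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 316.227766  # ~sqrt(0.1 km^2) in meters

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != (self.n_rows, self.n_cols):
            raise ConfigurationError(
                f"elevation shape {self.elevation.shape} != ({self.n_rows}, {self.n_cols})"
            )
        if not self.cell_size_km2 > 0:
            raise ConfigurationError("cell_size_km2 must be positive")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.elevation == self.nodata_value


def read_ascii_grid(path) -> Landscape:
    """Read an ESRI ASCII grid (.asc) into a :class:`Landscape`.

    The six canonical headers (``ncols``, ``nrows``, ``xllcorner``,
    ``yllcorner``, ``cellsize``, ``NODATA_value``) are required except for
    NODATA, which defaults to -9999 as in the format specification.
    """
    with open(path) as fh:
        text = fh.read()
    return _parse_ascii_grid(text)


def _parse_ascii_grid(text: str) -> Landscape:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"bad header line: {lines[i]!r}") from exc
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"missing required ASCII grid header {key!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    if n_cols <= 0 or n_rows <= 0:
        raise FormatError("ncols and nrows must be positive")
    nodata = header.get("nodata_value", -9999.0)
    rows = []
    for ln in lines[i:]:
        vals = ln.split()
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise FormatError(f"non-numeric raster value in line {ln!r}") from exc
    if len(rows) != n_rows:
        raise FormatError(f"expected {n_rows} raster rows, found {len(rows)}")
    for r, vals in enumerate(rows):
        if len(vals) != n_cols:
            raise FormatError(f"row {r} has {len(vals)} values, expected {n_cols}")
    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        elevation=np.array(rows, dtype=float),
        nodata_value=nodata,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header["cellsize"],
    )


def write_ascii_grid(landscape: Landscape, path) -> None:
    """Write a :class:`Landscape` back to ESRI ASCII format."""
    buf = io.StringIO()
    buf.write(f"ncols {landscape.n_cols}\n")
    buf.write(f"nrows {landscape.n_rows}\n")
    buf.write(f"xllcorner {landscape.xllcorner:.10g}\n")
    buf.write(f"yllcorner {landscape.yllcorner:.10g}\n")
    buf.write(f"cellsize {landscape.cellsize:.10g}\n")
    buf.write(f"NODATA_value {landscape.nodata_value:.10g}\n")
    for row in landscape.elevation:
        buf.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


@dataclass
class DemeGrid:
    """Boolean suitability lattice over a landscape with neighbour topology.

    ``deme_ids`` is implicit: suitable cells are numbered 0..n_demes-1 in
    row-major order; ``cell_to_deme`` maps each raster cell to its deme id
    (-1 for unsuitable cells) and ``deme_rows``/``deme_cols`` invert it.
    """

    landscape: Landscape
    threshold_m: float
    suitable: np.ndarray
    neighborhood: int = 4
    cell_to_deme: np.ndarray = field(init=False)
    deme_rows: np.ndarray = field(init=False)
    deme_cols: np.ndarray = field(init=False)
    nbr_indptr: np.ndarray = field(init=False)
    nbr_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        rows, cols = np.nonzero(self.suitable)
        self.deme_rows = rows.astype(np.int32)
        self.deme_cols = cols.astype(np.int32)
        self.cell_to_deme = np.full(self.suitable.shape, -1, dtype=np.int32)
        self.cell_to_deme[rows, cols] = np.arange(rows.size, dtype=np.int32)
        offsets = _OFFSETS_4 if self.neighborhood == 4 else _OFFSETS_8
        indptr = np.zeros(rows.size + 1, dtype=np.int64)
        idx: list[int] = []
        nr, nc = self.suitable.shape
        for d in range(rows.size):
            r, c = rows[d], cols[d]
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and self.suitable[rr, cc]:
                    idx.append(int(self.cell_to_deme[rr, cc]))
            indptr[d + 1] = len(idx)
        self.nbr_indptr = indptr
        self.nbr_indices = np.array(idx, dtype=np.int32)

    @property
    def n_demes(self) -> int:
        return int(self.deme_rows.size)

    def deme_at(self, row: int, col: int) -> int:
        """Deme id of a suitable cell; raises KeyError for unsuitable cells."""
        if not (0 <= row < self.suitable.shape[0] and 0 <= col < self.suitable.shape[1]):
            raise KeyError(f"cell ({row}, {col}) outside the grid")
        d = int(self.cell_to_deme[row, col])
        if d < 0:
            raise KeyError(f"cell ({row}, {col}) is not a suitable deme")
        return d


def make_deme_grid(
    landscape: Landscape, threshold_m: float = 1400.0, neighborhood: int = 4
) -> DemeGrid:
    """Threshold a landscape into a suitability lattice.

    A cell is suitable iff its elevation is finite, not NODATA and at least
    ``threshold_m``.  Raises :class:`ConfigurationError` when no cell
    qualifies (an empty metapopulation cannot be simulated).
    """
    if not np.isfinite(threshold_m):
        raise ConfigurationError("threshold_m must be finite")
    if neighborhood not in (4, 8):
        raise ConfigurationError("neighborhood must be 4 or 8")
    elev = landscape.elevation
    suitable = (elev >= threshold_m) & ~landscape.nodata_mask & np.isfinite(elev)
    if not suitable.any():
        raise ConfigurationError(
            f"no suitable demes at threshold {threshold_m} m"
        )
    return DemeGrid(landscape=landscape, threshold_m=threshold_m,
                    suitable=suitable, neighborhood=neighborhood)


def neighbors(grid: DemeGrid, deme: int) -> list[int]:
    """Suitable neighbours of a deme, in deterministic N, S, W, E order."""
    if not 0 <= deme < grid.n_demes:
        raise KeyError(f"invalid deme id {deme}")
    lo, hi = grid.nbr_indptr[deme], grid.nbr_indptr[deme + 1]
    return [int(x) for x in grid.nbr_indices[lo:hi]]


def validate_locality_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the locality-table contract and normalise dtypes."""
    missing = [c for c in LOCALITY_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"locality table missing columns {missing}")
    table = table.copy()
    table["sample_size"] = table["sample_size"].astype(int)
    table["group"] = table["group"].astype(int)
    table["row"] = table["row"].astype(int)
    table["col"] = table["col"].astype(int)
    table["is_origin"] = table["is_origin"].astype(bool)
    if (table["sample_size"] <= 0).any():
        raise FormatError("sample sizes must be positive")
    if int(table["is_origin"].sum()) > 1:
        raise FormatError("at most one locality may be flagged is_origin")
    return table


def read_locality_csv(path) -> pd.DataFrame:
    return validate_locality_table(pd.read_csv(path))


def write_locality_csv(table: pd.DataFrame, path) -> None:
    validate_locality_table(table)[LOCALITY_COLUMNS].to_csv(path, index=False)


@dataclass
class SamplingConfig:
    """Localities resolved onto demes: the sampling design of a simulation."""

    deme_ids: np.ndarray     # int32, one entry per locality
    sample_sizes: np.ndarray  # int64
    groups: np.ndarray        # int64, 1..G
    names: list[str]
    origin_deme: int | None = None

    @property
    def total_samples(self) -> int:
        return int(self.sample_sizes.sum())

    @property
    def n_groups(self) -> int:
        return int(len(np.unique(self.groups))) if self.groups.size else 0


def map_localities(grid: DemeGrid, table: pd.DataFrame) -> SamplingConfig:
    """Resolve a locality table onto deme ids.

    Every locality must sit on a suitable cell; the total sample size and
    the group labels are preserved exactly.
    """
    table = validate_locality_table(table)
    deme_ids, origin = [], None
    for rec in table.itertuples(index=False):
        try:
            d = grid.deme_at(int(rec.row), int(rec.col))
        except KeyError as exc:
            raise PlacementError(
                f"locality {rec.name!r} at ({rec.row}, {rec.col}) is not on a suitable deme"
            ) from exc
        deme_ids.append(d)
        if rec.is_origin:
            origin = d
    return SamplingConfig(
        deme_ids=np.array(deme_ids, dtype=np.int32),
        sample_sizes=table["sample_size"].to_numpy(),
        groups=table["group"].to_numpy(),
        names=list(table["name"]),
        origin_deme=origin,
    )
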