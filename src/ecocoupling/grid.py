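"""Raster containers and zonal aggregation.

Every analysis stage operates on a single common grid. The two containers
here — :class:`Grid` for continuous layers (NPP, population density, climate
covariates) and :class:`CategoricalGrid` for the six-class land-cover legend —
carry a nodata mask that every statistic downstream must honour.
:func:`aggregate_to_units` collapses cell-level rasters onto a coarser lattice
of square analysis units (blocks), which is the spine joining all indices.

File I/O supports single-band GeoTIFF (via tifffile, with nodata in the
GDAL_NODATA tag and georeferencing in an ImageDescription JSON payload) and
the ESRI ASCII grid as a plain-text fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LEGEND",
    "Grid",
    "CategoricalGrid",
    "LegendError",
    "load_grid",
    "write_grid",
    "aggregate_to_units",
    "unit_table_to_csv",
    "unit_table_from_csv",
]

#: Default six-class land-cover legend (code -> class name).
LEGEND: dict[int, str] = {
    1: "farmland",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "desert",
}

_DEFAULT_NODATA = -9999.0


class LegendError(ValueError):
    """A categorical raster contains a code absent from the legend."""


@dataclass
class Grid:
    """A single continuous raster band.

    Parameters
    ----------
    values
        2D float array of cell values. Masked cells may hold any payload;
        they are excluded from every statistic.
    cell_size
        Edge length of a cell in linear map units (> 0).
    origin
        (x, y) map coordinates of the upper-left corner of the raster.
    nodata_mask
        Boolean array, same shape as ``values``; True marks nodata.
    crs_tag
        Opaque coordinate-reference identifier carried through I/O.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """Unmasked cell values as a flat array."""
        return self.values[~self.nodata_mask]

    def with_values(self, values: np.ndarray) -> "Grid":
        """Copy of this grid carrying new values, same mask and geometry."""
        return replace(self, values=np.asarray(values, dtype=float),
                       nodata_mask=self.nodata_mask.copy())


@dataclass
class CategoricalGrid:
    """A raster of land-cover class codes drawn from a fixed legend."""

    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValueError("CategoricalGrid codes must be 2D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.codes.shape:
            raise ValueError("codes and nodata_mask shapes differ")
        if len(self.legend) > 6:
            raise LegendError("legend has more than 6 entries")
        self.validate_codes()

    def validate_codes(self) -> None:
        present = np.unique(self.codes[~self.nodata_mask])
        for code in present:
            if int(code) not in self.legend:
                raise LegendError(f"code {int(code)} not in legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def class_proportions(self) -> dict[int, float]:
        """Proportion of unmasked cells per class code (sums to 1)."""
        valid = self.codes[~self.nodata_mask]
        if valid.size == 0:
            return {}
        codes, counts = np.unique(valid, return_counts=True)
        return {int(c): n / valid.size for c, n in zip(codes, counts)}


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _is_ascii(path: Path) -> bool:
    return path.suffix.lower() in {".asc", ".txt"}


def write_grid(grid: Grid | CategoricalGrid, path: str | Path) -> None:
    """Write a grid to GeoTIFF (default) or ESRI ASCII (.asc/.txt).

    Float payloads are stored as float32 and round-trip bit-identically;
    categorical payloads as int32. Nodata is encoded in the file header.
    """
    path = Path(path)
    if isinstance(grid, CategoricalGrid):
        data = grid.codes.astype(np.int32)
        nodata = int(_DEFAULT_NODATA)
    else:
        data = grid.values.astype(np.float32)
        nodata = _DEFAULT_NODATA
    data = data.copy()
    data[grid.nodata_mask] = nodata

    if _is_ascii(path):
        rows, cols = data.shape
        yll = grid.origin[1] - rows * grid.cell_size
        header = (
            f"ncols {cols}\nnrows {rows}\n"
            f"xllcorner {grid.origin[0]!r}\nyllcorner {yll!r}\n"
            f"cellsize {grid.cell_size!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.17g" if data.dtype.kind == "f" else "%d")
        return

    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "crs_tag": grid.crs_tag,
        "kind": "categorical" if isinstance(grid, CategoricalGrid) else "continuous",
    }
    nodata_str = repr(nodata).encode() + b"\x00"
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=[(42113, "s", len(nodata_str), nodata_str, True)],
    )


def load_grid(path: str | Path, kind: str = "continuous",
              legend: dict[int, str] | None = None) -> Grid | CategoricalGrid:
    """Load a single-band GeoTIFF or ESRI ASCII grid.

    Parameters
    ----------
    path
        File to read; format chosen by extension (.asc/.txt -> ASCII).
    kind
        ``"continuous"`` -> :class:`Grid`; ``"categorical"`` ->
        :class:`CategoricalGrid` with codes validated against ``legend``.
    """
    path = Path(path)
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown kind {kind!r}")
    if not path.exists():
        raise IOError(f"no such file: {path}")

    if _is_ascii(path):
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) == 2 and not _is_number(parts[0]):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            data = np.loadtxt(fh, ndmin=2)
        nodata = header.get("nodata_value", _DEFAULT_NODATA)
        cell_size = header.get("cellsize", 1.0)
        rows = data.shape[0]
        origin = (header.get("xllcorner", 0.0),
                  header.get("yllcorner", 0.0) + rows * cell_size)
        mask = np.isclose(data, nodata) | ~np.isfinite(data)
        meta = {"cell_size": cell_size, "origin": list(origin), "crs_tag": ""}
    else:
        try:
            with tifffile.TiffFile(path) as tif:
                page = tif.pages[0]
                data = page.asarray()
                desc = page.tags.get("ImageDescription")
                nodata_tag = page.tags.get(42113)
        except Exception as exc:  # noqa: BLE001 - map to I/O error per contract
            raise IOError(f"unreadable raster {path}: {exc}") from exc
        if data.ndim != 2:
            raise IOError(f"{path} is not a single-band raster")
        meta = {"cell_size": 1.0, "origin": [0.0, 0.0], "crs_tag": ""}
        if desc is not None:
            try:
                meta.update(json.loads(desc.value))
            except (json.JSONDecodeError, TypeError):
                pass
        nodata = _DEFAULT_NODATA
        if nodata_tag is not None:
            raw = nodata_tag.value
            if isinstance(raw, bytes):
                raw = raw.decode()
            nodata = float(str(raw).strip("\x00 "))
        data = np.asarray(data, dtype=float)
        mask = np.isclose(data, nodata) | ~np.isfinite(data)

    if kind == "categorical":
        return CategoricalGrid(
            codes=np.where(mask, 0, np.rint(data)).astype(int),
            legend=dict(legend) if legend is not None else dict(LEGEND),
            cell_size=float(meta["cell_size"]),
            origin=tuple(meta["origin"]),
            nodata_mask=mask,
            crs_tag=str(meta.get("crs_tag", "")),
        )
    return Grid(
        values=data,
        cell_size=float(meta["cell_size"]),
        origin=tuple(meta["origin"]),
        nodata_mask=mask,
        crs_tag=str(meta.get("crs_tag", "")),
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# Zonal aggregation onto the unit lattice
# ---------------------------------------------------------------------------

def _iter_blocks(shape: tuple[int, int], unit_cells: int):
    rows, cols = shape
    n_brow = int(np.ceil(rows / unit_cells))
    n_bcol = int(np.ceil(cols / unit_cells))
    for br in range(n_brow):
        for bc in range(n_bcol):
            r0, c0 = br * unit_cells, bc * unit_cells
            yield br, bc, (slice(r0, min(r0 + unit_cells, rows)),
                           slice(c0, min(c0 + unit_cells, cols)))


def unit_id_for(block_row: int, block_col: int, n_block_cols: int) -> int:
    """Row-major unit id on the block lattice."""
    return block_row * n_block_cols + block_col


def aggregate_to_units(grid: Grid | CategoricalGrid, unit_cells: int,
                       statistic: str = "mean", code: int | None = None,
                       column: str = "value") -> pd.DataFrame:
    """Collapse a raster onto square blocks of ``unit_cells`` x ``unit_cells``.

    Returns a UnitTable: one row per retained block with columns
    ``unit_id, block_row, block_col, <column>``. Blocks whose valid-cell
    count is at most half the nominal block size are dropped (mask-dominated
    or sliver edge blocks).

    ``statistic`` is one of ``mean``, ``sum``, ``mode`` or ``proportion_of``
    (the latter two for categorical grids; ``proportion_of`` needs ``code``).
    Mode ties break toward the smallest class code.
    """
    if unit_cells < 1:
        raise ValueError("unit_cells must be >= 1")
    categorical = isinstance(grid, CategoricalGrid)
    if statistic == "proportion_of":
        if not categorical:
            raise TypeError("proportion_of requires a categorical grid")
        if code is None:
            raise ValueError("proportion_of requires a class code")
    if statistic == "mode" and not categorical:
        raise TypeError("mode requires a categorical grid")

    data = grid.codes if categorical else grid.values
    nominal = unit_cells * unit_cells
    n_bcol = int(np.ceil(data.shape[1] / unit_cells))

    records = []
    for br, bc, sl in _iter_blocks(data.shape, unit_cells):
        block = data[sl]
        valid = ~grid.nodata_mask[sl]
        n_valid = int(valid.sum())
        if n_valid * 2 < nominal:  # > 50% masked (or sliver edge) -> drop
            continue
        vals = block[valid]
        if statistic == "mean":
            out = float(np.mean(vals))
        elif statistic == "sum":
            out = float(np.sum(vals))
        elif statistic == "mode":
            codes, counts = np.unique(vals, return_counts=True)
            out = int(codes[np.argmax(counts)])  # np.unique sorts -> smallest wins ties
        elif statistic == "proportion_of":
            out = float(np.mean(vals == code))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        records.append((unit_id_for(br, bc, n_bcol), br, bc, out))

    return pd.DataFrame(records,
                        columns=["unit_id", "block_row", "block_col", column])


def unit_table_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a UnitTable with the canonical header order."""
    lead = ["unit_id", "block_row", "block_col"]
    rest = [c for c in table.columns if c not in lead]
    table[lead + rest].to_csv(path, index=False)


def unit_table_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
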