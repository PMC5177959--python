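"""Raster data model, I/O and the coarse grid-frame lattice.

Conventions used throughout the package (stated once, used everywhere):

* pixel indexing is 0-based ``(row, col)``; row 0 is the northernmost row;
* cell extents are half-open ``[x, x + cell)`` in map units;
* a ``True`` entry in a nodata mask means the cell carries no observation
  and is excluded from every statistic.

Rasters are stored as TIFF planes with the grid geometry, band labels and
nodata value carried as a JSON document in the TIFF ``ImageDescription``
tag.  MOD09-style integer reflectance is rescaled at read time when the
metadata declares a ``scale_factor``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridGeometry",
    "BandStack",
    "ClassMap",
    "GridFrame",
    "Legend",
    "read_raster",
    "write_raster",
    "resample_mean",
    "resample_nearest",
    "build_grid_frame",
]


class Legend:
    """Integer legend shared by every classified plane in the package."""

    NODATA = 0
    DESERTIFIED = 1
    VEGETATION = 2
    OTHERS = 3

    NAMES = {
        NODATA: "nodata",
        DESERTIFIED: "desertified",
        VEGETATION: "vegetation",
        OTHERS: "others",
    }

    #: classes a valid (unmasked) pixel may carry
    VALID = (DESERTIFIED, VEGETATION, OTHERS)


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular north-up grid in a projected (metric) coordinate system.

    ``origin_x``/``origin_y`` locate the outer corner of pixel (0, 0); x
    grows eastward along columns and y decreases southward along rows.
    ``crs_tag`` is an opaque identifier; the package's own grids use
    ``"metre:local"`` and any tag containing ``"metre"`` or starting with
    ``"EPSG:32"`` is treated as metric.
    """

    origin_x: float
    origin_y: float
    cell_size_x: float
    cell_size_y: float
    n_rows: int
    n_cols: int
    crs_tag: str = "metre:local"

    def __post_init__(self) -> None:
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_metric(self) -> bool:
        return "metre" in self.crs_tag or self.crs_tag.startswith("EPSG:32")

    @property
    def cell_area_km2(self) -> float:
        if not self.is_metric:
            raise ValueError(
                f"geometry with crs_tag={self.crs_tag!r} is not metric; "
                "area accounting requires metre-based coordinates"
            )
        return self.cell_size_x * self.cell_size_y / 1e6

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size_x": self.cell_size_x,
            "cell_size_y": self.cell_size_y,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs_tag": self.crs_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(**d)

    def coarsen(self, factor_rows: int, factor_cols: int | None = None) -> "GridGeometry":
        """Geometry of the grid obtained by aggregating ``factor`` pixels per axis."""
        if factor_cols is None:
            factor_cols = factor_rows
        if self.n_rows % factor_rows or self.n_cols % factor_cols:
            raise ValueError(
                f"grid shape {self.shape} is not divisible by "
                f"factors ({factor_rows}, {factor_cols})"
            )
        return GridGeometry(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size_x=self.cell_size_x * factor_cols,
            cell_size_y=self.cell_size_y * factor_rows,
            n_rows=self.n_rows // factor_rows,
            n_cols=self.n_cols // factor_cols,
            crs_tag=self.crs_tag,
        )


def _integer_factor(coarse: float, fine: float) -> int:
    """Ratio coarse/fine if it is a (near-)exact positive integer, else raise."""
    ratio = coarse / fine
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"coarse cell size {coarse} is not an integer multiple of fine {fine}"
        )
    return factor


@dataclass
class BandStack:
    """Multiband raster: float planes sharing one geometry and nodata mask."""

    geometry: GridGeometry
    bands: np.ndarray  # (n_bands, n_rows, n_cols) float
    band_labels: list[str]
    nodata_mask: np.ndarray | None = None  # (n_rows, n_cols) bool, True = masked

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim == 2:
            self.bands = self.bands[None]
        if self.bands.shape[1:] != self.geometry.shape:
            raise ValueError(
                f"band shape {self.bands.shape[1:]} does not match geometry "
                f"{self.geometry.shape}"
            )
        if len(self.band_labels) != self.bands.shape[0]:
            raise ValueError("one label per band required")
        if len(set(self.band_labels)) != len(self.band_labels):
            raise ValueError("band labels must be unique")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.geometry.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.geometry.shape:
                raise ValueError("nodata mask shape does not match geometry")

    @property
    def n_bands(self) -> int:
        return int(self.bands.shape[0])

    def band(self, label_or_index: str | int) -> np.ndarray:
        if isinstance(label_or_index, str):
            idx = self.band_labels.index(label_or_index)
        else:
            idx = label_or_index
        return self.bands[idx]

    def masked(self) -> np.ndarray:
        """Bands with masked cells replaced by NaN (copy)."""
        out = self.bands.copy()
        out[:, self.nodata_mask] = np.nan
        return out


@dataclass
class ClassMap:
    """Integer label plane over a grid; values follow :class:`Legend`."""

    geometry: GridGeometry
    labels: np.ndarray  # (n_rows, n_cols) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("label plane shape does not match geometry")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != Legend.NODATA

    def class_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass
class GridFrame:
    """Coarse lattice linking fine classification maps to coarse pixels.

    ``cell_ids`` are unique integers assigned row-major starting at 1.
    ``proportions`` maps each legend class to a per-cell fraction plane; the
    fractions over valid classes sum to 1 for every cell that contains at
    least one unmasked fine pixel (``valid`` plane).
    """

    geometry: GridGeometry
    cell_ids: np.ndarray  # (n_rows, n_cols) int
    proportions: dict[int, np.ndarray] = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.cell_ids.shape != self.geometry.shape:
            raise ValueError("cell_ids shape does not match geometry")
        flat = self.cell_ids.ravel()
        if len(np.unique(flat)) != flat.size:
            raise ValueError("cell_ids must be unique")

    def cell_rowcol(self, cell_id: int) -> tuple[int, int]:
        pos = np.argwhere(self.cell_ids == cell_id)
        if pos.size == 0:
            raise KeyError(f"no cell with id {cell_id}")
        return int(pos[0, 0]), int(pos[0, 1])

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: cell_id, row, col and one proportion column per class."""
        rows, cols = np.indices(self.geometry.shape)
        data = {
            "cell_id": self.cell_ids.ravel(),
            "row": rows.ravel(),
            "col": cols.ravel(),
        }
        for cls, plane in sorted(self.proportions.items()):
            data[f"p_{Legend.NAMES.get(cls, cls)}"] = plane.ravel()
        if self.valid is not None:
            data["valid"] = self.valid.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O

_DESCRIPTION_KEY = "aeoscan_raster"


def write_raster(stack: BandStack, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a :class:`BandStack` as TIFF with JSON geometry metadata."""
    data = stack.bands.astype(np.float64).copy()
    data[:, stack.nodata_mask] = nodata
    meta = {
        _DESCRIPTION_KEY: {
            "geometry": stack.geometry.to_dict(),
            "band_labels": list(stack.band_labels),
            "nodata": nodata,
        }
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta), photometric="minisblack")


def read_raster(path: str | Path) -> BandStack:
    """Read a raster written by :func:`write_raster` (or a compatible TIFF).

    The TIFF must declare its geometry in the ``ImageDescription`` JSON;
    rasters without geometry metadata are rejected rather than silently
    assigned a default grid.  A declared ``nodata`` value is translated to
    the mask and a declared ``scale_factor`` (MOD09-style integer storage)
    is applied to the band values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)[_DESCRIPTION_KEY]
    except (json.JSONDecodeError, KeyError, TypeError):
        raise ValueError(
            f"{path} carries no grid geometry metadata; refusing to guess "
            "an origin/cell size"
        ) from None
    geometry = GridGeometry.from_dict(meta["geometry"])
    if data.ndim == 2:
        data = data[None]
    labels = meta.get("band_labels") or [f"band{i + 1}" for i in range(data.shape[0])]
    nodata = meta.get("nodata")
    mask = np.zeros(geometry.shape, dtype=bool)
    if nodata is not None:
        mask = np.any(data == nodata, axis=0) | np.any(np.isnan(data), axis=0)
    scale = meta.get("scale_factor")
    if scale is not None:
        data = data * float(scale)
    return BandStack(geometry=geometry, bands=data, band_labels=list(labels), nodata_mask=mask)


# ---------------------------------------------------------------------------
# Resampling and the grid frame


def _check_nesting(fine: GridGeometry, target: GridGeometry) -> tuple[int, int]:
    fr = _integer_factor(target.cell_size_y, fine.cell_size_y)
    fc = _integer_factor(target.cell_size_x, fine.cell_size_x)
    if abs(fine.origin_x - target.origin_x) > 1e-6 or abs(fine.origin_y - target.origin_y) > 1e-6:
        raise ValueError("fine and target grids must share an origin")
    if fine.n_rows != target.n_rows * fr or fine.n_cols != target.n_cols * fc:
        raise ValueError(
            f"target extent ({target.n_rows}x{target.n_cols} at factor {fr}x{fc}) "
            f"does not cover the fine grid ({fine.n_rows}x{fine.n_cols})"
        )
    return fr, fc


def _block_view(plane: np.ndarray, fr: int, fc: int) -> np.ndarray:
    r, c = plane.shape
    return plane.reshape(r // fr, fr, c // fc, fc).swapaxes(1, 2)


def resample_mean(stack: BandStack, target: GridGeometry) -> BandStack:
    """Block-mean aggregation onto a coarser, integer-nested grid.

    Each target cell is the mean of the covered unmasked source cells; a
    target cell is masked iff every covered cell is masked.  Over a fully
    unmasked extent the global mean is conserved exactly.
    """
    fr, fc = _check_nesting(stack.geometry, target)
    masked = stack.masked()
    out = np.empty((stack.n_bands, target.n_rows, target.n_cols))
    for b in range(stack.n_bands):
        blocks = _block_view(masked[b], fr, fc).reshape(target.n_rows, target.n_cols, -1)
        finite = ~np.isnan(blocks)
        counts = finite.sum(axis=-1)
        sums = np.where(finite, blocks, 0.0).sum(axis=-1)
        out[b] = np.divide(sums, counts, out=np.full(counts.shape, np.nan), where=counts > 0)
    out_mask = np.all(np.isnan(out), axis=0)
    out[:, out_mask] = 0.0
    return BandStack(
        geometry=target, bands=out, band_labels=list(stack.band_labels), nodata_mask=out_mask
    )


def resample_nearest(stack: BandStack, target: GridGeometry) -> BandStack:
    """Nearest-neighbour aggregation (top-left cell of each block).

    Intended for categorical planes where a mean is meaningless.
    """
    fr, fc = _check_nesting(stack.geometry, target)
    bands = stack.bands[:, ::fr, ::fc].copy()
    mask = stack.nodata_mask[::fr, ::fc].copy()
    return BandStack(
        geometry=target, bands=bands, band_labels=list(stack.band_labels), nodata_mask=mask
    )


def upsample(stack: BandStack, target: GridGeometry) -> BandStack:
    """Replicate each cell of ``stack`` over the finer, integer-nested ``target``."""
    fr, fc = _check_nesting(target, stack.geometry)
    bands = np.repeat(np.repeat(stack.bands, fr, axis=1), fc, axis=2)
    mask = np.repeat(np.repeat(stack.nodata_mask, fr, axis=0), fc, axis=1)
    return BandStack(
        geometry=target, bands=bands, band_labels=list(stack.band_labels), nodata_mask=mask
    )


def build_grid_frame(fine: GridGeometry, coarse_cell: float) -> GridFrame:
    """Lay a coarse lattice with unique cell identities over a fine grid.

    ``coarse_cell`` (map units) must be an integer multiple of both fine
    cell sizes and divide the fine extent exactly; ids are assigned
    row-major starting at 1, mirroring a vector grid frame where every
    cell carries a unique identity.
    """
    fr = _integer_factor(coarse_cell, fine.cell_size_y)
    fc = _integer_factor(coarse_cell, fine.cell_size_x)
    coarse = fine.coarsen(fr, fc)
    ids = np.arange(1, coarse.n_rows * coarse.n_cols + 1, dtype=np.int64).reshape(coarse.shape)
    return GridFrame(geometry=coarse, cell_ids=ids)
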