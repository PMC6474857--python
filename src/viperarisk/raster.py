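"""Gridded spatial layers.

A :class:`RasterGrid` is a single-band 2D grid with a simple geographic
georeference (top-left origin in degrees, square cells) and a nodata mask.
Row 0 is the northernmost row; all indexing is (row, col), 0-based.  A
:class:`PredictorStack` is an ordered, name-keyed set of RasterGrids sharing
one geometry and mask — the in-memory analogue of a directory of bioclim
layers.

Layers are read and written as ESRI ASCII grids (plain text, ``NODATA_value``
sentinel −9999), a format every GIS reads; stacks as a directory of ``.asc``
files plus a JSON manifest mapping layer name to file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .errors import AlignmentError, ConfigurationError

NODATA = -9999.0


@dataclass
class RasterGrid:
    """Single-band 2D grid with georeference and nodata mask.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values in layer units.  Entries under the mask are ignored.
    origin_lon, origin_lat : float
        Longitude/latitude of the grid's top-left corner, degrees.
    cell_size : float
        Cell edge length in degrees; must be positive.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no data.  Defaults to all-valid.
    """

    values: np.ndarray
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size: float = 0.01
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ConfigurationError("raster values must be a non-empty 2D array")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ConfigurationError("nodata mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ConfigurationError("non-finite values outside the nodata mask")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_aligned(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise AlignmentError(
                f"grids not aligned: {self.shape}@({self.origin_lon},{self.origin_lat},"
                f"{self.cell_size}) vs {other.shape}@({other.origin_lon},"
                f"{other.origin_lat},{other.cell_size})"
            )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell centre."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; may be out of bounds."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        row, col = self.cell_of(lon, lat)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid with the same geometry/mask but different values."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy(),
        )

    # -- I/O (ESRI ASCII grid) -------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        vals = self.values.copy()
        vals[self.nodata_mask] = NODATA
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_lon!r}\n"
            f"yllcorner {self.origin_lat - self.n_rows * self.cell_size!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {NODATA}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
        vals = vals.reshape(n_rows, n_cols)
        nodata = header.get("nodata_value", NODATA)
        mask = vals == nodata
        vals = np.where(mask, 0.0, vals)
        cell = header["cellsize"]
        return cls(
            values=vals,
            origin_lon=header["xllcorner"],
            origin_lat=header["yllcorner"] + n_rows * cell,
            cell_size=cell,
            nodata_mask=mask,
        )


@dataclass
class PredictorStack:
    """Ordered, name-keyed set of co-registered predictor layers."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("a predictor stack needs at least one layer")
        ref = self.reference
        for name, layer in self.layers.items():
            ref.require_aligned(layer)
            if not np.array_equal(ref.nodata_mask, layer.nodata_mask):
                raise ConfigurationError(f"layer {name!r} has a different nodata mask")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.reference.nodata_mask

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self.layers[name]
        except KeyError:
            raise ConfigurationError(f"no layer named {name!r} in stack") from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def subset(self, names: list[str]) -> "PredictorStack":
        return PredictorStack({n: self[n] for n in names})

    def as_table(self) -> np.ndarray:
        """Valid cells as an (n_valid, n_layers) array, row-major cell order."""
        valid = ~self.nodata_mask
        return np.column_stack([self[n].values[valid] for n in self.names])

    # -- I/O --------------------------------------------------------------
    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, layer in self.layers.items():
            fname = f"{name}.asc"
            layer.write_ascii(directory / fname)
            manifest[name] = fname
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def read_dir(cls, directory: str | Path) -> "PredictorStack":
        directory = Path(directory)
        manifest: Mapping[str, str] = json.loads(
            (directory / "manifest.json").read_text()
        )
        return cls(
            {name: RasterGrid.read_ascii(directory / f) for name, f in manifest.items()}
        )
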