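"""Plain-text raster I/O in the ESRI ASCII grid (.asc) format.

The format stores the grid geometry in a six-line header (cell registration
by the lower-left corner) followed by rows of values from north to south,
which matches the in-memory row order of :class:`~threatscape.grid.GridLayer`.
Any desktop GIS can read these files directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import ClassLayer, GridLayer, GridSpec

FLOAT_NODATA = -9999.0
CLASS_NODATA = 255


def write_ascii_grid(layer: GridLayer | ClassLayer, path: str | Path) -> None:
    path = Path(path)
    spec = layer.spec
    west, _, south, _ = spec.extent()
    if isinstance(layer, ClassLayer):
        nodata: float = CLASS_NODATA
        data = np.where(layer.mask, layer.classes, CLASS_NODATA).astype(int)
        fmt = "%d"
    else:
        nodata = FLOAT_NODATA
        data = np.where(layer.mask, layer.values, FLOAT_NODATA)
        fmt = "%.8g"
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {west!r}\n"
        f"yllcorner {south!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {nodata:g}"
    )
    with path.open("w") as fh:
        np.savetxt(fh, data, fmt=fmt, header=header, comments="")


def _read_raw(path: str | Path) -> tuple[GridSpec, np.ndarray, float]:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
    )
    data = np.atleast_2d(data)
    if data.shape != spec.shape:
        raise ValueError(f"data shape {data.shape} does not match header {spec.shape}")
    return spec, data, header.get("nodata_value", FLOAT_NODATA)


def read_ascii_grid(path: str | Path) -> GridLayer:
    spec, data, nodata = _read_raw(path)
    mask = data != nodata
    return GridLayer(spec, np.where(mask, data, 0.0), mask)


def read_ascii_classes(path: str | Path) -> ClassLayer:
    spec, data, nodata = _read_raw(path)
    mask = data != nodata
    return ClassLayer(spec, np.where(mask, data, 0).astype(int), mask)
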