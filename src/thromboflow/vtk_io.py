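"""Legacy-VTK structured-points (ASCII) and CSV field I/O.

Cell-centered fields are written as POINT_DATA on a lattice of points at the
cell centers (ORIGIN at (dx/2, dy/2), SPACING (dx, dy)); scalar arrays keep
their field names bit-stable ("velocity", "pressure", "viscosity", species
names) so exported runs re-import exactly to writer precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "write_structured_points",
    "read_structured_points",
    "write_csv_field",
    "read_csv_field",
]

_FMT = "%.17g"


def write_structured_points(path, dx, dy, fields: dict) -> None:
    """Write named cell fields to a legacy VTK structured-points file.

    ``fields`` maps name -> (ny, nx) scalar array or (ny, nx, 2|3) vector
    array.  Point index varies fastest in x, matching the VTK convention.
    """
    shapes = {np.asarray(a).shape[:2] for a in fields.values()}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent field shapes: {sorted(shapes)}")
    (ny, nx) = shapes.pop()
    n = nx * ny
    lines = [
        "# vtk DataFile Version 3.0",
        "thromboflow structured field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {dx / 2!r} {dy / 2!r} 0",
        f"SPACING {dx!r} {dy!r} 1",
        f"POINT_DATA {n}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr, dtype=float)
        if a.ndim == 2:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(_FMT % v for v in a.ravel(order="C"))
        elif a.ndim == 3 and a.shape[2] in (2, 3):
            vec = np.zeros((ny, nx, 3))
            vec[:, :, : a.shape[2]] = a
            lines.append(f"VECTORS {name} double")
            lines.extend(
                " ".join(_FMT % c for c in row) for row in vec.reshape(-1, 3)
            )
        else:
            raise FormatError(f"field {name!r} has unsupported shape {a.shape}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_structured_points(path):
    """Read a legacy VTK structured-points ASCII file written by this package.

    Returns ``(dx, dy, fields)`` with scalar fields as (ny, nx) arrays and
    vector fields as (ny, nx, 3).  Raises :class:`FormatError` naming the
    defect on malformed input.
    """
    with open(path) as fh:
        tokens = fh.read().split()

    def _find(key):
        for k, tok in enumerate(tokens):
            if tok == key:
                return k
        raise FormatError(f"{path}: missing {key} header")

    if "STRUCTURED_POINTS" not in tokens:
        raise FormatError(f"{path}: not a structured-points dataset")
    k = _find("DIMENSIONS")
    try:
        nx, ny, nz = (int(t) for t in tokens[k + 1 : k + 4])
    except ValueError as e:
        raise FormatError(f"{path}: bad DIMENSIONS: {e}") from None
    if nz != 1:
        raise FormatError(f"{path}: expected planar data, got nz={nz}")
    k = _find("SPACING")
    dx, dy = float(tokens[k + 1]), float(tokens[k + 2])
    k = _find("POINT_DATA")
    n = int(tokens[k + 1])
    if n != nx * ny:
        raise FormatError(f"{path}: POINT_DATA {n} != nx*ny = {nx * ny}")

    fields = {}
    pos = k + 2
    while pos < len(tokens):
        tok = tokens[pos]
        if tok == "SCALARS":
            name = tokens[pos + 1]
            ncomp = int(tokens[pos + 3]) if tokens[pos + 3].isdigit() else 1
            pos += 4 if tokens[pos + 3].isdigit() else 3
            if tokens[pos] == "LOOKUP_TABLE":
                pos += 2
            count = n * ncomp
            vals = np.array(tokens[pos : pos + count], dtype=float)
            if len(vals) != count:
                raise FormatError(f"{path}: truncated SCALARS {name!r}")
            fields[name] = vals.reshape(ny, nx)
            pos += count
        elif tok == "VECTORS":
            name = tokens[pos + 1]
            pos += 3
            count = n * 3
            vals = np.array(tokens[pos : pos + count], dtype=float)
            if len(vals) != count:
                raise FormatError(f"{path}: truncated VECTORS {name!r}")
            fields[name] = vals.reshape(ny, nx, 3)
            pos += count
        else:
            raise FormatError(f"{path}: unexpected token {tok!r} in data section")
    return dx, dy, fields


def write_csv_field(path, grid, fields: dict) -> None:
    """Write cell-centered scalars to CSV with x,y coordinate columns."""
    x, y = np.meshgrid(grid.x_centers(), grid.y_centers())
    data = {"x": x.ravel(), "y": y.ravel()}
    for name, arr in fields.items():
        data[name] = np.asarray(arr, dtype=float).ravel()
    pd.DataFrame(data).to_csv(path, index=False)


def read_csv_field(path):
    """Read an x,y,u,v[,pressure,...] CSV into ``(dx, dy, fields)``."""
    df = pd.read_csv(path)
    for col in ("x", "y", "u", "v"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    xs = np.unique(df["x"].to_numpy())
    ys = np.unique(df["y"].to_numpy())
    nx, ny = len(xs), len(ys)
    if nx < 2 or ny < 2:
        raise FormatError(f"{path}: needs at least a 2x2 lattice of points")
    if len(df) != nx * ny:
        raise FormatError(f"{path}: {len(df)} rows != {nx}x{ny} lattice")
    dxs, dys = np.diff(xs), np.diff(ys)
    if not (
        np.allclose(dxs, dxs[0], rtol=1e-6) and np.allclose(dys, dys[0], rtol=1e-6)
    ):
        raise FormatError(f"{path}: non-uniform grid spacing")
    dx, dy = float(dxs[0]), float(dys[0])
    order = np.lexsort((df["x"].to_numpy(), df["y"].to_numpy()))
    fields = {}
    vel = np.stack(
        [
            df["u"].to_numpy()[order].reshape(ny, nx),
            df["v"].to_numpy()[order].reshape(ny, nx),
        ],
        axis=-1,
    )
    fields["velocity"] = vel
    for col in df.columns:
        if col in ("x", "y", "u", "v"):
            continue
        fields[col] = df[col].to_numpy()[order].reshape(ny, nx)
    return dx, dy, fields
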