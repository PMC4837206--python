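"""Plain-text hyperspectral cube format: one TSV per plane + ``cube.json``.

A cube directory contains::

    cube.json                      # shape, z values, pixel size, metadata
    plane_0_z+0.00um.tsv           # first column wavenumber, then one column
    plane_1_z+0.50um.tsv           #   per pixel in row-major order
    ...

TSV dialect: tab separator, ``.`` decimal point, LF line endings, header
row ``wavenumber\tpx_0_0\tpx_0_1...``.  Intensities are written with 17
significant digits so float64 values round-trip bit-exactly.  The reader
accepts axes stored in either direction and always returns an ascending
in-memory axis.  Sample-preparation dialect (fixed/unfixed) is metadata
only — it is never inferred from the data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import DataError
from .stack import PlaneImage, ZStack, _ascending_axis

__all__ = ["write_cube", "read_cube", "CUBE_FORMAT_VERSION"]

CUBE_FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


def _plane_filename(k: int, z: float) -> str:
    return f"plane_{k}_z{z:+.2f}um.tsv"


def write_cube(stack: ZStack, path: str | Path) -> list[str]:
    """Write ``stack`` to directory ``path``; return the manifest of files.

    The stack is validated before anything touches the filesystem, so an
    inconsistent stack never leaves a partial cube behind.
    """
    # Re-run container invariants (axis/grid consistency) before any I/O.
    ZStack(stack.planes, stack.z_step, stack.metadata)
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create cube directory {path}: {exc}") from exc

    h, w = stack.planes[0].shape
    manifest: list[str] = []
    header = "wavenumber\t" + "\t".join(
        f"px_{r}_{c}" for r in range(h) for c in range(w)
    )
    for k, plane in enumerate(stack.planes):
        name = _plane_filename(k, plane.z)
        table = np.column_stack([stack.axis, plane.pixels().T])
        try:
            np.savetxt(
                path / name,
                table,
                fmt=_FLOAT_FMT,
                delimiter="\t",
                header=header,
                comments="",
                newline="\n",
            )
        except OSError as exc:
            raise DataError(f"cannot write plane file {path / name}: {exc}") from exc
        manifest.append(name)

    meta = {
        "format_version": CUBE_FORMAT_VERSION,
        "n_planes": stack.n_planes,
        "height": h,
        "width": w,
        "n_channels": int(stack.axis.size),
        "z_values_um": [float(p.z) for p in stack.planes],
        "z_step_um": float(stack.z_step),
        "pixel_size_um": float(stack.planes[0].pixel_size),
        "pixel_order": "row-major, origin top-left",
        "planes": manifest,
        "metadata": {
            k: v for k, v in stack.metadata.items() if _json_safe(v)
        },
    }
    with open(path / "cube.json", "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    manifest.append("cube.json")
    return manifest


def _json_safe(value: Any) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def read_cube(path: str | Path) -> ZStack:
    """Read a cube directory written by :func:`write_cube`."""
    path = Path(path)
    meta_path = path / "cube.json"
    if not meta_path.is_file():
        raise DataError(f"no cube.json in {path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != CUBE_FORMAT_VERSION:
        raise DataError(
            f"unsupported cube format_version {meta.get('format_version')!r} in {meta_path}"
        )
    h, w = int(meta["height"]), int(meta["width"])
    n_ch = int(meta["n_channels"])
    names = meta["planes"]
    if len(names) != int(meta["n_planes"]):
        raise DataError(
            f"cube.json declares {meta['n_planes']} planes but lists {len(names)} files"
        )

    planes: list[PlaneImage] = []
    for k, name in enumerate(names):
        fpath = path / name
        if not fpath.is_file():
            raise DataError(f"missing plane file {name} in {path}")
        frame = pd.read_csv(fpath, sep="\t")
        if frame.shape[1] != 1 + h * w:
            raise DataError(
                f"shape mismatch in {name}: expected {1 + h * w} columns, got {frame.shape[1]}"
            )
        if frame.shape[0] != n_ch:
            raise DataError(
                f"shape mismatch in {name}: expected {n_ch} rows, got {frame.shape[0]}"
            )
        values = frame.to_numpy(dtype=float)
        axis = values[:, 0]
        intensities = values[:, 1:].T.reshape(h, w, n_ch)
        axis, intensities = _ascending_axis(axis, intensities)
        planes.append(
            PlaneImage(
                axis,
                intensities,
                z=float(meta["z_values_um"][k]),
                pixel_size=float(meta["pixel_size_um"]),
            )
        )
    return ZStack(planes, float(meta["z_step_um"]), dict(meta.get("metadata", {})))
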