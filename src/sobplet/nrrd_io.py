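"""Minimal NRRD reader/writer for 3-D grids (ASCII encoding).

Covers exactly what the pipeline needs: 3-D float or binary-mask volumes
with spatial origin and spacing in the header, text-encoded so every
artifact stays a plain-text file.  Writes are atomic (temp file + rename).
Axis 0 is the fastest-varying axis in the raster, per the NRRD convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_nrrd", "write_nrrd"]


def write_nrrd(path, array: np.ndarray, origin=(0.0, 0.0, 0.0),
               spacing=(1.0, 1.0, 1.0)) -> None:
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValueError("only 3-D arrays are supported")
    origin = tuple(float(v) for v in origin)
    spacing = tuple(float(v) for v in spacing)
    kind = "int" if arr.dtype.kind in "bui" else "double"
    header = [
        "NRRD0004",
        "# generated by sobplet",
        f"type: {kind}",
        "dimension: 3",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        "encoding: ascii",
        "space: left-posterior-superior",
        f"space directions: ({spacing[0]},0,0) (0,{spacing[1]},0) (0,0,{spacing[2]})",
        f"space origin: ({origin[0]},{origin[1]},{origin[2]})",
        "",
    ]
    flat = arr.ravel(order="F")
    if kind == "int":
        body = "\n".join(str(int(v)) for v in flat)
    else:
        body = "\n".join(f"{float(v):.9g}" for v in flat)
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text("\n".join(header) + "\n" + body + "\n")
    tmp.replace(path)


def _parse_vector_list(text: str):
    vecs = []
    for chunk in text.replace(") (", ")|(").split("|"):
        nums = chunk.strip().strip("()").split(",")
        vecs.append(tuple(float(v) for v in nums))
    return vecs


def read_nrrd(path):
    """Returns (array, origin, spacing)."""
    text = Path(path).read_text()
    head, _, body = text.partition("\n\n")
    lines = head.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    fields = {}
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip()] = val.strip()
    if fields.get("encoding") != "ascii":
        raise ValueError("only ascii encoding is supported")
    sizes = tuple(int(v) for v in fields["sizes"].split())
    if len(sizes) != 3:
        raise ValueError("only 3-D volumes are supported")
    dtype = np.int64 if fields.get("type", "double") == "int" else np.float64
    data = np.fromiter((float(t) for t in body.split()), dtype=float).astype(dtype)
    if data.size != int(np.prod(sizes)):
        raise ValueError("data length does not match sizes field")
    arr = data.reshape(sizes, order="F")
    dirs = _parse_vector_list(fields.get("space directions",
                                         "(1,0,0) (0,1,0) (0,0,1)"))
    spacing = tuple(dirs[a][a] for a in range(3))
    origin = tuple(_parse_vector_list(fields.get("space origin", "(0,0,0)"))[0])
    return arr, origin, spacing
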