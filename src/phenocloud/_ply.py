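"""Minimal PLY 1.0 codec for point-cloud vertex data.

Supports ``format ascii 1.0`` and ``format binary_little_endian 1.0``,
scalar vertex properties only.  Elements other than ``vertex`` are ignored
on read (for binary files they may only appear *after* the vertex element,
which is where standard exporters place faces).
"""

from __future__ import annotations

import numpy as np

from .errors import LoadError

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_header(raw: bytes, path: str):
    """Return (format, elements, header_size).

    ``elements`` is a list of ``(name, count, props)`` where props is a list
    of ``(prop_name, numpy_kind)`` or ``("__list__", None)`` markers.
    """
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise LoadError(f"{path}: not a PLY file (missing 'ply'/'end_header')")
    # header ends at the newline following end_header
    nl = raw.find(b"\n", end)
    if nl < 0:
        raise LoadError(f"{path}: truncated PLY header")
    header_size = nl + 1
    lines = raw[:end].decode("ascii", errors="replace").splitlines()

    fmt = None
    elements: list[tuple[str, int, list]] = []
    for line in lines[1:]:
        tokens = line.split()
        if not tokens or tokens[0] == "comment" or tokens[0] == "obj_info":
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in (
                "ascii", "binary_little_endian"
            ):
                raise LoadError(f"{path}: unsupported PLY format line {line!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise LoadError(f"{path}: malformed element line {line!r}")
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise LoadError(f"{path}: property before any element")
            if tokens[1] == "list":
                elements[-1][2].append(("__list__", None))
            else:
                if tokens[1] not in _PLY_TYPES:
                    raise LoadError(
                        f"{path}: unknown PLY property type {tokens[1]!r}"
                    )
                elements[-1][2].append((tokens[2], _PLY_TYPES[tokens[1]]))
    if fmt is None:
        raise LoadError(f"{path}: PLY header has no format line")
    return fmt, elements, header_size


def read_ply(path) -> dict[str, np.ndarray]:
    """Read vertex properties of a PLY file into ``{name: 1-D array}``."""
    path = str(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    fmt, elements, header_size = _parse_header(raw, path)

    vertex = None
    offset = header_size
    body = raw[header_size:]
    if fmt == "ascii":
        lines = body.decode("ascii", errors="replace").splitlines()
        cursor = 0
        for name, count, props in elements:
            if name != "vertex":
                cursor += count
                continue
            if any(p[0] == "__list__" for p in props):
                raise LoadError(f"{path}: list properties on vertex element")
            rows = lines[cursor:cursor + count]
            if len(rows) < count:
                raise LoadError(
                    f"{path}: expected {count} vertex rows, found {len(rows)}"
                )
            try:
                table = np.array(
                    [r.split() for r in rows], dtype=np.float64
                )
            except ValueError as exc:
                raise LoadError(f"{path}: malformed vertex row ({exc})") from exc
            if table.ndim != 2 or table.shape[1] != len(props):
                raise LoadError(f"{path}: vertex rows do not match header")
            vertex = {
                pname: table[:, i].astype(kind)
                for i, (pname, kind) in enumerate(props)
            }
            break
    else:
        for name, count, props in elements:
            if name != "vertex":
                if any(p[0] == "__list__" for p in props):
                    raise LoadError(
                        f"{path}: cannot skip binary list element {name!r} "
                        "placed before the vertex element"
                    )
                offset += count * sum(np.dtype(k).itemsize for _, k in props)
                continue
            if any(p[0] == "__list__" for p in props):
                raise LoadError(f"{path}: list properties on vertex element")
            dtype = np.dtype([(p, "<" + k) for p, k in props])
            nbytes = count * dtype.itemsize
            if len(raw) - offset < nbytes:
                raise LoadError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
            vertex = {p: np.ascontiguousarray(rec[p]) for p, _ in props}
            break
    if vertex is None:
        raise LoadError(f"{path}: PLY file has no vertex element")
    for axis in ("x", "y", "z"):
        if axis not in vertex:
            raise LoadError(f"{path}: vertex element lacks property {axis!r}")
    return vertex


def write_ply(path, points: np.ndarray, *, colors=None, labels=None,
              binary: bool = False) -> None:
    """Write points (float64 x/y/z) plus optional uchar RGB and int32 label."""
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    fields: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", points[:, 0]),
        ("y", "double", points[:, 1]),
        ("z", "double", points[:, 2]),
    ]
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8)
        for i, cname in enumerate(("red", "green", "blue")):
            fields.append((cname, "uchar", colors[:, i]))
    if labels is not None:
        fields.append(("label", "int", np.asarray(labels, dtype=np.int32)))

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property {ptype} {pname}" for pname, ptype, _ in fields]
    header.append("end_header")

    with open(str(path), "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype(
                [(pname, "<" + _PLY_TYPES[ptype]) for pname, ptype, _ in fields]
            )
            rec = np.empty(n, dtype=dtype)
            for pname, _, col in fields:
                rec[pname] = col
            fh.write(rec.tobytes())
        else:
            cols = []
            for pname, ptype, col in fields:
                if ptype == "double":
                    cols.append([format(v, ".17g") for v in col])
                else:
                    cols.append([str(int(v)) for v in col])
            rows = ("\n".join(" ".join(row) for row in zip(*cols)) + "\n")
            fh.write(rows.encode("ascii"))
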