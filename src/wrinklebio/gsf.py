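"""Gwyddion Simple Field (GSF) and ASCII-matrix height-map I/O.

GSF is the minimal single-channel interchange format for scanning-probe
height fields: a magic line, a text key-value header (XRes/YRes mandatory,
physical sizes in meters), NUL padding to a 4-byte boundary, then
row-major little-endian 32-bit floats. Heights are carried internally in
μm and converted at the file boundary.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .heightmap import HeightMap

__all__ = ["read_gsf", "write_gsf", "read_ascii_matrix", "write_ascii_matrix"]

GSF_MAGIC = b"Gwyddion Simple Field 1.0\n"
_M_PER_UM = 1e-6


class GsfFormatError(ValueError):
    """Malformed GSF file."""


def write_gsf(hmap: HeightMap, path: str | Path, title: str = "height") -> None:
    """Write a height map as GSF 1.0 (values and sizes in meters)."""
    rows, cols = hmap.shape
    header = GSF_MAGIC + (
        f"XRes = {cols}\n"
        f"YRes = {rows}\n"
        f"XReal = {cols * hmap.pixel_size * _M_PER_UM:.12e}\n"
        f"YReal = {rows * hmap.pixel_size * _M_PER_UM:.12e}\n"
        f"Title = {title}\n"
        "XYUnits = m\n"
        "ZUnits = m\n"
    ).encode("utf-8")
    pad = 4 - (len(header) % 4)
    payload = (hmap.values * _M_PER_UM).astype("<f4").tobytes()
    Path(path).write_bytes(header + b"\x00" * pad + payload)


def read_gsf(path: str | Path) -> HeightMap:
    """Read a GSF 1.0 file into a HeightMap (μm units).

    Raises
    ------
    GsfFormatError
        On a bad magic line, missing XRes/YRes, or a payload whose size
        disagrees with the declared resolution.
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(GSF_MAGIC):
        raise GsfFormatError(f"{path}: bad magic line at offset 0")
    nul = raw.find(b"\x00", len(GSF_MAGIC))
    if nul < 0:
        raise GsfFormatError(f"{path}: header not NUL-terminated")
    fields: dict[str, str] = {}
    for line in raw[len(GSF_MAGIC) : nul].decode("utf-8").splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        cols = int(fields["XRes"])
        rows = int(fields["YRes"])
    except KeyError as exc:
        raise GsfFormatError(f"{path}: missing mandatory header field {exc}") from exc
    # the padding block is 1..4 NULs ending on a 4-byte boundary
    offset = (nul // 4 + 1) * 4
    expected = 4 * rows * cols
    payload = raw[offset:]
    if len(payload) != expected:
        raise GsfFormatError(
            f"{path}: payload of {len(payload)} bytes at offset {offset}, "
            f"expected {expected} for {cols}×{rows} float32"
        )
    values = np.frombuffer(payload, dtype="<f4").reshape(rows, cols).astype(float)
    xreal = float(fields.get("XReal", cols * _M_PER_UM))
    yreal = float(fields.get("YReal", rows * _M_PER_UM))
    px_x = xreal / cols / _M_PER_UM
    px_y = yreal / rows / _M_PER_UM
    if abs(px_x - px_y) > 1e-6 * max(px_x, px_y):
        raise GsfFormatError(f"{path}: non-square pixels ({px_x:g} × {px_y:g} μm)")
    return HeightMap(values / _M_PER_UM, px_x, {"title": fields.get("Title", "")})


def write_ascii_matrix(hmap: HeightMap, path: str | Path) -> None:
    """Tab-separated height matrix (μm) with commented header."""
    buf = io.StringIO()
    rows, cols = hmap.shape
    buf.write("# wrinklebio height map\n")
    buf.write(f"# rows: {rows}\n# cols: {cols}\n")
    buf.write(f"# pixel_size_um: {hmap.pixel_size:.9g}\n")
    buf.write("# units: um\n")
    np.savetxt(buf, hmap.values, fmt="%.6e", delimiter="\t")
    Path(path).write_text(buf.getvalue())


def read_ascii_matrix(path: str | Path) -> HeightMap:
    """Read the ASCII matrix format written by :func:`write_ascii_matrix`."""
    px = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "pixel_size_um:" in line:
                px = float(line.split(":", 1)[1])
    if px is None:
        raise ValueError(f"{path}: missing '# pixel_size_um:' header")
    values = np.loadtxt(path, comments="#", delimiter="\t")
    return HeightMap(np.atleast_2d(values), px)
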