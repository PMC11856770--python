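"""Minimal ENVI raster reader/writer (text header + flat binary payload).

Supports the subset of the format that hyperspectral benchmark cubes and the
synthetic scenes here actually use: BSQ/BIL/BIP interleaves, little/big
endian, the common numeric dtypes.  Always writes BSQ, byte order 0.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

# ENVI "data type" codes <-> numpy dtypes
_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4",
           14: "i8", 15: "u8"}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def read_header(hdr_path: str | os.PathLike) -> dict:
    text = Path(hdr_path).read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{hdr_path}: not an ENVI header")
    # fold brace-delimited multi-line values onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip().strip("{}").strip()
    return fields


def read_envi(hdr_path: str | os.PathLike,
              data_path: str | os.PathLike | None = None) -> np.ndarray:
    """Read an ENVI raster into a (rows, columns, bands) array."""
    hdr_path = Path(hdr_path)
    fields = read_header(hdr_path)
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields.get("bands", 1))
    code = int(fields["data type"])
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    order = ">" if int(fields.get("byte order", 0)) == 1 else "<"
    dtype = np.dtype(order + _DTYPES[code])
    interleave = fields.get("interleave", "bsq").lower()

    if data_path is None:
        for cand in (hdr_path.with_suffix(""), hdr_path.with_suffix(".img"),
                     hdr_path.with_suffix(".raw"), hdr_path.with_suffix(".dat")):
            if cand.exists() and cand != hdr_path:
                data_path = cand
                break
        else:
            raise FileNotFoundError(f"no data file found next to {hdr_path}")
    raw = np.fromfile(data_path, dtype=dtype, count=rows * cols * bands)
    if raw.size != rows * cols * bands:
        raise ValueError(f"{data_path}: payload size does not match header")
    if interleave == "bsq":
        arr = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return np.ascontiguousarray(arr)


def write_envi(arr: np.ndarray, hdr_path: str | os.PathLike,
               description: str = "") -> Path:
    """Write (rows, columns[, bands]) as BSQ ENVI; returns the data path."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected a 2-D or 3-D array")
    if arr.dtype not in _CODES:
        arr = arr.astype(np.float32)
    rows, cols, bands = arr.shape
    hdr_path = Path(hdr_path)
    data_path = hdr_path.with_suffix(".img")
    hdr = (
        "ENVI\n"
        f"description = {{{description}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODES[arr.dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
    )
    hdr_path.write_text(hdr)
    arr.transpose(2, 0, 1).astype(arr.dtype.newbyteorder("<")).tofile(data_path)
    return data_path
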