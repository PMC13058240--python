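"""Minimal read-only FCS 3.0/3.1 list-mode adapter.

Imaging flow-cytometry pipelines typically hand over delimited feature
exports, which are the canonical input of this package; FCS support exists
only as a thin bridge for instruments that write standard flow files. The
parser covers plain list-mode files: HEADER offsets, a TEXT segment with a
single-byte delimiter, and a DATA segment of uniform-width floats, doubles or
integers. Escaped (doubled) delimiters inside keyword values and analysis
segments are not supported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .events_io import EventTable, SampleMeta

__all__ = ["read_fcs", "read_fcs_events"]

_DTYPES = {"F": "f4", "D": "f8"}


def _text_segment(blob: bytes, start: int, end: int) -> dict:
    text = blob[start : end + 1].decode("latin-1")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path) -> tuple[pd.DataFrame, dict]:
    """Parse an FCS 3.0/3.1 file into (events, keywords).

    Events come back as a DataFrame with one column per parameter, named by
    $PnN. Only list mode ($MODE/L) with a uniform $DATATYPE is handled.
    """
    blob = Path(path).read_bytes()
    version = blob[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ParseError(f"unsupported FCS version {version!r}")
    text_start = int(blob[10:18])
    text_end = int(blob[18:26])
    kw = _text_segment(blob, text_start, text_end)

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise ParseError(f"only list-mode FCS is supported, got $MODE={mode}")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")

    data_start = int(kw.get("$BEGINDATA") or blob[26:34])
    data_end = int(kw.get("$ENDDATA") or blob[34:42])

    if datatype in _DTYPES:
        base = _DTYPES[datatype]
    elif datatype == "I":
        widths = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(widths) != 1 or widths.pop() not in (16, 32):
            raise ParseError("integer FCS data requires a uniform 16- or 32-bit width")
        base = "u2" if int(kw["$P1B"]) == 16 else "u4"
    else:
        raise ParseError(f"unsupported $DATATYPE {datatype!r}")

    dtype = np.dtype(("<" if little else ">") + base)
    raw = np.frombuffer(blob[data_start : data_end + 1], dtype=dtype, count=n_par * n_tot)
    values = raw.reshape(n_tot, n_par).astype(float)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(values, columns=names), kw


def read_fcs_events(path, column_map: Mapping[str, str], meta: SampleMeta) -> EventTable:
    """Read an FCS file into an :class:`EventTable`.

    ``column_map`` maps schema roles (``intensity_dye``, ``intensity_auto``,
    ``area``) to $PnN parameter names.
    """
    frame, _ = read_fcs(path)
    if "intensity_dye" not in column_map:
        raise SchemaError("column_map must cover the role 'intensity_dye'")
    data = {}
    for role in ("intensity_dye", "intensity_auto", "area"):
        name = column_map.get(role)
        if name is None:
            continue
        if name not in frame.columns:
            if role == "intensity_dye":
                raise SchemaError(f"parameter {name!r} for role 'intensity_dye' not in FCS file")
            continue
        data[role] = frame[name].to_numpy(float)
    return EventTable(meta=meta, events=pd.DataFrame(data))
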