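"""Minimal FCS 3.1 list-mode reader/writer.

Covers the subset of the standard this package produces and consumes:
single data set, list mode ($MODE L), float32 ($DATATYPE F) or float64
($DATATYPE D) data, little- or big-endian $BYTEORD, 32/64-bit parameters.
Channel parameters are named ``Intensity_<channel key>`` in $PnN; scatter
parameters are FSC, SSC and AR_SSC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs"]

_DELIMITER = b"|"
_HEADER_LEN = 58  # "FCS3.1    " + 8 x 6-char offset fields


def _build_text(keywords: dict) -> bytes:
    delim = _DELIMITER
    parts = [delim]
    for key, value in keywords.items():
        parts.append(str(key).encode("ascii") + delim)
        parts.append(str(value).encode("ascii") + delim)
    return b"".join(parts)


def write_fcs(df: pd.DataFrame, path, channels, dtype: str = "float32") -> None:
    """Write events as a single-dataset FCS 3.1 file.

    ``df`` must hold fsc/ssc/ar_ssc plus one column per channel key; an
    optional truth column is not representable in FCS and is dropped.
    """
    param_names = ["FSC", "SSC", "AR_SSC"] + [f"Intensity_{c}" for c in channels]
    columns = ["fsc", "ssc", "ar_ssc"] + list(channels)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    np_dtype = np.dtype(dtype)
    if np_dtype not in (np.dtype("float32"), np.dtype("float64")):
        raise ValueError("FCS writer supports float32/float64 only")
    data = np.ascontiguousarray(df[columns].to_numpy(dtype=np_dtype))
    data_bytes = data.astype(f"<{np_dtype.str[1:]}").tobytes()

    bits = np_dtype.itemsize * 8
    keywords = {
        "$BEGINANALYSIS": 0,
        "$ENDANALYSIS": 0,
        "$BEGINSTEXT": 0,
        "$ENDSTEXT": 0,
        "$BEGINDATA": 0,
        "$ENDDATA": 0,
        "$NEXTDATA": 0,
        "$MODE": "L",
        "$DATATYPE": "F" if bits == 32 else "D",
        "$BYTEORD": "1,2,3,4",
        "$TOT": len(df),
        "$PAR": len(param_names),
    }
    for i, name in enumerate(param_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = bits
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = int(max(1.0, float(np.ceil(data[:, i - 1].max() + 1))))

    # data offsets depend on the text length which depends on the offsets:
    # iterate to a fixed point (converges in a couple of passes)
    begin_data = end_data = 0
    for _ in range(8):
        keywords["$BEGINDATA"] = begin_data
        keywords["$ENDDATA"] = end_data
        text = _build_text(keywords)
        new_begin = _HEADER_LEN + len(text)
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _build_text(keywords)

    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode("ascii")
        for v in (text_begin, text_end, begin_data, end_data, 0, 0)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict:
    delim = raw[:1]
    fields = raw[1:].split(delim)
    if fields and fields[-1] == b"":
        fields = fields[:-1]
    if len(fields) % 2:
        raise ValueError("malformed FCS text segment (odd keyword count)")
    return {
        fields[i].decode("ascii", "replace").strip(): fields[i + 1].decode(
            "ascii", "replace"
        )
        for i in range(0, len(fields), 2)
    }


def read_fcs(path) -> tuple:
    """Read a single-dataset FCS file; returns (DataFrame, keywords).

    The frame has one column per $PnN parameter name.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    keywords = _parse_text(raw[text_begin : text_end + 1])

    begin_data = int(keywords.get("$BEGINDATA") or raw[26:34])
    end_data = int(keywords.get("$ENDDATA") or raw[34:42])
    n_events = int(keywords["$TOT"])
    n_params = int(keywords["$PAR"])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    if keywords.get("$MODE", "L").strip().upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS is supported")
    if datatype not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {datatype!r} (need F or D)")
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    width = 4 if datatype == "F" else 8

    payload = raw[begin_data : end_data + 1]
    expected = n_events * n_params * width
    if len(payload) < expected:
        raise ValueError("FCS data segment shorter than $TOT x $PAR events")
    data = np.frombuffer(payload[:expected], dtype=f"{endian}f{width}").reshape(
        n_events, n_params
    )
    names = [
        keywords.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_params + 1)
    ]
    return pd.DataFrame(data, columns=names), keywords
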