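"""Minimal FCS 3.0/3.1 list-mode support.

Covers exactly what mass-cytometry workflows need: reading list-mode (``$MODE
L``) files with float, double or integer data, and writing a small, valid FCS
3.1 float32 file for fixtures and round-trip tests.  Logarithmic channel
scaling (``$PnE`` with a non-zero first value) is a flow-cytometry convention
that does not apply to mass cytometry; when such metadata is present it is
ignored with a warning and values are returned as stored.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

__all__ = ["read_fcs", "write_fcs"]

_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    # FCS escapes a literal delimiter by doubling it; our fixture writer never
    # does, but tolerate it by splitting on single delimiters only.
    parts = body.split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    kv: dict[str, str] = {}
    for i in range(0, len(parts) - 1, 2):
        kv[parts[i].strip().upper()] = parts[i + 1]
    return kv


def read_fcs(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read an FCS 3.0/3.1 list-mode file.

    Returns
    -------
    values : ndarray of shape (n_events, n_params), float64
    names : list of channel names ($PnN, falling back to $PnS or "P<n>")
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r} (need FCS 3.0/3.1)")
    offsets = []
    for i in range(6):
        field = raw[10 + 8 * i : 18 + 8 * i].decode("latin-1").strip()
        offsets.append(int(field) if field else 0)
    text_start, text_end, data_start, data_end = offsets[:4]
    text = _parse_text_segment(raw[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    mode = text.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise ValueError(f"only list-mode ($MODE L) FCS is supported, got {mode!r}")
    datatype = text.get("$DATATYPE", "F").strip().upper()
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    byteord = text.get("$BYTEORD", "1,2,3,4").replace(" ", "")
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2,1"):
        endian = ">"
    else:
        raise ValueError(f"unsupported $BYTEORD {byteord!r}")

    names = []
    for p in range(1, n_par + 1):
        names.append(text.get(f"$P{p}N") or text.get(f"$P{p}S") or f"P{p}")
    for p in range(1, n_par + 1):
        pne = text.get(f"$P{p}E", "0,0").replace(" ", "")
        if pne and float(pne.split(",")[0]) != 0.0:
            warnings.warn(
                f"channel {names[p - 1]!r} declares log scaling $P{p}E={pne}; "
                "ignoring it (linear mass-cytometry convention)",
                stacklevel=2,
            )

    bits = {int(text.get(f"$P{p}B", "32")) for p in range(1, n_par + 1)}
    if len(bits) != 1:
        raise ValueError("mixed $PnB bit widths are not supported")
    nbits = bits.pop()
    if datatype == "F":
        if nbits != 32:
            raise ValueError("$DATATYPE F requires $PnB 32")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        if nbits != 64:
            raise ValueError("$DATATYPE D requires $PnB 64")
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        if nbits not in (8, 16, 32):
            raise ValueError(f"unsupported integer width {nbits}")
        dtype = np.dtype(endian + f"u{nbits // 8}")
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    count = n_par * n_tot
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=data_start)
    values = data.reshape(n_tot, n_par).astype(np.float64)
    return values, names


def write_fcs(path: str | os.PathLike, values: np.ndarray, names: list[str]) -> None:
    """Write a minimal valid FCS 3.1 file (float32, little-endian, list mode)."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    if len(names) != n_par:
        raise ValueError("one channel name required per column")
    data_bytes = values.tobytes()

    delim = "/"
    keys = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for p, name in enumerate(names, start=1):
        if delim in name:
            raise ValueError(f"channel name {name!r} contains the delimiter {delim!r}")
        keys[f"$P{p}N"] = name
        keys[f"$P{p}B"] = "32"
        keys[f"$P{p}E"] = "0,0"
        rng = float(values[:, p - 1].max()) if n_tot else 0.0
        keys[f"$P{p}R"] = str(int(np.ceil(abs(rng))) + 1)

    # Two-pass assembly: the TEXT segment must contain the DATA offsets, whose
    # width depends on the TEXT length; pad BEGINDATA/ENDDATA to fixed width.
    def build_text(begin_data: int, end_data: int) -> bytes:
        items = {"$BEGINDATA": f"{begin_data:>10d}", "$ENDDATA": f"{end_data:>10d}", **keys}
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in items.items()) + delim
        return body.encode("latin-1")

    text_start = _HEADER_LEN
    probe = build_text(0, 0)
    data_start = text_start + len(probe)
    data_end = data_start + len(data_bytes) - 1
    text = build_text(data_start, data_end)
    assert len(text) == len(probe)
    text_end = text_start + len(text) - 1

    def hfield(x: int) -> bytes:
        s = str(x)
        return (" " * (8 - len(s)) + s).encode("ascii") if len(s) <= 8 else b"       0"

    header = b"FCS3.1    " + b"".join(
        hfield(v)
        for v in (
            text_start,
            text_end,
            data_start if data_start <= 99_999_999 else 0,
            data_end if data_end <= 99_999_999 else 0,
            0,
            0,
        )
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)
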