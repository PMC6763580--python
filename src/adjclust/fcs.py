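"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers the subset of the standard that cytometry exports in practice use:
list mode (``$MODE L``), floating-point data (``$DATATYPE F`` or ``D``) and
integer data (``$DATATYPE I`` with byte-aligned widths), little- or
big-endian ``$BYTEORD``. One dataset per file (``$NEXTDATA 0``).

Only the event matrix and channel names are modelled; analysis segments and
supplemental text are ignored on read and never written.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from adjclust.errors import SchemaError

_HEADER_FMT = "{magic:<10.10s}{tb:>8d}{te:>8d}{db:>8d}{de:>8d}{ab:>8d}{ae:>8d}"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # a doubled delimiter escapes a literal delimiter inside a value; rare,
    # handled by splitting on single delimiters then re-joining empties
    parts = body.split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    fields: list[str] = []
    i = 0
    while i < len(parts):
        piece = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            piece += delim + parts[i + 2]
            i += 2
        fields.append(piece)
        i += 1
    if len(fields) % 2:
        fields = fields[:-1]
    return {
        fields[j].strip().upper(): fields[j + 1]
        for j in range(0, len(fields), 2)
    }


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file; return ``(events x channels array, channel names)``.

    Channel names come from ``$PnS`` when present, else ``$PnN``.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58 or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise SchemaError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise SchemaError(f"{path}: malformed FCS header") from exc
    text = _parse_text_segment(raw[text_begin : text_end + 1])

    data_begin = int(text.get("$BEGINDATA") or raw[26:34])
    data_end = int(text.get("$ENDDATA") or raw[34:42])
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32):
            raise SchemaError(f"{path}: unsupported integer channel widths")
        width = int(text["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise SchemaError(f"{path}: unsupported $DATATYPE {datatype!r}")

    buf = raw[data_begin : data_end + 1]
    need = n_par * n_tot * dtype.itemsize
    if len(buf) < need:
        raise SchemaError(f"{path}: data segment truncated")
    values = np.frombuffer(buf[:need], dtype=dtype).reshape(n_tot, n_par)
    names = [
        text.get(f"$P{i}S", "").strip() or text.get(f"$P{i}N", f"P{i}").strip()
        for i in range(1, n_par + 1)
    ]
    return np.asarray(values, dtype=np.float64), names


def write_fcs(path: str | Path, values: np.ndarray, channel_names: list[str]) -> None:
    """Write an events x channels matrix as FCS 3.0 (float32, little-endian)."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    if len(channel_names) != n_par:
        raise SchemaError("channel name count does not match matrix width")
    data = values.tobytes()

    keywords = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}N"] = str(name).replace("/", "_")
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(values)) + 1)) if n_tot else 1)

    # iterate because $BEGINDATA/$ENDDATA lengths feed back into the offsets
    text_begin = 58
    data_begin = 0
    for _ in range(8):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(max(data_begin + len(data) - 1, 0))
        text = "/" + "".join(f"{k}/{v}/" for k, v in sorted(kw.items()))
        new_begin = text_begin + len(text)
        if new_begin == data_begin:
            break
        data_begin = new_begin
    text_bytes = text.encode("latin-1")
    text_end = text_begin + len(text_bytes) - 1
    data_end = data_begin + len(data) - 1 if data else 0

    def fits(x: int) -> int:  # header fields are 8 ASCII digits; 0 = "see TEXT"
        return x if x <= 99_999_999 else 0

    header = _HEADER_FMT.format(
        magic="FCS3.0",
        tb=text_begin,
        te=text_end,
        db=fits(data_begin),
        de=fits(data_end),
        ab=0,
        ae=0,
    ).encode("ascii")
    assert len(header) == 58
    Path(path).write_bytes(header + text_bytes + data)
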