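"""Minimal Flow Cytometry Standard (FCS) 3.0/3.1 reader and writer.

Supports list-mode ($MODE L) files with floating-point data
($DATATYPE F or D) and either byte order — the layout produced by
modern cytometer software and by :func:`write_fcs` here.  Integer data
types, FCS 2.0 dialects and analysis segments are out of scope.

All offsets and element counts are handled as Python integers / 64-bit
numpy indices, so files whose ``events x channels`` product exceeds
2**31 - 1 are read without wraparound.
"""

from __future__ import annotations

import numpy as np

from .preprocess import ExpressionMatrix

__all__ = ["read_fcs", "write_fcs_matrix", "FCSFormatError"]

_HEADER_LEN = 58  # version(6) + spaces(4) + six 8-char ASCII offsets


class FCSFormatError(ValueError):
    """Raised for unreadable, truncated or unsupported FCS files."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Decode a TEXT segment into a keyword dict.

    The first byte is the delimiter; doubled delimiters inside values are
    the standard's escape for a literal delimiter.
    """
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim_b = raw[0:1]
    delim = delim_b.decode("latin-1")
    body = raw[1:]
    if body.endswith(delim_b):
        body = body[:-1]
    tokens = [t.decode("latin-1", errors="replace") for t in body.split(delim_b)]
    # A doubled delimiter escapes a literal delimiter inside a value and
    # shows up here as an empty token between two fragments: merge them.
    decoded: list[str] = []
    for tok in tokens:
        if tok == "" and decoded:
            decoded[-1] += delim
        elif decoded and decoded[-1].endswith(delim):
            decoded[-1] += tok
        else:
            decoded.append(tok)
    if len(decoded) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    return {
        decoded[j].strip().upper(): decoded[j + 1]
        for j in range(0, len(decoded), 2)
    }


def _read_segment_offsets(header: bytes) -> tuple[int, int]:
    try:
        text_start = int(header[10:18])
        text_end = int(header[18:26])
    except ValueError as exc:
        raise FCSFormatError("malformed HEADER offsets") from exc
    return text_start, text_end


def read_fcs(path, marker_channels: list[str] | None = None) -> ExpressionMatrix:
    """Read an FCS 3.0/3.1 file, optionally keeping only some channels.

    Parameters
    ----------
    path : path-like
        FCS file to read.
    marker_channels : list of str, optional
        Channel short names ($PnN) to keep, in the order requested.
        ``None`` keeps every channel.

    Returns
    -------
    ExpressionMatrix
        With ``transform_state="raw"``.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _HEADER_LEN:
        raise FCSFormatError(f"file too short to be FCS: {len(data)} bytes")
    version = data[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")
    text_start, text_end = _read_segment_offsets(data[:_HEADER_LEN])
    if text_end >= len(data) or text_start >= text_end:
        raise FCSFormatError("TEXT segment offsets out of range (truncated file?)")
    kw = _parse_text_segment(data[text_start : text_end + 1])

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"only list mode is supported, got $MODE={mode}")
    dtype_code = kw.get("$DATATYPE", "").upper()
    if dtype_code not in ("F", "D"):
        raise FCSFormatError(
            f"only float ($DATATYPE F/D) data supported, got {dtype_code!r}"
        )
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    np_dtype = np.dtype(endian + ("f4" if dtype_code == "F" else "f8"))

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = int(kw.get("$BEGINDATA", 0)) or int(data[26:34])
    data_end = int(kw.get("$ENDDATA", 0)) or int(data[34:42])
    n_bytes = n_tot * n_par * np_dtype.itemsize
    if data_end - data_start + 1 < n_bytes or data_start + n_bytes > len(data):
        raise FCSFormatError("DATA segment shorter than $TOT x $PAR events")

    values = (
        np.frombuffer(data, dtype=np_dtype, count=n_tot * n_par, offset=data_start)
        .astype(np.float64)
        .reshape(n_tot, n_par)
    )
    names = tuple(
        kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)
    )
    matrix = ExpressionMatrix(values, names, transform_state="raw")
    if marker_channels is not None:
        matrix = matrix.select_channels(list(marker_channels))
    return matrix


def write_fcs_matrix(
    values: np.ndarray, channel_names: list[str], path
) -> None:
    """Write an events-by-channels matrix as FCS 3.1 (float32, list mode)."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match number of columns")

    delim = "/"
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(channel_names, start=1):
        if delim in name:
            raise ValueError(f"channel name {name!r} contains the delimiter")
        keywords += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", name),
            (f"$P{i}R", "262144"),
        ]

    # DATA offsets appear both in the HEADER and as $BEGINDATA/$ENDDATA;
    # fixed-width placeholders keep the TEXT length independent of their value.
    width = 16
    def render(begin: int, end: int) -> bytes:
        kws = keywords + [
            ("$BEGINDATA", str(begin).rjust(width)),
            ("$ENDDATA", str(end).rjust(width)),
        ]
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in kws) + delim
        return body.encode("latin-1")

    text_start = _HEADER_LEN
    text_len = len(render(0, 0))
    data_start = text_start + text_len
    data_end = data_start + values.nbytes - 1
    text = render(data_start, data_end)
    assert len(text) == text_len

    def hdr_off(v: int) -> bytes:
        return (str(v) if v <= 99_999_999 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        hdr_off(v)
        for v in (text_start, text_start + text_len - 1, data_start, data_end, 0, 0)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())
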