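"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Deliberately small: it reads the HEADER and TEXT segments and a DATA segment
in list mode with ``$DATATYPE`` ``F`` (float32) or ``I`` (unsigned integer,
uniform byte width 16 or 32), little- or big-endian.  That covers the files a
CytoFLEX-style instrument exports and everything this package writes for its
own fixtures.  Analysis segments, ``$PnE`` log amplification, bit-masked
integers, multi-dataset files and ``$MODE`` other than ``L`` are rejected
rather than guessed at.

The writer always emits FCS 3.1, float32, little-endian ($BYTEORD 1,2,3,4),
with sample metadata carried as plain TEXT keywords (SAMPLE_ID, DONOR_ID,
TISSUE, STIMULATION, REPLICATE_ID, CONDITION).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

_DELIM = "/"

#: TEXT keywords used to round-trip sample metadata (meta key -> keyword).
META_KEYWORDS = {
    "sample_id": "SAMPLE_ID",
    "donor_id": "DONOR_ID",
    "tissue": "TISSUE",
    "stimulation": "STIMULATION",
    "replicate_id": "REPLICATE_ID",
    "condition": "CONDITION",
}
_KEYWORD_TO_META = {v: k for k, v in META_KEYWORDS.items()}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("ascii", errors="replace")
    parts = raw[1:].decode("utf-8", errors="replace").split(delim)
    # trailing delimiter produces an empty final token
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FormatError("malformed TEXT segment: odd number of tokens")
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file; return (values, channel_names, meta)."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise ValidationError(f"{path}: file too short to be FCS")
    version = blob[0:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(field: bytes) -> int:
        text = field.decode("ascii", errors="replace").strip()
        return int(text) if text else 0

    text_begin = _offset(blob[10:18])
    text_end = _offset(blob[18:26])
    data_begin = _offset(blob[26:34])
    data_end = _offset(blob[34:42])
    if text_begin <= 0 or text_end <= text_begin:
        raise FormatError(f"{path}: invalid TEXT segment offsets")
    keywords = _parse_text_segment(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(keywords.get("$BEGINDATA", "0"))
        data_end = int(keywords.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin:
        raise FormatError(f"{path}: invalid DATA segment offsets")
    if int(keywords.get("$NEXTDATA", "0")) != 0:
        raise FormatError(f"{path}: multi-dataset FCS files are not supported")

    mode = keywords.get("$MODE", "L")
    if mode != "L":
        raise FormatError(f"{path}: unsupported $MODE {mode!r} (list mode only)")
    datatype = keywords.get("$DATATYPE", "")
    if datatype not in ("F", "I"):
        raise FormatError(
            f"{path}: unsupported $DATATYPE {datatype!r} (only F and I)"
        )
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    if n_par < 1 or n_tot < 1:
        raise ValidationError(f"{path}: empty data ($PAR={n_par}, $TOT={n_tot})")

    names: list[str] = []
    widths: list[int] = []
    for i in range(1, n_par + 1):
        names.append(keywords.get(f"$P{i}N", f"P{i}"))
        widths.append(int(keywords[f"$P{i}B"]))
        amp = keywords.get(f"$P{i}E", "0,0")
        if amp.replace(" ", "") not in ("0,0", "0.0,0.0"):
            raise FormatError(
                f"{path}: log-amplified parameter $P{i}E={amp!r} not supported"
            )
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate channel names {names}")

    if datatype == "F":
        if any(w != 32 for w in widths):
            raise FormatError(f"{path}: $DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(f"{endian}f4")
    else:
        if len(set(widths)) != 1 or widths[0] not in (16, 32):
            raise FormatError(
                f"{path}: $DATATYPE I requires a uniform 16- or 32-bit width"
            )
        dtype = np.dtype(f"{endian}u{widths[0] // 8}")

    expected = n_par * n_tot * dtype.itemsize
    raw = blob[data_begin : data_begin + expected]
    if len(raw) != expected:
        raise FormatError(
            f"{path}: DATA segment truncated ({len(raw)} bytes, expected {expected})"
        )
    values = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par)
    meta = {
        meta_key: keywords[kw]
        for kw, meta_key in _KEYWORD_TO_META.items()
        if kw in keywords
    }
    return values.astype(np.float64), names, meta


def write_fcs(
    path: str | Path,
    values: np.ndarray,
    channel_names: list[str],
    meta: dict[str, str] | None = None,
) -> None:
    """Write float32 little-endian FCS 3.1."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float64)
    n_tot, n_par = values.shape
    data = values.astype("<f4").tobytes()

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%012d"),  # placeholders, fixed width
        ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    finite = values[np.isfinite(values)]
    vmax = float(finite.max()) if finite.size else 0.0
    for i, name in enumerate(channel_names, start=1):
        if _DELIM in name:
            raise ValidationError(
                f"channel name {name!r} contains the TEXT delimiter {_DELIM!r}"
            )
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(vmax, 1.0)) + 1)),
        ]
    for meta_key, keyword in META_KEYWORDS.items():
        if meta and meta.get(meta_key):
            keywords.append((keyword, str(meta[meta_key])))

    def _render(data_begin: int, data_end: int) -> bytes:
        parts = []
        for key, val in keywords:
            if val == "%012d":
                val = "%012d" % (data_begin if key == "$BEGINDATA" else data_end)
            parts.append(f"{key}{_DELIM}{val}")
        return (_DELIM + _DELIM.join(parts) + _DELIM).encode("utf-8")

    # TEXT length does not depend on the offset values (fixed-width placeholders)
    text_begin = 58
    text_len = len(_render(0, 0))
    text_end = text_begin + text_len - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = _render(data_begin, data_end)

    def _field(value: int) -> bytes:
        rendered = str(value) if value <= 99_999_999 else "0"
        return rendered.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _field(v) for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == 58
    path.write_bytes(header + text + data)
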