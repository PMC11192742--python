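"""Event-table and panel-configuration I/O.

Two event dialects are supported:

* ``csv`` — UTF-8, comma-separated, ``.`` decimal, channel names on the first
  line, one event per row. Values are written with Python's shortest
  round-trip float repr, so a write/read cycle is bit-exact.
* ``fcs`` — FCS 3.1, list mode, one dataset per file. Written as datatype F
  (little-endian float32); the reader accepts datatypes F, D and I and both
  byte orders. Only ``$PnN`` channel names and a few bookkeeping keywords are
  preserved; display transforms are never applied.

Panel configurations are YAML (or JSON, a YAML subset) documents declaring
the detector channels, both cocktails and the control fluorophore.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ChannelDef, EventTable, PanelSpec, PanelValidationError, ReporterDef

__all__ = [
    "read_events",
    "write_events",
    "load_panel",
    "default_panel",
    "matched_mass_panel",
    "FcsFormatError",
]


class FcsFormatError(ValueError):
    """File is not readable as the supported FCS dialect."""


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

def _write_csv(table: EventTable, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(table.channels) + "\n")
        vals = table.data.to_numpy(dtype=float)
        for row in vals:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _read_csv(path: Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FcsFormatError(f"{path}: empty CSV event table")
        channels = [c.strip() for c in header.rstrip("\n").split(",")]
        rows = [line.rstrip("\n").split(",") for line in fh if line.strip()]
    try:
        data = np.array(rows, dtype=float) if rows else np.empty((0, len(channels)))
    except ValueError as exc:
        raise FcsFormatError(f"{path}: malformed CSV event row ({exc})") from exc
    if data.shape[1] != len(channels):
        raise FcsFormatError(f"{path}: row width does not match header")
    return pd.DataFrame(data, columns=channels)


# --------------------------------------------------------------------------
# FCS 3.1 (minimal list-mode dialect)
# --------------------------------------------------------------------------

_DELIM = "/"


def _fcs_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, val in keywords.items():
        sval = str(val)
        if _DELIM in key or _DELIM in sval:
            raise FcsFormatError(f"delimiter {_DELIM!r} not allowed in keyword {key!r}")
        parts.append(f"{key}{_DELIM}{sval}{_DELIM}")
    return "".join(parts).encode("utf-8")


def _write_fcs(table: EventTable, path: Path) -> None:
    channels = table.channels
    data = table.data.to_numpy(dtype="<f4")
    n_par, n_tot = len(channels), table.n_events
    rng_max = float(np.max(data)) if data.size else 1.0

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "FMDSBR$SAMPLEID": table.sample_id or "-",
        "FMDSBR$COCKTAIL": table.cocktail,
    }
    for i, name in enumerate(channels, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = repr(max(rng_max, 1.0))

    # two-pass sizing: offsets appear inside the TEXT segment
    header_len = 58
    for _ in range(2):
        kw = dict(keywords)
        text = _fcs_text(kw)
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + data.nbytes - 1 if data.size else 0
        keywords["$BEGINDATA"] = str(data_start if data.size else 0)
        keywords["$ENDDATA"] = str(data_end)
    text = _fcs_text(keywords)
    text_end = header_len + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1 if data.size else 0

    header = (
        b"FCS3.1    "
        + f"{header_len:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start if data.size else 0:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FcsFormatError("empty TEXT segment")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FcsFormatError("odd number of TEXT tokens")
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def _read_fcs(path: Path) -> EventTable:
    blob = path.read_bytes()
    if len(blob) < 58 or not blob[:6].startswith(b"FCS3"):
        raise FcsFormatError(f"{path}: not an FCS 3.x file")
    try:
        offs = [int(blob[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FcsFormatError(f"{path}: unreadable header offsets") from exc
    text_start, text_end, data_start, data_end = offs
    if text_end >= len(blob) or text_start >= text_end:
        raise FcsFormatError(f"{path}: truncated TEXT segment")
    kw = _parse_fcs_text(blob[text_start : text_end + 1])

    data_start = int(kw.get("$BEGINDATA", data_start))
    data_end = int(kw.get("$ENDDATA", data_end))
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    order = "<" if byteord.startswith("1") else ">"
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    if datatype == "F":
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        bits = {int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FcsFormatError(f"{path}: unsupported integer widths")
        width = int(kw["$P1B"]) // 8
        dtype = np.dtype(f"{order}u{width}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    if n_tot == 0:
        data = np.empty((0, n_par), dtype=float)
    else:
        raw = blob[data_start : data_end + 1]
        if len(raw) < expected:
            raise FcsFormatError(f"{path}: truncated DATA segment")
        data = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    frame = pd.DataFrame(np.asarray(data, dtype=float), columns=names)
    sample_id = kw.get("FMDSBR$SAMPLEID", path.stem)
    if sample_id == "-":
        sample_id = path.stem
    return EventTable(frame, sample_id=sample_id, cocktail=kw.get("FMDSBR$COCKTAIL", "none"))


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def read_events(path: str | Path, dialect: str | None = None) -> EventTable:
    """Read an event table from CSV or FCS; dialect inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if dialect == "csv":
        return EventTable(_read_csv(path), sample_id=path.stem)
    if dialect == "fcs":
        return _read_fcs(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_events(table: EventTable, path: str | Path, dialect: str | None = None) -> Path:
    """Write an event table; returns the path written."""
    path = Path(path)
    if dialect is None:
        dialect = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if dialect == "csv":
        _write_csv(table, path)
    elif dialect == "fcs":
        _write_fcs(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _reporter_from_mapping(entry: dict) -> ReporterDef:
    try:
        return ReporterDef(
            reporter_name=entry["reporter"],
            pathway=entry["pathway"],
            mass_ng=float(entry["mass_ng"]),
            fluorophore=entry.get("fluorophore"),
            channel=entry.get("channel"),
            damaged=bool(entry.get("damaged", False)),
        )
    except KeyError as exc:
        raise PanelValidationError(f"cocktail entry missing key {exc}") from exc


def load_panel(path: str | Path) -> PanelSpec:
    """Load and validate a panel/cocktail configuration from YAML or JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PanelValidationError(f"{path}: panel config must be a mapping")
    for key in ("channels", "damaged_cocktail", "undamaged_cocktail", "control_fluorophore"):
        if key not in doc:
            raise PanelValidationError(f"{path}: missing required key {key!r}")
    channels = tuple(
        ChannelDef(c["name"], float(c.get("excitation_nm", 0)), str(c.get("filter", "")))
        for c in doc["channels"]
    )
    return PanelSpec(
        channels=channels,
        damaged_cocktail=tuple(_reporter_from_mapping(e) for e in doc["damaged_cocktail"]),
        undamaged_cocktail=tuple(_reporter_from_mapping(e) for e in doc["undamaged_cocktail"]),
        control_fluorophore=str(doc["control_fluorophore"]),
    )


_CHANNELS = (
    ChannelDef("VL1", 405, "450/40"),   # BFP
    ChannelDef("VL2", 405, "525/50"),   # AmCyan
    ChannelDef("BL1", 488, "530/30"),   # GFP
    ChannelDef("YL1", 561, "620/15"),   # mCherry
)


def default_panel() -> PanelSpec:
    """The four-color multiplexed DSB-repair panel.

    Damaged cocktail: 100 ng BFP NHEJ reporter, 250 ng GFP MMEJ reporter,
    100 ng mCherry HR reporter, 100 ng intact AmCyan transfection control,
    1000 ng promoterless carrier. Undamaged cocktail: 100 ng of each intact
    wild-type plasmid plus the same control and carrier.
    """
    damaged = (
        ReporterDef("BFP_NHEJ", "NHEJ", 100, "BFP", "VL1", damaged=True),
        ReporterDef("GFP_MMEJ6", "MMEJ", 250, "GFP", "BL1", damaged=True),
        ReporterDef("mCherry_HR", "HR", 100, "mCherry", "YL1", damaged=True),
        ReporterDef("pMax_AmCyan", "TRANSFECTION_CONTROL", 100, "AmCyan", "VL2"),
        ReporterDef("deltaCMV_carrier", "CARRIER", 1000),
    )
    undamaged = (
        ReporterDef("pMax_BFP", "NHEJ", 100, "BFP", "VL1"),
        ReporterDef("pMax_GFP", "MMEJ", 100, "GFP", "BL1"),
        ReporterDef("pMax_mCherry", "HR", 100, "mCherry", "YL1"),
        ReporterDef("pMax_AmCyan", "TRANSFECTION_CONTROL", 100, "AmCyan", "VL2"),
        ReporterDef("deltaCMV_carrier", "CARRIER", 1000),
    )
    return PanelSpec(_CHANNELS, damaged, undamaged, "AmCyan")


def matched_mass_panel() -> PanelSpec:
    """Variant of :func:`default_panel` with 100 ng of every scored reporter
    in both cocktails, so expected %Reporter Expression equals
    100 x repair efficiency for every pathway (used for recovery studies)."""
    base = default_panel()
    damaged = tuple(
        ReporterDef(r.reporter_name, r.pathway, 100 if r.pathway == "MMEJ" else r.mass_ng,
                    r.fluorophore, r.channel, r.damaged)
        for r in base.damaged_cocktail
    )
    return PanelSpec(base.channels, damaged, base.undamaged_cocktail, base.control_fluorophore)
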