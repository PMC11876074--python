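"""Event-level file formats and sample-sheet handling.

The pipeline's atom is the :class:`EventTable` — a per-event channel matrix
(time, scatter, fluorescence) plus sample metadata.  Two on-disk formats are
supported:

* a plain CSV dialect: one header row of channel names, one event per row,
  UTF-8, ``.`` decimal separator;
* FCS 3.1 list-mode files (single data set, 32-bit float, little-endian),
  via a small reader/writer that covers the required keyword set
  ($TOT, $PAR, $PnN/$PnB/$PnE/$PnR, $BTIM/$ETIM, segment offsets).

Channel names are normalised through a configurable map so that e.g. a
"FITC-A" detector can feed the pipeline's "GFP-A" slot.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: channels every sample must provide for the full pipeline
REQUIRED_CHANNELS = (
    "time_s",
    "FSC-A",
    "FSC-H",
    "SSC-A",
    "GFP-A",
    "BFP-A",
    "speck_metric",
)

#: default detector saturation value (18-bit digitiser convention)
DEFAULT_CHANNEL_MAX = 262144.0

#: channels whose dynamic range is checked by QC
FLUORESCENCE_CHANNELS = ("GFP-A", "BFP-A", "speck_metric")

#: default per-channel ranges ($PnR analogue)
DEFAULT_CHANNEL_RANGES = {
    "time_s": 1e6,
    "FSC-A": DEFAULT_CHANNEL_MAX,
    "FSC-H": DEFAULT_CHANNEL_MAX,
    "SSC-A": DEFAULT_CHANNEL_MAX,
    "GFP-A": DEFAULT_CHANNEL_MAX,
    "BFP-A": DEFAULT_CHANNEL_MAX,
    "speck_metric": 1.5,
}


class ChannelError(ValueError):
    """A required channel is missing or inconsistent."""


class FormatError(ValueError):
    """A file does not conform to the documented CSV/FCS dialect."""


@dataclass
class EventTable:
    """Per-event channel matrix with sample metadata.

    Parameters
    ----------
    data
        One column per channel, one row per event.
    sample_id
        Free-text identifier, usually the file stem.
    channel_ranges
        Detector range per channel (the FCS ``$PnR`` analogue); used by QC's
        dynamic-range rule and by the anomaly injector.
    meta
        Additional keywords (acquisition times, provenance, ...).
    """

    data: pd.DataFrame
    sample_id: str = ""
    channel_ranges: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        for ch in self.data.columns:
            self.channel_ranges.setdefault(
                ch, DEFAULT_CHANNEL_RANGES.get(ch, DEFAULT_CHANNEL_MAX)
            )

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list:
        return list(self.data.columns)

    def require(self, *channels: str) -> None:
        missing = [c for c in channels if c not in self.data.columns]
        if missing:
            raise ChannelError(
                f"sample {self.sample_id!r} is missing required channel(s): "
                + ", ".join(missing)
            )

    def copy(self) -> "EventTable":
        return EventTable(
            data=self.data.copy(),
            sample_id=self.sample_id,
            channel_ranges=dict(self.channel_ranges),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_events_csv(table: EventTable, path) -> None:
    """Write the documented CSV dialect (header row, one event per row).

    Floats are written with ``repr`` so the round trip is bit-exact.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(table.channels)
        cols = [table.data[c].to_numpy() for c in table.channels]
        for row in zip(*cols):
            writer.writerow([repr(float(v)) for v in row])


def read_events_csv(path, channel_map: dict | None = None) -> EventTable:
    """Read the documented CSV dialect into an :class:`EventTable`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=np.float64, float_precision="round_trip")
    if channel_map:
        df = df.rename(columns=channel_map)
    return EventTable(data=df, sample_id=path.stem)


# ---------------------------------------------------------------------------
# FCS 3.1 (minimal list-mode codec)
# ---------------------------------------------------------------------------

_DELIM = "/"


def _text_segment(keywords: dict) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        parts.append(str(k))
        parts.append(_DELIM)
        parts.append(str(v))
        parts.append(_DELIM)
    return "".join(parts).encode("utf-8")


def write_fcs(table: EventTable, path) -> None:
    """Write a single-dataset FCS 3.1 file (float32, little-endian)."""
    path = Path(path)
    data = np.ascontiguousarray(
        table.data.to_numpy(dtype=np.float32, copy=True)
    )
    n_events, n_par = data.shape
    t = table.data["time_s"] if "time_s" in table.data else None
    btim = table.meta.get("$BTIM", "00:00:00")
    etim = table.meta.get("$ETIM", "00:00:00")
    if t is not None and len(t):
        span = float(t.iloc[-1])
        h, rem = divmod(int(span), 3600)
        m, s = divmod(rem, 60)
        etim = table.meta.get("$ETIM", f"{h:02d}:{m:02d}:{s:02d}")

    keywords = {
        "$BEGINANALYSIS": 0,
        "$ENDANALYSIS": 0,
        "$BEGINSTEXT": 0,
        "$ENDSTEXT": 0,
        # placeholders, fixed width so offsets are stable
        "$BEGINDATA": "0" * 10,
        "$ENDDATA": "0" * 10,
        "$NEXTDATA": 0,
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$TOT": n_events,
        "$PAR": n_par,
        "$BTIM": btim,
        "$ETIM": etim,
    }
    for i, ch in enumerate(table.channels, start=1):
        keywords[f"$P{i}N"] = ch
        keywords[f"$P{i}B"] = 32
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = int(np.ceil(table.channel_ranges.get(ch, DEFAULT_CHANNEL_MAX)))

    header_len = 58
    text = _text_segment(keywords)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1

    keywords["$BEGINDATA"] = f"{data_start:010d}"
    keywords["$ENDDATA"] = f"{data_end:010d}"
    text = _text_segment(keywords)
    assert text_start + len(text) - 1 == text_end  # widths fixed

    header = b"FCS3.1    "
    header += f"{text_start:8d}".encode()
    header += f"{text_end:8d}".encode()
    if data_end <= 99_999_999:
        header += f"{data_start:8d}".encode()
        header += f"{data_end:8d}".encode()
    else:  # large files defer to TEXT offsets
        header += f"{0:8d}".encode() * 2
    header += f"{0:8d}".encode() * 2  # no ANALYSIS segment
    assert len(header) == header_len

    with path.open("wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path, channel_map: dict | None = None) -> EventTable:
    """Read a single-dataset FCS 3.0/3.1 list-mode file.

    Supports float32/float64 list-mode data with a uniform ``$BYTEORD``;
    raises :class:`FormatError` when ``$TOT`` disagrees with the data
    segment length.
    """
    path = Path(path)
    raw = path.read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FormatError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header") from exc

    text = raw[text_start : text_end + 1].decode("utf-8", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FormatError(f"{path}: odd keyword/value count in TEXT segment")
    kw = {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}

    data_start = int(kw.get("$BEGINDATA", 0)) or int(raw[26:34] or 0)
    data_end = int(kw.get("$ENDDATA", 0)) or int(raw[34:42] or 0)
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code == "F":
        itemsize, np_type = 4, "f4"
    elif dtype_code == "D":
        itemsize, np_type = 8, "f8"
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    seg = raw[data_start : data_end + 1]
    n_values = len(seg) // itemsize
    if n_values != n_par * n_tot:
        raise FormatError(
            f"{path}: $TOT={n_tot} x $PAR={n_par} disagrees with data "
            f"segment ({n_values} values)"
        )
    arr = np.frombuffer(seg, dtype=endian + np_type).reshape(n_tot, n_par)

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    ranges = {}
    for i, name in enumerate(names, start=1):
        if f"$P{i}R" in kw:
            try:
                ranges[name] = float(kw[f"$P{i}R"])
            except ValueError:
                pass
    df = pd.DataFrame(np.asarray(arr, dtype=np.float64), columns=names)
    if channel_map:
        df = df.rename(columns=channel_map)
        ranges = {channel_map.get(k, k): v for k, v in ranges.items()}
    meta = {k: v for k, v in kw.items() if k in ("$BTIM", "$ETIM", "$DATE", "$CYT")}
    return EventTable(
        data=df, sample_id=path.stem, channel_ranges=ranges, meta=meta
    )


def read_events(path, format_hint: str | None = None,
                channel_map: dict | None = None,
                required: tuple = REQUIRED_CHANNELS) -> EventTable:
    """Read an event file, dispatching on ``format_hint`` or the suffix.

    After channel-name mapping, presence of the pipeline's required channels
    is checked and the missing names are listed in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "fcs":
        table = read_fcs(path, channel_map)
    elif fmt in ("csv", "txt"):
        table = read_events_csv(path, channel_map)
    else:
        raise FormatError(f"unknown event-file format {fmt!r} for {path}")
    if required:
        table.require(*required)
    return table


def write_events(table: EventTable, path, format_hint: str | None = None) -> None:
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "fcs":
        write_fcs(table, path)
    elif fmt in ("csv", "txt"):
        write_events_csv(table, path)
    else:
        raise FormatError(f"unknown event-file format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("file", "variant_label", "condition", "replicate",
                        "batch", "role")
ROLES = ("wt_control", "variant", "untransfected_control")


@dataclass
class SampleSheet:
    """Maps event files to (variant, condition, replicate, batch, role)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.rows.columns]
        if missing:
            raise FormatError(
                "sample sheet is missing column(s): " + ", ".join(missing)
            )
        if len(self.rows) == 0:
            raise FormatError("sample sheet is empty")
        bad_roles = set(self.rows["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown role(s) in sample sheet: {sorted(bad_roles)}")
        for batch, grp in self.rows.groupby("batch"):
            if not (grp["role"] == "wt_control").any():
                raise FormatError(f"batch {batch!r} has no wt_control sample")
            keys = grp.loc[grp["role"] != "untransfected_control",
                           ["variant_label", "condition", "replicate"]]
            if keys.duplicated().any():
                dup = keys[keys.duplicated()].iloc[0].tolist()
                raise FormatError(
                    f"batch {batch!r}: duplicate (variant, condition, replicate) {dup}"
                )

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        return cls(pd.read_csv(path, sep=sep, dtype={"replicate": str, "batch": str}))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.rows)
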