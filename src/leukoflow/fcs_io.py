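"""FCS 3.0/3.1 I/O for the 12-channel ALOT panel, plus label sidecars and manifests.

Implements the subset of the Flow Cytometry Standard needed to round-trip
ALOT event data: list mode ($MODE=L), single-precision float ($DATATYPE=F),
little- or big-endian on read, little-endian FCS 3.1 on write. Channels are
located by their stain name ($PnS) first and short name ($PnN) second, via a
case-insensitive pattern table, because vendor naming of the same antibody
varies between instruments.

Per-event cell-type labels travel as CSV sidecars (``event_index,label``)
rather than FCS keywords; a cohort manifest CSV
(``sample_id,fcs_path,label_path,diagnosis``) ties samples together.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, CapExceeded, FormatError, PanelMismatch, UnknownLabel
from .vocab import CELL_TYPES, DEBRIS, DIAGNOSES

logger = logging.getLogger(__name__)

#: Hard cap on events per sample (instrument export limit for ALOT acquisitions).
DEFAULT_EVENT_CAP = 250_000

FLUORESCENCE_CHANNELS: tuple[str, ...] = (
    "CyCD3", "CD45", "CyMPO", "CyCD79a", "CD34", "CD19", "CD7", "SmCD3",
)
SCATTER_CHANNELS: tuple[str, ...] = ("FSC-A", "FSC-H", "SSC-A", "SSC-H")

#: Full marker-fluorochrome stain names written to $PnS.
STAIN_NAMES: dict[str, str] = {
    "CyCD3": "CyCD3-PacB",
    "CD45": "CD45-KrO",
    "CyMPO": "CyMPO-FITC",
    "CyCD79a": "CyCD79a-PE",
    "CD34": "CD34-PerCP-Cy5.5",
    "CD19": "CD19-PC7",
    "CD7": "CD7-APC",
    "SmCD3": "SmCD3-APCH7",
    "FSC-A": "FSC-A",
    "FSC-H": "FSC-H",
    "SSC-A": "SSC-A",
    "SSC-H": "SSC-H",
}

# Claim order matters: CyCD79a before CD7, and the cytoplasmic/surface CD3
# patterns before bare CD7, so substring collisions (cd7 in cd79a) cannot
# steal a parameter. Patterns are matched against lower-cased $PnS then $PnN.
_CHANNEL_PATTERNS: tuple[tuple[str, str], ...] = (
    ("FSC-A", r"fsc[-_ ]?a"),
    ("FSC-H", r"fsc[-_ ]?h"),
    ("SSC-A", r"ssc[-_ ]?a"),
    ("SSC-H", r"ssc[-_ ]?h"),
    ("CD45", r"cd45"),
    ("CD34", r"cd34"),
    ("CD19", r"cd19"),
    ("CyCD79a", r"cd79"),
    ("CyMPO", r"mpo"),
    ("CyCD3", r"(cy|c)[-_ ]?cd3(?![0-9])"),
    ("SmCD3", r"(sm|s)[-_ ]?cd3(?![0-9])"),
    ("CD7", r"cd7(?![0-9])"),
)


@dataclass(frozen=True)
class ChannelPanel:
    """The ordered 12-channel ALOT panel: 8 fluorescence markers + 4 scatter."""

    names: tuple[str, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != 12:
            raise PanelMismatch(f"panel must have 12 channels, got {len(self.names)}")
        if len(set(self.names)) != 12:
            raise PanelMismatch("panel channel names must be unique")
        if len(self.roles) != 12 or set(self.roles) - {"fluorescence", "scatter"}:
            raise PanelMismatch("roles must be 12 tags from {fluorescence, scatter}")
        if self.roles.count("fluorescence") != 8 or self.roles.count("scatter") != 4:
            raise PanelMismatch("panel must have 8 fluorescence and 4 scatter channels")

    @property
    def fluorescence_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "fluorescence"])

    @property
    def scatter_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "scatter"])

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_PANEL = ChannelPanel(
    names=FLUORESCENCE_CHANNELS + SCATTER_CHANNELS,
    roles=("fluorescence",) * 8 + ("scatter",) * 4,
)


@dataclass
class EventMatrix:
    """One sample's events-by-channel intensity matrix with panel metadata."""

    sample_id: str
    values: np.ndarray
    panel: ChannelPanel = DEFAULT_PANEL
    max_events: int = DEFAULT_EVENT_CAP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.panel.names):
            raise PanelMismatch(
                f"event matrix must be n x {len(self.panel.names)}, got {self.values.shape}"
            )
        n = self.values.shape[0]
        if n < 1:
            raise FormatError("event matrix must contain at least one event")
        if n > self.max_events:
            raise CapExceeded(f"{n} events exceeds cap of {self.max_events}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("event matrix contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# FCS binary segments
# ---------------------------------------------------------------------------

_HEADER_LEN = 58
_DELIM = "/"


def _build_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        if _DELIM in key or _DELIM in str(value):
            raise FormatError(f"delimiter {_DELIM!r} inside keyword {key}={value!r}")
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(em: EventMatrix, path: str | Path) -> Path:
    """Write an :class:`EventMatrix` as FCS 3.1, float, list mode, little-endian.

    ``read_fcs(write_fcs(em))`` reproduces values to float32 precision with
    event order preserved.
    """
    path = Path(path)
    data = em.values.astype("<f4").tobytes()
    n_events, n_par = em.values.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # placeholders, fixed width, patched below
        "$BEGINDATA": "0" * 10,
        "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(em.panel.names, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}S"] = STAIN_NAMES.get(name, name)
        keywords[f"$P{i}R"] = "262144"

    text = _build_text(keywords)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1

    keywords["$BEGINDATA"] = str(data_start).rjust(10, "0")
    keywords["$ENDDATA"] = str(data_end).rjust(10, "0")
    text = _build_text(keywords)
    assert text_end == text_start + len(text) - 1  # widths fixed, length unchanged

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    path.write_bytes(header + text + data)
    return path


def _parse_header(raw: bytes) -> tuple[str, list[int]]:
    if len(raw) < _HEADER_LEN:
        raise FormatError("file shorter than an FCS header")
    version = raw[:10].decode("ascii", errors="replace").strip()
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r} (need FCS 3.0/3.1)")
    offsets = []
    for i in range(6):
        fld = raw[10 + 8 * i : 18 + 8 * i].decode("ascii", errors="replace").strip()
        try:
            offsets.append(int(fld) if fld else 0)
        except ValueError as exc:
            raise FormatError(f"non-numeric header offset field {fld!r}") from exc
    return version, offsets


def _parse_text(raw: bytes, start: int, end: int) -> dict[str, str]:
    if end <= start or end >= len(raw):
        raise FormatError("TEXT segment offsets outside file")
    seg = raw[start : end + 1].decode("ascii", errors="replace")
    delim = seg[0]
    # split on delimiter; FCS allows escaped delimiters (doubled) but our
    # subset never emits them inside values
    fields = seg[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of delimited fields")
    return {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields), 2)}


def _map_panel(kw: dict[str, str], n_par: int, panel: ChannelPanel) -> list[int]:
    """Return the 0-based parameter index for each panel channel in order."""
    pns = [kw.get(f"$P{i}S", "").lower() for i in range(1, n_par + 1)]
    pnn = [kw.get(f"$P{i}N", "").lower() for i in range(1, n_par + 1)]
    claimed: dict[str, int] = {}
    taken: set[int] = set()
    for channel, pattern in _CHANNEL_PATTERNS:
        if channel not in panel.names:
            continue
        rx = re.compile(pattern)
        hit = None
        for j in range(n_par):
            if j in taken:
                continue
            if rx.search(pns[j]) or rx.search(pnn[j]):
                hit = j
                break
        if hit is None:
            raise PanelMismatch(
                f"panel channel {channel!r} not found among $PnS/$PnN names"
            )
        claimed[channel] = hit
        taken.add(hit)
    extra = [kw.get(f"$P{j + 1}N", f"P{j + 1}") for j in range(n_par) if j not in taken]
    if extra:
        logger.warning("ignoring %d extra FCS parameter(s): %s", len(extra), extra)
    return [claimed[name] for name in panel.names]


def read_fcs(
    path: str | Path,
    panel: ChannelPanel = DEFAULT_PANEL,
    sample_id: str | None = None,
    max_events: int = DEFAULT_EVENT_CAP,
) -> EventMatrix:
    """Read an FCS 3.0/3.1 file and select the 12 ALOT panel channels by name.

    Extra instrument parameters (e.g. ``Time``) are ignored with a logged
    warning. Raises :class:`FormatError` for malformed segments or non-finite
    data and :class:`PanelMismatch` when a panel channel cannot be mapped.
    """
    path = Path(path)
    raw = path.read_bytes()
    _, offsets = _parse_header(raw)
    text_start, text_end = offsets[0], offsets[1]
    kw = _parse_text(raw, text_start, text_end)

    def _kw_int(key: str) -> int:
        try:
            return int(kw[key])
        except KeyError as exc:
            raise FormatError(f"required keyword {key} missing") from exc
        except ValueError as exc:
            raise FormatError(f"keyword {key} is not an integer: {kw[key]!r}") from exc

    data_start = _kw_int("$BEGINDATA") if "$BEGINDATA" in kw else offsets[2]
    data_end = _kw_int("$ENDDATA") if "$ENDDATA" in kw else offsets[3]
    # header offsets, when present, must agree with TEXT
    if offsets[2] and offsets[2] != data_start:
        raise FormatError(
            f"header DATA start {offsets[2]} disagrees with TEXT $BEGINDATA {data_start}"
        )
    if offsets[3] and offsets[3] != data_end:
        raise FormatError(
            f"header DATA end {offsets[3]} disagrees with TEXT $ENDDATA {data_end}"
        )

    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"only list mode supported, got $MODE={kw.get('$MODE')!r}")
    datatype = kw.get("$DATATYPE", "").upper()
    if datatype != "F":
        raise FormatError(f"only $DATATYPE=F supported, got {datatype!r}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord == "1,2,3,4":
        dtype = "<f4"
    elif byteord == "4,3,2,1":
        dtype = ">f4"
    else:
        raise FormatError(f"unsupported $BYTEORD {byteord!r}")

    n_par = _kw_int("$PAR")
    n_tot = _kw_int("$TOT")
    if n_par < 12:
        raise PanelMismatch(f"file declares {n_par} parameters; panel needs 12")
    for i in range(1, n_par + 1):
        if kw.get(f"$P{i}B", "32") != "32":
            raise FormatError(f"only 32-bit float parameters supported ($P{i}B)")

    expected = n_tot * n_par * 4
    if data_end - data_start + 1 != expected or data_end >= len(raw):
        raise FormatError(
            f"DATA segment length {data_end - data_start + 1} does not match "
            f"$TOT x $PAR x 4 = {expected}"
        )
    values = np.frombuffer(raw[data_start : data_end + 1], dtype=dtype).reshape(
        n_tot, n_par
    )
    if not np.all(np.isfinite(values)):
        raise FormatError("FCS data contains NaN or Inf values")

    cols = _map_panel(kw, n_par, panel)
    return EventMatrix(
        sample_id=sample_id if sample_id is not None else path.stem,
        values=values[:, cols].astype(np.float64),
        panel=panel,
        max_events=max_events,
    )


# ---------------------------------------------------------------------------
# Label sidecars and cohort manifest
# ---------------------------------------------------------------------------


def write_label_sidecar(labels: np.ndarray, path: str | Path) -> Path:
    """Write per-event labels as a CSV sidecar with columns event_index,label."""
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        if lab not in CELL_TYPES:
            raise UnknownLabel(f"label {lab!r} outside the 16-class vocabulary")
    path = Path(path)
    pd.DataFrame(
        {"event_index": np.arange(len(labels)), "label": labels}
    ).to_csv(path, index=False)
    return path


def read_label_sidecar(path: str | Path, n_events: int) -> np.ndarray:
    """Read a label sidecar into a vector aligned to the event-matrix rows.

    Events without a sidecar row default to ``debris`` (ungated events are
    non-classified by convention). Labels outside the 16-class vocabulary
    raise :class:`UnknownLabel`.
    """
    df = pd.read_csv(path, dtype={"event_index": int, "label": str})
    if not {"event_index", "label"} <= set(df.columns):
        raise FormatError(f"sidecar {path} must have columns event_index,label")
    labels = np.full(n_events, DEBRIS, dtype=object)
    idx = df["event_index"].to_numpy()
    if len(idx) and (idx.min() < 0 or idx.max() >= n_events):
        raise AlignmentError(
            f"sidecar event_index range [{idx.min()}, {idx.max()}] "
            f"outside 0..{n_events - 1}"
        )
    for lab in df["label"].unique():
        if lab not in CELL_TYPES:
            raise UnknownLabel(f"label {lab!r} outside the 16-class vocabulary")
    labels[idx] = df["label"].to_numpy()
    return labels.astype("U16")


MANIFEST_COLUMNS = ("sample_id", "fcs_path", "label_path", "diagnosis")


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    bad = set(df["diagnosis"].unique()) - set(DIAGNOSES)
    if bad:
        raise UnknownLabel(f"diagnoses {sorted(bad)} outside {DIAGNOSES}")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns {sorted(missing)}")
    bad = set(df["diagnosis"].unique()) - set(DIAGNOSES)
    if bad:
        raise UnknownLabel(f"diagnoses {sorted(bad)} outside {DIAGNOSES}")
    return df
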