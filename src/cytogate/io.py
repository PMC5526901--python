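"""FCS list-mode file handling and event-table plumbing.

Flow cytometers emit FCS files: a text HEADER giving byte offsets, a TEXT
segment of delimited ``$KEYWORD/value`` pairs, and a binary DATA segment of
per-event channel intensities.  This module reads FCS 2.0/3.0/3.1 list-mode
files into :class:`EventTable`, writes FCS 3.1 (float, little-endian), and
provides the channel harmonization / transform / subsampling steps that
cross-laboratory analysis needs.

Ground-truth population labels (from the simulator) have no standard FCS
segment, so they travel in a CSV sidecar keyed by event id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized channel roles. ``multimer-PE`` / ``multimer-APC`` are the two
#: fluorochrome-conjugated peptide-MHC multimer channels; ``dump`` pools
#: lineage-exclusion markers (CD4/CD14/CD16/CD19...).
ROLES = (
    "FSC-A",
    "FSC-H",
    "SSC-A",
    "viability",
    "dump",
    "CD3",
    "CD8",
    "multimer-PE",
    "multimer-APC",
    "unused",
)

#: Roles measured by light scatter rather than fluorescence; these stay on
#: the raw linear scale when fluorescence channels are arcsinh-transformed.
SCATTER_ROLES = frozenset({"FSC-A", "FSC-H", "SSC-A"})


class FCSFormatError(ValueError):
    """Malformed or unsupported FCS file content."""


class ChannelMismatchError(ValueError):
    """Tables do not share a harmonized channel set."""


@dataclass
class ChannelInfo:
    """One detector channel: FCS $PnN short name, optional $PnS stain label,
    and its analysis role."""

    short_name: str
    stain_label: str | None = None
    role: str = "unused"

    def __post_init__(self) -> None:
        if not self.short_name:
            raise ValueError("channel short_name must be nonempty")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; valid: {ROLES}")

    @property
    def display_name(self) -> str:
        return self.stain_label or self.short_name


@dataclass
class EventTable:
    """n_events x n_channels intensity matrix with channel metadata.

    Parameters
    ----------
    values
        Intensities, one row per event, arbitrary linear units (or arcsinh
        units after :func:`arcsinh_transform`).
    channels
        Per-column :class:`ChannelInfo`.
    event_ids
        Stable 0-based integer identifiers; unique within the table.
    labels
        Optional ground-truth population tag per event (simulator output).
    transform_state
        ``"raw"`` or ``"arcsinh"``.
    source_index
        Optional provenance: index of the source table each event came from
        (set by :func:`subsample_concat`).
    """

    values: np.ndarray
    channels: list[ChannelInfo]
    event_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray | None = None
    transform_state: str = "raw"
    source_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.channels)} channels declared"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all intensities must be finite")
        if self.event_ids is None:
            self.event_ids = np.arange(self.n_events, dtype=np.int64)
        self.event_ids = np.asarray(self.event_ids, dtype=np.int64)
        if self.event_ids.shape != (self.n_events,):
            raise ValueError("event_ids must have one entry per event")
        if np.unique(self.event_ids).size != self.n_events:
            raise ValueError("event_ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.n_events,):
                raise ValueError("labels, when present, must have length n_events")
        names = [c.short_name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel short_names must be unique within a table")
        role_counts: dict[str, int] = {}
        for c in self.channels:
            if c.role != "unused":
                role_counts[c.role] = role_counts.get(c.role, 0) + 1
        dup = [r for r, k in role_counts.items() if k > 1]
        if dup:
            raise ValueError(f"role(s) assigned to more than one channel: {dup}")
        if self.transform_state not in ("raw", "arcsinh"):
            raise ValueError("transform_state must be 'raw' or 'arcsinh'")

    # ------------------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.short_name for c in self.channels]

    @property
    def roles(self) -> list[str]:
        return [c.role for c in self.channels]

    def role_index(self, role: str) -> int:
        """Column index of the channel carrying `role`."""
        for i, c in enumerate(self.channels):
            if c.role == role:
                return i
        raise KeyError(f"no channel with role {role!r} in table")

    def has_role(self, role: str) -> bool:
        return any(c.role == role for c in self.channels)

    def get_role(self, role: str) -> np.ndarray:
        return self.values[:, self.role_index(role)]

    def take(self, index: np.ndarray) -> "EventTable":
        """Row-subset (or reorder) preserving metadata."""
        index = np.asarray(index)
        return EventTable(
            values=self.values[index],
            channels=[replace(c) for c in self.channels],
            event_ids=self.event_ids[index],
            labels=None if self.labels is None else self.labels[index],
            transform_state=self.transform_state,
            source_index=None if self.source_index is None else self.source_index[index],
        )

    def copy(self) -> "EventTable":
        return self.take(np.arange(self.n_events))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df.insert(0, "event_id", self.event_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df


# ----------------------------------------------------------------------
# FCS reading
# ----------------------------------------------------------------------

_SUPPORTED_VERSIONS = ("FCS2.0", "FCS3.0", "FCS3.1")


def _parse_header(raw: bytes, path: str) -> tuple[int, int, int, int]:
    if len(raw) < 58:
        raise FCSFormatError(f"{path}: HEADER truncated at offset {len(raw)} (< 58 bytes)")
    version = raw[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r} at offset 0")

    def _off(a: int, b: int) -> int:
        txt = raw[a:b].decode("ascii", errors="replace").strip()
        if not txt:
            return 0
        try:
            return int(txt)
        except ValueError as exc:
            raise FCSFormatError(f"{path}: non-numeric HEADER offset at byte {a}") from exc

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    if text_begin <= 0 or text_end < text_begin:
        raise FCSFormatError(f"{path}: invalid TEXT offsets at byte 10")
    return text_begin, text_end, data_begin, data_end


def _parse_text(raw: bytes, begin: int, end: int, path: str) -> dict[str, str]:
    segment = raw[begin : end + 1]
    if not segment:
        raise FCSFormatError(f"{path}: empty TEXT segment at offset {begin}")
    delim = segment[0:1].decode("latin-1")
    body = segment.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 == 1:
        # odd count usually means escaped delimiters we do not support
        raise FCSFormatError(
            f"{path}: TEXT segment at offset {begin} has an odd key/value count"
        )
    kw: dict[str, str] = {}
    for k, v in zip(parts[0::2], parts[1::2]):
        kw[k.strip().upper()] = v.strip()
    return kw


def read_fcs(path: str | Path, role_map: Mapping[str, str] | None = None) -> EventTable:
    """Read an FCS 2.0/3.0/3.1 list-mode file.

    Parameters
    ----------
    path
        File to read.
    role_map
        Optional mapping from channel name ($PnS stain label or $PnN short
        name) to role; matching channels get that role assigned.

    Returns
    -------
    EventTable
        One row per event; values are the stored intensities (assumed
        compensated); ``transform_state`` is ``"raw"``.  The ANALYSIS
        segment, if any, is ignored.
    """
    path = Path(path)
    raw = path.read_bytes()
    text_begin, text_end, data_begin, data_end = _parse_header(raw, str(path))
    kw = _parse_text(raw, text_begin, text_end, str(path))

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"unsupported $MODE {mode!r} (only list mode supported)")
    if "$SPILLOVER" in kw or "SPILL" in kw:
        logger.warning(
            "%s declares a spillover matrix; input is assumed already "
            "compensated and the matrix is NOT applied", path.name
        )

    # FCS 3.x may move DATA offsets into TEXT when the file is large.
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin:
        raise FCSFormatError(f"{path}: invalid DATA offsets")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FCSFormatError("$DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FCSFormatError(f"unsupported integer widths {sorted(set(bits))}")
        dtype = np.dtype(f"{order}u{bits[0] // 8}")
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_tot * n_par * dtype.itemsize
    data = raw[data_begin : data_begin + expected]
    if len(data) < expected:
        raise FCSFormatError(
            f"{path}: DATA segment truncated at offset {data_begin + len(data)} "
            f"({len(data)} of {expected} bytes)"
        )
    values = np.frombuffer(data, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    channels = []
    for i in range(1, n_par + 1):
        short = kw.get(f"$P{i}N", f"P{i}")
        stain = kw.get(f"$P{i}S") or None
        role = "unused"
        if role_map:
            for key in (stain, short):
                if key is not None and key in role_map:
                    role = role_map[key]
                    break
        channels.append(ChannelInfo(short_name=short, stain_label=stain, role=role))

    return EventTable(values=values, channels=channels, transform_state="raw")


# ----------------------------------------------------------------------
# FCS writing
# ----------------------------------------------------------------------

_DELIM = "/"


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write `table` as FCS 3.1, $DATATYPE=F (float32 little-endian), $MODE=L.

    $PnN/$PnS are preserved.  No timestamp keywords are written, so two
    writes of the same table are byte-identical.  Labels are NOT written
    (use :func:`write_label_sidecar`).
    """
    if not table.channels:
        raise ValueError("cannot write a table with zero channels")
    path = Path(path)

    data = table.values.astype("<f4")
    n_tot, n_par = data.shape

    kw: list[tuple[str, str]] = [
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i, c in enumerate(table.channels, start=1):
        col = data[:, i - 1]
        rng = float(np.max(col)) if n_tot else 0.0
        kw.append((f"$P{i}N", c.short_name))
        if c.stain_label:
            kw.append((f"$P{i}S", c.stain_label))
        kw.append((f"$P{i}B", "32"))
        kw.append((f"$P{i}E", "0,0"))
        kw.append((f"$P{i}R", str(int(np.ceil(rng)) + 1)))

    data_bytes = data.tobytes()

    # Two-pass: offsets depend on TEXT length, which contains the offsets.
    def render(text_kw: list[tuple[str, str]]) -> bytes:
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in text_kw) + _DELIM
        return body.encode("latin-1")

    header_len = 58
    base_kw = kw
    begin_data = end_data = 0
    text = b""
    for _ in range(3):  # fixed point: offset digit counts stabilize quickly
        full_kw = [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))] + base_kw
        text = render(full_kw)
        new_begin = header_len + len(text)
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    text_begin = header_len
    text_end = text_begin + len(text) - 1

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # too large for HEADER; TEXT keywords carry the truth
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_begin) + fmt(text_end)
    header += fmt(begin_data if end_data <= 99_999_999 else 0)
    header += fmt(end_data if end_data <= 99_999_999 else 0)
    header += fmt(0) + fmt(0)  # no ANALYSIS segment

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)
    return path


def write_label_sidecar(table: EventTable, path: str | Path) -> Path:
    """Write ground-truth labels as a CSV sidecar (columns event_id,label)."""
    if table.labels is None:
        raise ValueError("table carries no labels")
    path = Path(path)
    pd.DataFrame({"event_id": table.event_ids, "label": table.labels}).to_csv(
        path, index=False
    )
    return path


def read_label_sidecar(table: EventTable, path: str | Path) -> EventTable:
    """Attach labels from a CSV sidecar.

    The sidecar rows are written in table row order; when the row counts
    match, labels (and the original event ids, which FCS does not store)
    are attached positionally.  Otherwise the join is by event_id.
    """
    df = pd.read_csv(path)
    out = table.copy()
    if len(df) == table.n_events:
        out.event_ids = df["event_id"].to_numpy(dtype=np.int64)
        out.labels = df["label"].to_numpy()
    else:
        indexed = df.set_index("event_id")
        out.labels = indexed.loc[table.event_ids, "label"].to_numpy()
    return out


# ----------------------------------------------------------------------
# Harmonization / transforms / consensus
# ----------------------------------------------------------------------


def harmonize_channels(table: EventTable, rename_map: Mapping[str, str]) -> EventTable:
    """Uniformly rename channels across files from different instruments.

    Keys of `rename_map` are matched against stain_label first, falling back
    to short_name.  The intensity matrix is untouched.  Mapping two distinct
    source channels onto one target name is a conflict error; a key matching
    no channel logs a warning.
    """
    out = table.copy()
    matched: dict[str, int] = {}
    for key, target in rename_map.items():
        hit = None
        for i, c in enumerate(out.channels):
            if c.stain_label == key:
                hit = i
                break
        if hit is None:
            for i, c in enumerate(out.channels):
                if c.short_name == key:
                    hit = i
                    break
        if hit is None:
            warnings.warn(f"harmonize_channels: key {key!r} matches no channel")
            continue
        if target in matched and matched[target] != hit:
            raise ValueError(
                f"harmonize_channels: channels {key!r} and others both map to "
                f"{target!r}"
            )
        matched[target] = hit
        out.channels[hit].stain_label = target
    # uniqueness check on resulting display names
    seen: dict[str, int] = {}
    for i, c in enumerate(out.channels):
        name = c.display_name
        if name in seen:
            raise ValueError(
                f"harmonize_channels: two channels share the target name {name!r}"
            )
        seen[name] = i
    return out


def arcsinh_transform(
    table: EventTable, cofactor: float | Mapping[str, float] = 150.0
) -> EventTable:
    """Map fluorescence channels x -> asinh(x / cofactor); scatter untouched.

    `cofactor` may be a single positive number or a per-role mapping.
    Double application is a state error.
    """
    if table.transform_state != "raw":
        raise ValueError("arcsinh_transform: table is already transformed")
    out = table.copy()
    for i, c in enumerate(out.channels):
        if c.role in SCATTER_ROLES:
            continue
        cf = cofactor[c.role] if isinstance(cofactor, Mapping) else cofactor
        if not cf > 0:
            raise ValueError(f"cofactor for {c.role} must be positive, got {cf}")
        out.values[:, i] = np.arcsinh(out.values[:, i] / cf)
    out.transform_state = "arcsinh"
    return out


def subsample_concat(
    tables: Sequence[EventTable], n_per_table: int, seed: int
) -> EventTable:
    """Build a consensus table: sample without replacement up to `n_per_table`
    events from each table and concatenate.

    Source-table provenance is recorded per event (``source_index``).
    Deterministic given `seed`.  An undersized table contributes all its
    events with a warning.
    """
    if not tables:
        raise ValueError("subsample_concat: need at least one table")
    ref = tables[0].channel_names
    for j, t in enumerate(tables[1:], start=1):
        if t.channel_names != ref:
            missing = set(ref) ^ set(t.channel_names)
            raise ChannelMismatchError(
                f"table {j} channel set differs from table 0: {sorted(missing)}"
            )
    rng = np.random.default_rng(seed)
    parts, sources, labels = [], [], []
    any_labels = all(t.labels is not None for t in tables)
    for j, t in enumerate(tables):
        n_take = min(n_per_table, t.n_events)
        if n_take < n_per_table:
            warnings.warn(
                f"subsample_concat: table {j} has only {t.n_events} events "
                f"(< {n_per_table} requested); taking all"
            )
        idx = rng.choice(t.n_events, size=n_take, replace=False)
        parts.append(t.values[idx])
        sources.append(np.full(n_take, j, dtype=np.int64))
        if any_labels:
            labels.append(t.labels[idx])  # type: ignore[index]
    values = np.concatenate(parts, axis=0)
    return EventTable(
        values=values,
        channels=[replace(c) for c in tables[0].channels],
        event_ids=np.arange(values.shape[0], dtype=np.int64),
        labels=np.concatenate(labels) if any_labels else None,
        transform_state=tables[0].transform_state,
        source_index=np.concatenate(sources),
    )
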