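"""Event-level cytometry data: containers, CSV/FCS I/O, channel binding.

The :class:`EventTable` is the universal currency between pipeline stages:
one row per measured event (cell), one column per fluorescence channel, raw
instrument-exported intensities in arbitrary units.  No compensation or
display transform is ever applied — quantification works on the values as
stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _fcs
from .errors import ConfigError, FormatError, ValidationError

#: Metadata keys carried through I/O (FCS TEXT keywords or CSV ``meta_`` columns).
META_KEYS = tuple(_fcs.META_KEYWORDS)


@dataclass
class EventTable:
    """Events x channels matrix of raw fluorescence intensities.

    Parameters
    ----------
    values
        Shape ``(n_events, n_channels)`` float array, arbitrary units.
    channel_names
        Unique channel names, one per column, in file order.
    meta
        Optional sample annotations (``sample_id``, ``donor_id``, ``tissue``,
        ``stimulation``, ``replicate_id``, ``condition``), all strings.
    """

    values: np.ndarray
    channel_names: list[str]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("EventTable values must be a 2-D matrix")
        n_events, n_channels = self.values.shape
        if n_events < 1 or n_channels < 1:
            raise ValidationError(
                f"EventTable needs at least 1 event and 1 channel, got "
                f"{n_events} x {n_channels}"
            )
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n_channels} columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError(f"duplicate channel names: {self.channel_names}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Intensity vector of one channel by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ValidationError(
                f"channel {name!r} not in table (have {self.channel_names})"
            ) from None
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


@dataclass(frozen=True)
class ChannelMap:
    """Names the channels playing each role in the assay.

    ``ncaa_signal`` is the clicked azide-dye channel reading out nascent
    protein synthesis; ``barcode_a``/``barcode_b`` are the two amine-reactive
    barcoding dyes (omit both for unpooled, one-file-per-condition runs);
    ``markers`` maps lineage-marker roles to channel names; ``viability`` is
    optional.
    """

    ncaa_signal: str
    barcode_a: str | None = None
    barcode_b: str | None = None
    markers: dict[str, str] = field(default_factory=dict)
    viability: str | None = None

    def __post_init__(self) -> None:
        core = [self.ncaa_signal, self.barcode_a, self.barcode_b]
        named = [c for c in core if c is not None]
        if len(set(named)) != len(named):
            raise ConfigError(
                "ncaa_signal, barcode_a and barcode_b must be distinct channels, "
                f"got {named}"
            )
        if (self.barcode_a is None) != (self.barcode_b is None):
            raise ConfigError("barcode_a and barcode_b must be given together")


@dataclass(frozen=True)
class ChannelBinding:
    """Resolved column indices for every role of a :class:`ChannelMap`."""

    ncaa_signal: int
    barcode_a: int | None
    barcode_b: int | None
    markers: dict[str, int]
    viability: int | None


def validate_channels(table: EventTable, cmap: ChannelMap) -> ChannelBinding:
    """Resolve every role in ``cmap`` to a column index of ``table``.

    Fails atomically: if any referenced channel is absent, no binding is
    returned and the error names every (role, channel) pair that failed.
    """
    index = {name: i for i, name in enumerate(table.channel_names)}
    missing: list[str] = []

    def _resolve(role: str, name: str | None) -> int | None:
        if name is None:
            return None
        if name not in index:
            missing.append(f"{role}={name!r}")
            return None
        return index[name]

    ncaa = _resolve("ncaa_signal", cmap.ncaa_signal)
    bc_a = _resolve("barcode_a", cmap.barcode_a)
    bc_b = _resolve("barcode_b", cmap.barcode_b)
    markers = {
        role: _resolve(f"markers.{role}", name) for role, name in cmap.markers.items()
    }
    viability = _resolve("viability", cmap.viability)
    if missing:
        raise ConfigError(
            "channel map references channels absent from the event table: "
            + ", ".join(missing)
        )
    return ChannelBinding(
        ncaa_signal=ncaa,  # type: ignore[arg-type]
        barcode_a=bc_a,
        barcode_b=bc_b,
        markers=markers,  # type: ignore[arg-type]
        viability=viability,
    )


def read_event_table(path: str | Path, format: str | None = None) -> EventTable:
    """Read an event table from CSV or FCS.

    ``format`` is inferred from the suffix when not given ("fcs" vs "csv").
    Values are returned exactly as stored; events keep file order.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "fcs":
        values, names, meta = _fcs.read_fcs(path)
        return EventTable(values=values, channel_names=names, meta=meta)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValidationError(f"{path}: empty file") from None
        if frame.shape[0] < 1:
            raise ValidationError(f"{path}: no event rows")
        meta_cols = [c for c in frame.columns if str(c).startswith("meta_")]
        meta = {c[len("meta_"):]: str(frame[c].iloc[0]) for c in meta_cols}
        channels = [c for c in frame.columns if c not in meta_cols]
        if len(set(channels)) != len(channels):
            raise ValidationError(f"{path}: duplicate channel names {channels}")
        values = frame[channels].to_numpy(dtype=np.float64)
        return EventTable(values=values, channel_names=list(channels), meta=meta)
    raise FormatError(f"unsupported event-table format {fmt!r} (use fcs or csv)")


def write_event_table(
    table: EventTable, path: str | Path, format: str | None = None
) -> None:
    """Write an event table as CSV (exact round-trip) or FCS 3.1 (float32)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "fcs":
        _fcs.write_fcs(path, table.values, table.channel_names, table.meta)
        return
    if fmt == "csv":
        frame = table.to_frame()
        for key in META_KEYS:
            if table.meta.get(key):
                frame[f"meta_{key}"] = table.meta[key]
        frame.to_csv(path, index=False)
        return
    raise FormatError(f"unsupported event-table format {fmt!r} (use fcs or csv)")
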