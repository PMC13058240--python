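"""Data model and readers/writers for single-cell event tables, colony counts and OD series.

Per-cell records come from imaging flow-cytometry feature exports: delimited
text with one row per acquired object and named columns for the dye channel
intensity, the autofluorescence channel intensity and the brightfield area.
The on-disk schema is user-defined, so readers take a ``column_map`` from the
roles used here (``intensity_dye``, ``intensity_auto``, ``area``, optionally
``event_id`` and ``true_label``) to the file's column names.

Intensities are kept exactly as read: background-subtracted cytometry values
are frequently zero or negative and must never be clipped or reordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "CultureKind",
    "SampleMeta",
    "EventTable",
    "ODSeries",
    "PlateSeries",
    "DEFAULT_COLUMN_MAP",
    "read_event_table",
    "write_event_table",
    "read_plate_counts",
    "write_plate_counts",
    "read_od_series",
    "write_od_series",
    "read_sample_meta",
    "write_sample_meta",
]

TRUE_LABELS = ("stained", "unstained", "unknown")

#: Schema roles understood by :func:`read_event_table`, mapped to themselves.
DEFAULT_COLUMN_MAP = {
    "event_id": "event_id",
    "intensity_dye": "intensity_dye",
    "intensity_auto": "intensity_auto",
    "area": "area",
    "true_label": "true_label",
}

_NUMERIC_ROLES = ("intensity_dye", "intensity_auto", "area")


class CultureKind(str, Enum):
    MONOCULTURE_STAINED = "monoculture_stained"
    MONOCULTURE_UNSTAINED = "monoculture_unstained"
    COCULTURE = "coculture"


@dataclass
class SampleMeta:
    """Identity and experimental condition of one sample.

    ``initial_ratio`` is the initial volume fraction of the focal competitor
    (``competitor_a``) and is only meaningful for cocultures. For
    monocultures ``competitor_b`` is empty and ``initial_ratio`` is ``None``.
    """

    sample_id: str
    culture_kind: CultureKind
    competitor_a: str
    competitor_b: str = ""
    stained_competitor: Optional[str] = None
    initial_ratio: Optional[float] = None
    predator_present: bool = False
    replicate: int = 1
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.culture_kind = CultureKind(self.culture_kind)
        if self.stained_competitor == "":
            self.stained_competitor = None
        if not self.competitor_a:
            raise ValidationError("competitor_a must be a non-empty label")
        if self.culture_kind is CultureKind.COCULTURE:
            if not self.competitor_b:
                raise ValidationError("coculture requires competitor_b")
            if self.initial_ratio is not None and not 0.0 <= self.initial_ratio <= 1.0:
                raise ValidationError(
                    f"initial_ratio must be in [0, 1], got {self.initial_ratio}"
                )
        if self.stained_competitor is not None and self.stained_competitor not in (
            self.competitor_a,
            self.competitor_b,
        ):
            raise ValidationError(
                f"stained_competitor {self.stained_competitor!r} is neither "
                f"{self.competitor_a!r} nor {self.competitor_b!r}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")
        if self.time_h < 0:
            raise ValidationError("time_h must be non-negative")

    @property
    def condition(self) -> tuple:
        """(initial_ratio, stained_competitor, predator_present) grouping key."""
        return (self.initial_ratio, self.stained_competitor, self.predator_present)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "culture_kind": self.culture_kind.value,
            "competitor_a": self.competitor_a,
            "competitor_b": self.competitor_b,
            "stained_competitor": self.stained_competitor,
            "initial_ratio": self.initial_ratio,
            "predator_present": self.predator_present,
            "replicate": self.replicate,
            "time_h": self.time_h,
        }


@dataclass
class EventTable:
    """Per-cell event records of one sample.

    ``events`` holds one row per acquired object with columns ``event_id``,
    ``intensity_dye`` and optionally ``intensity_auto``, ``area`` and
    ``true_label``. ``true_label`` is ``"unknown"`` for real coculture data
    and known only for monoculture controls and simulated events.
    """

    meta: SampleMeta
    events: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.events
        if "intensity_dye" not in df.columns:
            raise SchemaError("EventTable requires an 'intensity_dye' column")
        if "event_id" not in df.columns:
            df = df.copy()
            df.insert(0, "event_id", np.arange(len(df), dtype=np.int64))
        if "true_label" not in df.columns:
            df = df.copy()
            df["true_label"] = "unknown"
        bad = set(df["true_label"].unique()) - set(TRUE_LABELS)
        if bad:
            raise ValidationError(f"unknown true_label values: {sorted(bad)}")
        for col in _NUMERIC_ROLES:
            if col in df.columns and not np.all(np.isfinite(df[col].to_numpy(float))):
                raise ValidationError(f"non-finite values in column {col!r}")
        self.events = df

    def __len__(self) -> int:
        return len(self.events)

    @property
    def intensity_dye(self) -> np.ndarray:
        return self.events["intensity_dye"].to_numpy(float)

    def with_events(self, events: pd.DataFrame, note: Optional[dict] = None) -> "EventTable":
        prov = list(self.provenance) + ([note] if note else [])
        return EventTable(meta=self.meta, events=events, provenance=prov)


@dataclass
class ODSeries:
    """Optical-density (600 nm) time series of one culture."""

    meta: SampleMeta
    points: pd.DataFrame  # columns: time_h, od600

    def __post_init__(self) -> None:
        df = self.points
        for col in ("time_h", "od600"):
            if col not in df.columns:
                raise SchemaError(f"ODSeries requires column {col!r}")
        t = df["time_h"].to_numpy(float)
        od = df["od600"].to_numpy(float)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(od))):
            raise ValidationError("OD series values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time_h must be strictly increasing")
        if np.any(od < 0):
            raise ValidationError("od600 must be non-negative")


@dataclass
class PlateSeries:
    """Dilution-series colony counts of one sample.

    ``plates`` has one row per plate: a ``dilution_exponent`` column (log10 of
    the dilution factor) plus one non-negative integer count column per
    morphotype.
    """

    meta: Optional[SampleMeta]
    plates: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.plates
        if "dilution_exponent" not in df.columns:
            raise SchemaError("PlateSeries requires column 'dilution_exponent'")
        if len(self.morphotypes) == 0:
            raise SchemaError("PlateSeries requires at least one morphotype column")
        dil = df["dilution_exponent"].to_numpy(float)
        if len(np.unique(dil)) != len(dil):
            raise ValidationError("duplicate dilution_exponent in plate series")
        for m in self.morphotypes:
            counts = df[m].to_numpy(float)
            if np.any(~np.isfinite(counts)) or np.any(counts < 0):
                raise ValidationError(f"negative or non-finite count for morphotype {m!r}")
            if np.any(counts % 1 != 0):
                raise ValidationError(f"non-integer count for morphotype {m!r}")

    @property
    def morphotypes(self) -> list:
        return [c for c in self.plates.columns if c != "dilution_exponent"]


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_event_table(
    path,
    column_map: Mapping[str, str],
    meta: SampleMeta,
) -> EventTable:
    """Read a delimited per-object feature export into an :class:`EventTable`.

    ``column_map`` maps schema roles to the file's column names and must cover
    ``intensity_dye``; ``intensity_auto`` and ``area`` are optional (gating is
    then restricted to the available channels). Row order is preserved and
    intensity values are taken verbatim — negatives included.
    """
    path = Path(path)
    if "intensity_dye" not in column_map:
        raise SchemaError("column_map must cover the role 'intensity_dye'")
    raw = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    for role, col in column_map.items():
        if role in _NUMERIC_ROLES and col not in raw.columns and role != "intensity_dye":
            continue  # optional role not present in this file
        if role == "intensity_dye" and col not in raw.columns:
            raise SchemaError(f"column {col!r} for role 'intensity_dye' not found in {path.name}")

    data: dict = {}
    for role in _NUMERIC_ROLES:
        col = column_map.get(role)
        if col is None or col not in raw.columns:
            continue
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw[col].iloc[idx]!r} for role {role!r} at row {idx}"
            )
        if numeric.isna().any():
            idx = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"missing value for role {role!r} at row {idx}")
        data[role] = numeric.to_numpy(float)

    df = pd.DataFrame(data)
    id_col = column_map.get("event_id")
    if id_col is not None and id_col in raw.columns:
        df.insert(0, "event_id", pd.to_numeric(raw[id_col]).to_numpy(np.int64))
    label_col = column_map.get("true_label")
    if label_col is not None and label_col in raw.columns:
        df["true_label"] = raw[label_col].astype(str).to_numpy()
    return EventTable(meta=meta, events=df)


def _write_full_precision(df: pd.DataFrame, path, sep: str) -> None:
    # shortest round-trip float representation, so read(write(x)) == x exactly
    df.to_csv(path, sep=sep, index=False, float_format=lambda v: repr(float(v)))


def write_event_table(table: EventTable, path, sep: str = ",") -> None:
    """Write an event table as delimited text with full numeric precision."""
    _write_full_precision(table.events, path, sep)


def read_plate_counts(path, meta: Optional[SampleMeta] = None) -> PlateSeries:
    """Read dilution-series colony counts.

    Expects a ``dilution_exponent`` column; every other column is a morphotype
    count. Duplicate dilutions and negative counts are rejected.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    return PlateSeries(meta=meta, plates=raw)


def write_plate_counts(series: PlateSeries, path, sep: str = ",") -> None:
    _write_full_precision(series.plates, path, sep)


def read_od_series(path, meta: Optional[SampleMeta] = None) -> ODSeries:
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    return ODSeries(meta=meta, points=raw)


def write_od_series(series: ODSeries, path, sep: str = ",") -> None:
    _write_full_precision(series.points, path, sep)


def read_sample_meta(path) -> SampleMeta:
    """Read a sidecar metadata record (plain ``key: value`` file)."""
    with open(path, "r", encoding="utf-8") as fh:
        record = yaml.safe_load(fh)
    if not isinstance(record, dict):
        raise ParseError(f"expected a key: value record in {path}")
    return SampleMeta(**record)


def write_sample_meta(meta: SampleMeta, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta.to_dict(), fh, sort_keys=False)
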