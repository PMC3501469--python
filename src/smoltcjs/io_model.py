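"""Core data types and delimited-text I/O.

Defines the typed records shared by every other module (fish, receiver
lines, detection events, encounter histories, segment geometry), CSV
readers/writers with schema validation, and a MARK-compatible ``.inp``
encounter-history exporter.

Canonical CSV schemas (comma-separated, header row required, UTF-8):

``fish.csv``
    fish_id, population, origin, year, fork_length_mm, weight_g,
    smolt_index, release_date, release_site
``receivers.csv``
    receiver_id, line_id, corridor_position_km, occasion_index
    (occasion_index blank for behavioral receivers)
``events.csv``
    fish_id, receiver_id, timestamp

Timestamps are real-valued days from a per-run epoch; ``release_date`` is
a day-of-year integer on the same axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "Origin",
    "FishRecord",
    "ReceiverLine",
    "SegmentGeometry",
    "DetectionEvent",
    "EncounterHistory",
    "SchemaError",
    "ReferentialError",
    "IntegrityError",
    "compute_condition_factor",
    "read_fish",
    "read_receivers",
    "read_events",
    "read_tables",
    "write_fish",
    "write_receivers",
    "write_events",
    "write_inp",
]


class SchemaError(ValueError):
    """A delimited file is missing a required column or has a bad value."""


class ReferentialError(ValueError):
    """A record refers to an entity that does not exist."""


class IntegrityError(ValueError):
    """A uniqueness or consistency constraint is violated."""


class Population(str, enum.Enum):
    BigBeefW = "BigBeefW"
    SkokomishW = "SkokomishW"
    SkokomishH = "SkokomishH"
    DuckabushH = "DuckabushH"


class Origin(str, enum.Enum):
    wild = "wild"
    hatchery = "hatchery"


#: Hatchery-of-rearing level per population (3-level grouping factor).
HATCHERY_OF = {
    Population.BigBeefW: "wild",
    Population.SkokomishW: "wild",
    Population.SkokomishH: "McKernan",
    Population.DuckabushH: "Lilliwaup",
}

#: Origin implied by each population code.
ORIGIN_OF = {
    Population.BigBeefW: Origin.wild,
    Population.SkokomishW: Origin.wild,
    Population.SkokomishH: Origin.hatchery,
    Population.DuckabushH: Origin.hatchery,
}


def compute_condition_factor(weight_g: float, fork_length_mm: float) -> float:
    """Fulton condition factor ``K = 1e5 * weight / length**3``.

    The 1e5 scaling puts gram/millimetre inputs on the conventional
    ~0.8-1.2 scale for salmonid smolts.
    """
    weight_g = np.asarray(weight_g, dtype=float)
    fork_length_mm = np.asarray(fork_length_mm, dtype=float)
    if np.any(weight_g <= 0) or np.any(fork_length_mm <= 0):
        raise ValueError("weight and fork length must be positive")
    k = 1e5 * weight_g / fork_length_mm**3
    return float(k) if k.ndim == 0 else k


@dataclass(frozen=True)
class FishRecord:
    """One tagged smolt with biological covariates and release metadata."""

    fish_id: str
    population: Population
    origin: Origin
    year: int
    fork_length_mm: float
    weight_g: float
    smolt_index: int
    release_date: float  # day-of-year on the run's time axis
    release_site: str
    condition_factor: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.fork_length_mm <= 0 or self.weight_g <= 0:
            raise ValueError(f"{self.fish_id}: non-positive length/weight")
        if self.smolt_index not in (1, 2, 3):
            raise ValueError(f"{self.fish_id}: smolt_index must be 1, 2 or 3")
        if self.condition_factor is None:
            object.__setattr__(
                self,
                "condition_factor",
                compute_condition_factor(self.weight_g, self.fork_length_mm),
            )


@dataclass(frozen=True)
class ReceiverLine:
    """A cross-channel receiver array treated as one encounter occasion.

    ``occasion_index`` is ``None`` for behavioral (non-occasion) receivers.
    Receivers are ``(receiver_id, corridor_position_km)`` pairs on a common
    along-corridor axis increasing seaward.
    """

    line_id: str
    receivers: tuple  # of (receiver_id, corridor_position_km)
    occasion_index: int | None = None

    @property
    def position_km(self) -> float:
        return float(np.mean([pos for _, pos in self.receivers]))

    def receiver_ids(self) -> list[str]:
        return [rid for rid, _ in self.receivers]


@dataclass(frozen=True)
class SegmentGeometry:
    """Ordered migration segments for one population's corridor.

    ``segments`` is a tuple of ``(from_line, to_line, distance_km)`` with
    contiguous endpoints and strictly positive distances.
    """

    population: Population
    segments: tuple  # of (from_line, to_line, distance_km)

    def __post_init__(self):
        for (_, to_a, d), (from_b, _, _) in zip(self.segments, self.segments[1:]):
            if to_a != from_b:
                raise ValueError("segments must be contiguous")
        if any(d <= 0 for _, _, d in self.segments):
            raise ValueError("segment distances must be positive")

    @property
    def distances_km(self) -> np.ndarray:
        return np.array([d for _, _, d in self.segments], dtype=float)

    @property
    def line_order(self) -> list[str]:
        return [self.segments[0][0]] + [to for _, to, _ in self.segments]


@dataclass(frozen=True)
class DetectionEvent:
    """A single acoustic detection of a tagged fish at a receiver."""

    fish_id: str
    receiver_id: str
    timestamp: float  # days since the run epoch


@dataclass
class EncounterHistory:
    """Binary detection vector over occasions; the CJS data unit.

    ``history[0]`` is the release occasion and is always 1.
    """

    fish_id: str
    history: np.ndarray
    record: FishRecord | None = None

    def __post_init__(self):
        self.history = np.asarray(self.history, dtype=int)
        if self.history[0] != 1:
            raise ValueError("history[0] is the release occasion and must be 1")
        if not np.isin(self.history, (0, 1)).all():
            raise ValueError("history entries must be 0/1")

    def as_string(self) -> str:
        return "".join(map(str, self.history.tolist()))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_FISH_COLS = [
    "fish_id", "population", "origin", "year", "fork_length_mm",
    "weight_g", "smolt_index", "release_date", "release_site",
]
_RECV_COLS = ["receiver_id", "line_id", "corridor_position_km", "occasion_index"]
_EVENT_COLS = ["fish_id", "receiver_id", "timestamp"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_fish(path) -> list[FishRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _FISH_COLS, path)
    dupes = df["fish_id"].astype(str)[df["fish_id"].astype(str).duplicated()]
    if len(dupes):
        raise IntegrityError(f"{path}: duplicate fish_id {sorted(set(dupes))}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                FishRecord(
                    fish_id=str(row["fish_id"]),
                    population=Population(row["population"]),
                    origin=Origin(row["origin"]),
                    year=int(row["year"]),
                    fork_length_mm=float(row["fork_length_mm"]),
                    weight_g=float(row["weight_g"]),
                    smolt_index=int(row["smolt_index"]),
                    release_date=float(row["release_date"]),
                    release_site=str(row["release_site"]),
                )
            )
        except (ValueError, KeyError) as exc:  # report 1-based data line
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def read_receivers(path) -> list[ReceiverLine]:
    df = pd.read_csv(path)
    _require_columns(df, _RECV_COLS, path)
    if df["receiver_id"].astype(str).duplicated().any():
        raise IntegrityError(f"{path}: duplicate receiver_id")
    lines = []
    for line_id, grp in df.groupby("line_id", sort=False):
        occ = grp["occasion_index"].dropna().unique()
        if len(occ) > 1:
            raise IntegrityError(f"{path}: line {line_id} has mixed occasion_index")
        occasion = int(occ[0]) if len(occ) else None
        receivers = tuple(
            (str(r["receiver_id"]), float(r["corridor_position_km"]))
            for _, r in grp.iterrows()
        )
        lines.append(ReceiverLine(str(line_id), receivers, occasion))
    positions = [(l.occasion_index, l.position_km) for l in lines if l.occasion_index]
    positions.sort()
    if any(b[1] <= a[1] for a, b in zip(positions, positions[1:])):
        raise IntegrityError(
            f"{path}: occasion lines must be strictly ordered along the corridor"
        )
    return lines


def read_events(path, lines: Iterable[ReceiverLine] | None = None) -> list[DetectionEvent]:
    df = pd.read_csv(path)
    _require_columns(df, _EVENT_COLS, path)
    events = [
        DetectionEvent(str(r["fish_id"]), str(r["receiver_id"]), float(r["timestamp"]))
        for _, r in df.iterrows()
    ]
    if lines is not None:
        known = {rid for line in lines for rid in line.receiver_ids()}
        unknown = sorted({e.receiver_id for e in events} - known)
        if unknown:
            raise ReferentialError(f"{path}: unknown receiver(s) {unknown}")
    return events


def read_tables(fish_path, receivers_path, events_path):
    """Read and cross-validate the three input tables."""
    fish = read_fish(fish_path)
    lines = read_receivers(receivers_path)
    events = read_events(events_path, lines=lines)
    return fish, lines, events


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fish(records: Iterable[FishRecord], path) -> None:
    df = pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in records],
            "population": [r.population.value for r in records],
            "origin": [r.origin.value for r in records],
            "year": [r.year for r in records],
            "fork_length_mm": [r.fork_length_mm for r in records],
            "weight_g": [r.weight_g for r in records],
            "smolt_index": [r.smolt_index for r in records],
            "release_date": [r.release_date for r in records],
            "release_site": [r.release_site for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_receivers(lines: Iterable[ReceiverLine], path) -> None:
    rows = []
    for line in lines:
        for rid, pos in line.receivers:
            rows.append(
                {
                    "receiver_id": rid,
                    "line_id": line.line_id,
                    "corridor_position_km": pos,
                    "occasion_index": line.occasion_index,
                }
            )
    pd.DataFrame(rows, columns=_RECV_COLS).to_csv(path, index=False)


def write_events(events: Iterable[DetectionEvent], path) -> None:
    df = pd.DataFrame(
        {
            "fish_id": [e.fish_id for e in events],
            "receiver_id": [e.receiver_id for e in events],
            "timestamp": [e.timestamp for e in events],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MARK .inp export
# ---------------------------------------------------------------------------

def write_inp(
    histories: Sequence[EncounterHistory],
    grouping: str | None = None,
    group_order: Sequence[str] | None = None,
) -> str:
    """Render encounter histories in the MARK ``.inp`` dialect.

    One line per unique (history, group) combination: the history string,
    one frequency column per group, and a terminating semicolon.
    ``grouping`` names a FishRecord attribute (e.g. ``"origin"``); ``None``
    puts every fish in a single group. Group column order follows
    ``group_order`` when given, else first appearance.
    """
    if not histories:
        return ""
    lengths = {len(h.history) for h in histories}
    if len(lengths) != 1:
        raise ValueError(f"ragged histories: lengths {sorted(lengths)}")

    def group_of(h: EncounterHistory) -> str:
        if grouping is None:
            return "all"
        if h.record is None:
            raise ValueError(f"{h.fish_id}: grouping requires attached FishRecord")
        value = getattr(h.record, grouping)
        return value.value if isinstance(value, enum.Enum) else str(value)

    groups: list[str] = list(group_order) if group_order is not None else []
    counts: dict[str, dict[str, int]] = {}
    for h in histories:
        g = group_of(h)
        if g not in groups:
            groups.append(g)
        row = counts.setdefault(h.as_string(), {})
        row[g] = row.get(g, 0) + 1
    out = []
    for hist in sorted(counts):
        freqs = " ".join(str(counts[hist].get(g, 0)) for g in groups)
        out.append(f"{hist} {freqs} ;")
    return "\n".join(out) + "\n"
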