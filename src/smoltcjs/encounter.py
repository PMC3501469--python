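"""Collapse raw detections into CJS encounter histories and compute
migration-behavior metrics (travel rates, migration range, receiver
density tables)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    DetectionEvent,
    EncounterHistory,
    FishRecord,
    IntegrityError,
    ReceiverLine,
    ReferentialError,
)

__all__ = [
    "build_encounter_histories",
    "first_detection_times",
    "travel_rate",
    "migration_range",
    "density_table",
    "behavior_metrics",
    "BehaviorMetrics",
]


def _receiver_maps(lines: Iterable[ReceiverLine]):
    """receiver_id -> (line_id, occasion_index, position_km)."""
    out = {}
    for line in lines:
        for rid, pos in line.receivers:
            out[rid] = (line.line_id, line.occasion_index, pos)
    return out


def build_encounter_histories(
    events: Sequence[DetectionEvent],
    fish: Sequence[FishRecord],
    lines: Sequence[ReceiverLine],
) -> list[EncounterHistory]:
    """One history per released fish: ``history[k] = 1`` iff the fish has at
    least one event on any receiver of the occasion-``k`` line(s).

    Behavioral (non-occasion) receivers are ignored; duplicate events and
    event order are irrelevant. Events timestamped before the fish's
    release raise IntegrityError; events for unknown receivers raise
    ReferentialError.
    """
    rmap = _receiver_maps(lines)
    occasions = sorted({l.occasion_index for l in lines if l.occasion_index is not None})
    if occasions != list(range(1, len(occasions) + 1)):
        raise ValueError(f"occasion indices must be 1..T, got {occasions}")
    T = len(occasions)
    release = {f.fish_id: f.release_date for f in fish}
    hist = {f.fish_id: np.zeros(T + 1, dtype=int) for f in fish}
    for f in fish:
        hist[f.fish_id][0] = 1
    for ev in events:
        if ev.receiver_id not in rmap:
            raise ReferentialError(f"event references unknown receiver {ev.receiver_id!r}")
        if ev.fish_id not in hist:
            continue  # untracked fish (e.g. filtered cohort subset)
        if ev.timestamp < release[ev.fish_id] - 1e-9:
            raise IntegrityError(
                f"fish {ev.fish_id}: event at t={ev.timestamp} precedes release"
            )
        occ = rmap[ev.receiver_id][1]
        if occ is not None:
            hist[ev.fish_id][occ] = 1
    by_id = {f.fish_id: f for f in fish}
    return [EncounterHistory(f.fish_id, hist[f.fish_id], record=by_id[f.fish_id]) for f in fish]


def first_detection_times(
    events: Sequence[DetectionEvent], lines: Sequence[ReceiverLine]
) -> pd.DataFrame:
    """Tidy table of each fish's first detection time per line."""
    rmap = _receiver_maps(lines)
    rows = [
        {"fish_id": e.fish_id, "line_id": rmap[e.receiver_id][0], "timestamp": e.timestamp}
        for e in events
        if e.receiver_id in rmap
    ]
    if not rows:
        return pd.DataFrame(columns=["fish_id", "line_id", "timestamp"])
    df = pd.DataFrame(rows)
    return df.groupby(["fish_id", "line_id"], as_index=False)["timestamp"].min()


def travel_rate(
    events: Sequence[DetectionEvent],
    fish: FishRecord,
    from_point: str,
    to_point: str,
    distance_km: float,
    lines: Sequence[ReceiverLine],
) -> float | None:
    """km/day from ``from_point`` to ``to_point`` using first detections.

    ``from_point`` may be ``"release"``, in which case the fish's release
    timestamp is the reference. Returns None when a bounding detection is
    missing (undefined, not zero).
    """
    firsts = first_detection_times([e for e in events if e.fish_id == fish.fish_id], lines)
    times = dict(zip(firsts["line_id"], firsts["timestamp"]))
    t0 = fish.release_date if from_point == "release" else times.get(from_point)
    t1 = times.get(to_point)
    if t0 is None or t1 is None:
        return None
    dt = t1 - t0
    if dt <= 0:
        return None
    return distance_km / dt


def migration_range(
    events: Sequence[DetectionEvent],
    corridor_positions: Mapping[str, float],
    estuary_km: float = 0.0,
) -> float | None:
    """Distance from the estuary to the northernmost detection.

    ``corridor_positions`` maps receiver_id -> along-corridor km. Returns
    None for a never-detected fish; 0 when only estuary detections exist.
    """
    positions = [corridor_positions[e.receiver_id] for e in events]
    if not positions:
        return None
    return max(0.0, max(positions) - estuary_km)


@dataclass(frozen=True)
class BehaviorMetrics:
    fish_id: str
    freshwater_travel_rate_kmday: float | None
    marine_travel_rate_kmday: float | None
    migration_range_km: float | None
    northernmost_receiver: str | None


def behavior_metrics(
    events: Sequence[DetectionEvent],
    fish: Sequence[FishRecord],
    lines: Sequence[ReceiverLine],
    rm_line_of: Mapping,
    freshwater_km: Mapping,
    rm_to_hcb_km: Mapping,
    estuary_km: float = 0.0,
) -> pd.DataFrame:
    """Per-fish behavior metric table.

    Freshwater rate: release -> river-mouth line over ``freshwater_km``;
    marine rate: river mouth -> HCB over ``rm_to_hcb_km`` (both mappings
    keyed by population). Range uses all detections on the corridor axis.
    """
    rmap = _receiver_maps(lines)
    by_fish: dict[str, list[DetectionEvent]] = {f.fish_id: [] for f in fish}
    for e in events:
        if e.fish_id in by_fish:
            by_fish[e.fish_id].append(e)
    positions = {rid: pos for rid, (_, _, pos) in rmap.items()}
    rows = []
    for f in fish:
        evs = by_fish[f.fish_id]
        rm_line = rm_line_of[f.population]
        fw = travel_rate(evs, f, "release", rm_line, freshwater_km[f.population], lines)
        mar = travel_rate(evs, f, rm_line, "HCB", rm_to_hcb_km[f.population], lines)
        rng_km = migration_range(evs, positions, estuary_km)
        northernmost = None
        if evs:
            northernmost = max(evs, key=lambda e: positions[e.receiver_id]).receiver_id
        rows.append(
            {
                "fish_id": f.fish_id,
                "population": f.population.value,
                "origin": f.origin.value,
                "year": f.year,
                "freshwater_travel_rate_kmday": fw,
                "marine_travel_rate_kmday": mar,
                "migration_range_km": rng_km,
                "northernmost_receiver": northernmost,
            }
        )
    return pd.DataFrame(rows)


def density_table(
    events: Sequence[DetectionEvent],
    fish_subset: Sequence[FishRecord],
    region_lines: Sequence[ReceiverLine],
) -> pd.DataFrame:
    """Distinct-fish detection counts per receiver in a named region.

    Proportions are relative to the number of subset fish with at least one
    detection on any region receiver. Empty subset -> empty table.
    """
    ids = {f.fish_id for f in fish_subset}
    region = {rid for line in region_lines for rid in line.receiver_ids()}
    if not ids:
        return pd.DataFrame(columns=["receiver_id", "n_detected_fish", "proportion_of_detected"])
    hits: dict[str, set] = {rid: set() for rid in region}
    detected: set = set()
    for e in events:
        if e.fish_id in ids and e.receiver_id in region:
            hits[e.receiver_id].add(e.fish_id)
            detected.add(e.fish_id)
    denom = max(len(detected), 1)
    rows = [
        {
            "receiver_id": rid,
            "n_detected_fish": len(fish_ids),
            "proportion_of_detected": len(fish_ids) / denom,
        }
        for rid, fish_ids in sorted(hits.items())
    ]
    return pd.DataFrame(rows)
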