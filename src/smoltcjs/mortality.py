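"""Cumulative marine survival, distance-scaled instantaneous mortality, and
the fixed-terminal-p sensitivity range.

Mortality is scaled per kilometre of migration corridor rather than per
unit time: with per-segment survival ``phi`` over distance ``d`` km, the
exponential-decay rate is ``M = -ln(phi) / d``, so ``exp(-M d)`` recovers
``phi`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import SegmentGeometry

__all__ = [
    "MortalityRate",
    "cumulative_survival",
    "instantaneous_mortality",
    "sensitivity_range",
    "mortality_rate_table",
]


@dataclass(frozen=True)
class MortalityRate:
    """Distance-scaled instantaneous mortality for one segment."""

    phi: float
    distance_km: float
    M_per_km: float
    infinite: bool = False
    population: str | None = None
    segment: str | None = None
    year: int | None = None


def cumulative_survival(segment_phis: Sequence[float], cov: np.ndarray | None = None):
    """Product of segment survival probabilities.

    Empty input returns 1.0 by convention. With ``cov`` (covariance of the
    per-segment estimates), also returns a delta-method SE computed on the
    log scale: ``var(log prod) = sum_ij cov_ij / (phi_i phi_j)``.
    """
    phis = np.asarray(list(segment_phis), dtype=float)
    if phis.size == 0:
        return 1.0 if cov is None else (1.0, 0.0)
    if np.any(phis <= 0) or np.any(phis > 1):
        raise ValueError("segment survivals must be in (0, 1]")
    prod = float(np.prod(phis))
    if cov is None:
        return prod
    cov = np.asarray(cov, dtype=float)
    grad = 1.0 / phis
    var_log = float(grad @ cov @ grad)
    se = prod * math.sqrt(max(var_log, 0.0))
    return prod, se


def instantaneous_mortality(phi: float, distance_km: float, **labels) -> MortalityRate:
    """``M = -ln(phi) / d`` per km; ``phi = 0`` flags an infinite rate."""
    if distance_km <= 0:
        raise ValueError("distance must be positive")
    if phi > 1 or phi < 0:
        raise ValueError(f"survival probability {phi} outside [0, 1]")
    if phi == 0:
        return MortalityRate(phi, distance_km, math.inf, infinite=True, **labels)
    return MortalityRate(phi, distance_km, -math.log(phi) / distance_km, **labels)


def sensitivity_range(
    fit_builder: Callable[[float], Mapping[str, Sequence[float]]],
    p_values: Sequence[float],
) -> pd.DataFrame:
    """Cumulative-survival range over a set of fixed terminal-p values.

    ``fit_builder(p_fixed)`` refits the model with the terminal detection
    probability fixed at ``p_fixed`` and returns a mapping of group label
    -> marine segment survivals. Failed refits are flagged per value and
    excluded from the range. Returns one row per group with the
    cumulative survival under each p and the min/max envelope.
    """
    results: dict[float, Mapping] = {}
    failures: dict[float, str] = {}
    for p_fixed in p_values:
        try:
            results[p_fixed] = fit_builder(p_fixed)
        except Exception as exc:  # propagate as flag, not crash
            failures[p_fixed] = str(exc)
    if not results:
        raise RuntimeError(f"all refits failed: {failures}")
    groups = list(next(iter(results.values())).keys())
    rows = []
    for g in groups:
        by_p = {p: cumulative_survival(res[g]) for p, res in results.items()}
        rows.append(
            {
                "group": g,
                **{f"survival_at_p={p}": s for p, s in by_p.items()},
                "min": min(by_p.values()),
                "max": max(by_p.values()),
                "failed_p_values": sorted(failures) or None,
            }
        )
    return pd.DataFrame(rows)


def mortality_rate_table(
    phis_by_group: Mapping,
    geometry_by_population: Mapping[object, SegmentGeometry],
    marine_only: bool = True,
) -> pd.DataFrame:
    """Per (population, year, segment) distance-scaled mortality rates.

    ``phis_by_group`` maps ``(population, year)`` -> per-segment survival
    sequence aligned with the population's SegmentGeometry (freshwater
    segment first). The freshwater segment is dropped when ``marine_only``.
    """
    rows = []
    for (population, year), phis in phis_by_group.items():
        geom = geometry_by_population.get(population)
        if geom is None:
            raise KeyError(f"no geometry for population {population!r}")
        names = [f"{a}-{b}" for a, b, _ in geom.segments]
        dists = geom.distances_km
        if len(phis) != len(dists):
            raise ValueError(
                f"{population}/{year}: {len(phis)} survivals for {len(dists)} segments"
            )
        start = 1 if marine_only else 0
        for s in range(start, len(dists)):
            rate = instantaneous_mortality(float(phis[s]), float(dists[s]))
            rows.append(
                {
                    "population": getattr(population, "value", population),
                    "year": year,
                    "segment": names[s],
                    "phi": rate.phi,
                    "distance_km": rate.distance_km,
                    "M_per_km": rate.M_per_km,
                }
            )
    return pd.DataFrame(rows)
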