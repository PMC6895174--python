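"""Descriptive statistics for clonal single-cell culture assays.

Covers sphere-forming efficiency (SFE) from micro-raft clonal events,
efficiency fold ratios between sorted populations, organoid budding rates
across replicates, and lineage proportion tables from flow-cytometry
counts.  Percentages are rounded half-away-from-zero, matching how such
figures are conventionally printed (one decimal for SFE and fold ratios,
two for proportions).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "ClonalCounts",
    "SFE",
    "sfe",
    "sfe_ratio",
    "consistent_sphere_counts",
    "BuddingRate",
    "budding_rate",
    "ProportionTable",
    "proportions",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (printing convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClonalCounts:
    """Single-cell clonal events at t=0 and resulting spheres at day 8."""

    events: int
    spheres: int

    def __post_init__(self) -> None:
        if self.events < 0 or self.spheres < 0:
            raise ValidationError("ClonalCounts: counts must be >= 0")
        if self.spheres > self.events:
            raise ValidationError(
                f"ClonalCounts: spheres ({self.spheres}) cannot exceed events ({self.events})"
            )


@dataclass
class SFE:
    """Sphere-forming efficiency: printed percentage and exact proportion."""

    percent: float
    proportion: float


def sfe(counts: ClonalCounts) -> SFE:
    """Sphere-forming efficiency of clonal events.

    100 x spheres / events, rounded half-away-from-zero to one decimal; the
    unrounded proportion is returned alongside.
    """
    if counts.events == 0:
        raise ConfigurationError("sfe: events must be > 0")
    prop = counts.spheres / counts.events
    return SFE(percent=round_half_away(100.0 * prop, 1), proportion=prop)


def sfe_ratio(sfe_1: float, sfe_2: float) -> float:
    """Fold ratio of two SFE percentages, rounded to one decimal."""
    if sfe_2 == 0:
        raise ConfigurationError("sfe_ratio: denominator SFE must be > 0")
    return round_half_away(sfe_1 / sfe_2, 1)


def consistent_sphere_counts(events: int, printed_percent: float) -> list[int]:
    """All sphere counts in [0, events] whose SFE rounds to a printed value.

    Published efficiencies are often given only as rounded percentages; this
    brute-force scan recovers the integer sphere counts consistent with the
    printed figure (a single-element list means the count is unambiguous).
    """
    if events <= 0:
        raise ConfigurationError("consistent_sphere_counts: events must be > 0")
    return [
        s
        for s in range(events + 1)
        if round_half_away(100.0 * s / events, 1) == printed_percent
    ]


@dataclass
class BuddingRate:
    """Budding-rate summary across replicates (sample SD, n-1)."""

    mean: float
    sd: float
    rates: list[float]


def budding_rate(n_budding, n_total) -> BuddingRate:
    """Fraction of organoids with budding structures.

    Accepts scalars (one replicate) or equal-length sequences of
    per-replicate counts; returns the per-replicate rates with their mean
    and sample standard deviation (0 for a single replicate).
    """
    nb = np.atleast_1d(np.asarray(n_budding, dtype=np.int64))
    nt = np.atleast_1d(np.asarray(n_total, dtype=np.int64))
    if nb.shape != nt.shape:
        raise ConfigurationError("budding_rate: replicate vectors must align")
    if (nt <= 0).any():
        raise ConfigurationError("budding_rate: totals must be > 0")
    if (nb < 0).any() or (nb > nt).any():
        raise ConfigurationError("budding_rate: need 0 <= n_budding <= n_total")
    rates = nb / nt
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return BuddingRate(mean=float(rates.mean()), sd=sd, rates=rates.tolist())


@dataclass
class ProportionTable:
    """Category counts with derived percentages (two decimals)."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float]


def proportions(counts: Mapping[str, int]) -> ProportionTable:
    """Percentage breakdown of category counts.

    Percentages are rounded half-away-from-zero to two decimals and checked
    to sum to 100 within 0.05 (rounding slack).
    """
    clean = {str(k): int(v) for k, v in counts.items()}
    if any(v < 0 for v in clean.values()):
        raise ValidationError("proportions: counts must be >= 0")
    total = sum(clean.values())
    if total == 0:
        raise ConfigurationError("proportions: all counts are zero")
    pct = {k: round_half_away(100.0 * v / total, 2) for k, v in clean.items()}
    if abs(sum(pct.values()) - 100.0) > 0.05:
        raise ValidationError("proportions: rounded percentages drift beyond 0.05 of 100")
    return ProportionTable(counts=clean, total=total, percentages=pct)
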