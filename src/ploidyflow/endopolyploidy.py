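"""Endopolyploidy profiling: C-level classification and the cycle value.

Endoreduplicating tissues hold nuclei at a doubling series of DNA levels
(2C, 4C, 8C, ... 64C).  The degree of endopolyploidy is summarised by the
cycle value, the mean number of endocycles a nucleus has passed::

    cycle value = (0*n2C + 1*n4C + 2*n8C + ...) / (n2C + n4C + n8C + ...)

A tissue with cycle value > 0.1 is called polysomatic.  The number of
endocycles of a profile is the number of occupied levels above 4C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._utils import round_half_up
from .simulate import C_LEVELS, EventSample

#: endocycle index per level: 2C nuclei have undergone none, 64C five
LEVEL_WEIGHTS: Mapping[str, int] = {lv: i for i, lv in enumerate(C_LEVELS)}

#: cycle values above this are classed polysomatic (strict inequality)
POLYSOMATY_THRESHOLD = 0.1

#: default half-width, in log2 units, of the assignment window per level
DEFAULT_TOLERANCE = 0.25


@dataclass
class CLevelProfile:
    """Per-level nuclei percentages of one tissue, with derived indices."""

    percent_per_level: dict[str, float]
    counts_per_level: dict[str, int] | None = None
    taxon: str = ""
    accession: str = ""
    n_endocycles: int = field(init=False)
    cycle_value_raw: float = field(init=False)
    polysomatic: bool = field(init=False)

    def __post_init__(self) -> None:
        pct = {
            lv: float(self.percent_per_level.get(lv, 0.0)) for lv in C_LEVELS
        }
        if any(v < 0 for v in pct.values()):
            raise ValueError("percentages must be non-negative")
        total = math.fsum(pct.values())
        if abs(total - 100.0) > 0.05:
            raise ValueError(
                f"percentages must sum to 100 within 0.05 (got {total:.4f})"
            )
        self.percent_per_level = pct
        self.n_endocycles = count_endocycles(pct)
        self.cycle_value_raw = cycle_value(pct)
        self.polysomatic = is_polysomatic(self.cycle_value_raw)

    @property
    def cycle_value(self) -> float:
        """The reported (3-decimal) cycle value."""
        return round_half_up(self.cycle_value_raw, 3)


@dataclass
class PopulationSummary:
    """Aggregate of individual profiles from one population."""

    individual_cycle_values: list[float]
    mean_cycle_value: float
    endocycle_counts: list[int]
    endocycles_label: str
    polysomatic: bool


def classify_c_levels(
    events: EventSample,
    base_2c_position: float,
    tolerance_fraction: float = DEFAULT_TOLERANCE,
) -> dict[str, int]:
    """Assign each event to the nearest C-level of the doubling series.

    Assignment is in log2 space: an event at intensity I has offset
    ``log2(I / base)``; it joins level k (0 for 2C .. 5 for 64C) when the
    offset is within ``tolerance_fraction`` of k.  Everything else —
    debris, inter-peak events, zero intensities — is counted under the
    ``"unclassified"`` key and excluded from the cycle value.
    """
    if base_2c_position <= 0:
        raise ValueError("base_2c_position must be positive")
    if not 0 < tolerance_fraction < 0.5:
        raise ValueError("tolerance_fraction must lie in (0, 0.5)")
    values = events.intensities
    counts = {lv: 0 for lv in C_LEVELS}
    unclassified = 0
    positive = values > 0
    offsets = np.full(len(values), np.nan)
    offsets[positive] = np.log2(values[positive] / base_2c_position)
    nearest = np.rint(offsets)
    ok = (
        positive
        & (np.abs(offsets - nearest) <= tolerance_fraction)
        & (nearest >= 0)
        & (nearest < len(C_LEVELS))
    )
    for k, lv in enumerate(C_LEVELS):
        counts[lv] = int(np.sum(ok & (nearest == k)))
    unclassified = int(len(values) - sum(counts.values()))
    counts["unclassified"] = unclassified
    return counts


def cycle_value(counts_or_percent: Mapping[str, float]) -> float:
    """Mean endocycles per nucleus (weights 0..5 over 2C..64C).

    Accepts raw counts or percentages; the denominator is the actual sum
    of the supplied values, so any positive rescaling leaves the result
    unchanged.  Keys outside the 2C..64C series are ignored.
    """
    num = 0.0
    den = 0.0
    for lv, w in LEVEL_WEIGHTS.items():
        v = float(counts_or_percent.get(lv, 0.0) or 0.0)
        if v < 0:
            raise ValueError("nuclei counts must be non-negative")
        num += w * v
        den += v
    if den == 0:
        raise ValueError("cycle value undefined for an all-zero profile")
    return num / den


def count_endocycles(
    percent_per_level: Mapping[str, float],
    min_fraction_percent: float = 0.0,
) -> int:
    """Number of occupied levels strictly above 4C (8C, 16C, 32C, 64C).

    A level counts as occupied when its percentage exceeds
    ``min_fraction_percent``; the default 0 counts any gated presence.
    """
    return sum(
        1
        for lv in C_LEVELS[2:]
        if float(percent_per_level.get(lv, 0.0) or 0.0) > min_fraction_percent
    )


def is_polysomatic(value: float) -> bool:
    """True iff the cycle value strictly exceeds 0.1."""
    if value < 0:
        raise ValueError("cycle value must be >= 0")
    return value > POLYSOMATY_THRESHOLD


def profile_from_events(
    events: EventSample,
    base_2c_position: float,
    tolerance_fraction: float = DEFAULT_TOLERANCE,
    taxon: str = "",
    accession: str = "",
) -> CLevelProfile:
    """Classify events and package the result as a percentage profile."""
    counts = classify_c_levels(events, base_2c_position, tolerance_fraction)
    level_counts = {lv: counts[lv] for lv in C_LEVELS}
    total = sum(level_counts.values())
    if total == 0:
        raise ValueError("no events classified into any C-level")
    pct = {lv: 100.0 * c / total for lv, c in level_counts.items()}
    return CLevelProfile(
        percent_per_level=pct,
        counts_per_level=level_counts,
        taxon=taxon,
        accession=accession,
    )


def aggregate_individuals(
    profiles: Sequence[CLevelProfile],
) -> PopulationSummary:
    """Summarise a population from its per-individual profiles.

    Reports each individual's 3-decimal cycle value, their unweighted mean
    (of the reported values, rounded half-up), and the distinct endocycle
    counts as a label such as ``"3 or 4"``.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    values = [p.cycle_value for p in profiles]
    mean = round_half_up(math.fsum(values) / len(values), 3)
    counts = sorted({p.n_endocycles for p in profiles})
    label = " or ".join(str(c) for c in counts)
    return PopulationSummary(
        individual_cycle_values=values,
        mean_cycle_value=mean,
        endocycle_counts=counts,
        endocycles_label=label,
        polysomatic=is_polysomatic(mean),
    )
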