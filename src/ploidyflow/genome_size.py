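"""Nuclear 2C DNA content and monoploid (1Cx) genome size.

The 2C content of a sample is estimated against a co-acquired internal
standard of known genome size::

    A = (B / C) x D

with A the sample 2C content (pg), B the sample G0/G1 peak mean, C the
standard G0/G1 peak mean and D the standard's 2C content (pg).  Replicates
are averaged to mean +/- SE; the monoploid genome size is 1Cx = 2C divided
by the ploidy multiplier, converted to Mbp at 1 pg = 978 Mbp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from ._utils import PG_TO_MBP, round_half_up


@dataclass(frozen=True)
class InternalStandard:
    """A reference species of known 2C DNA content, in picograms."""

    name: str
    two_c_pg: float

    def __post_init__(self) -> None:
        if not self.two_c_pg > 0:
            raise ValueError("standard two_c_pg must be positive")


#: built-in calibration standards routinely used for plant genome sizing
STANDARDS: dict[str, InternalStandard] = {
    "tomato": InternalStandard(
        "Solanum lycopersicum cv. Stupicke polni rane", 1.96
    ),
    "maize": InternalStandard("Zea mays cv. CE-777", 5.43),
    "pea": InternalStandard("Pisum sativum cv. Ctirad", 9.09),
}


@dataclass(frozen=True)
class PloidyRecord:
    """One population's karyology: 2n = multiplier * x + extra."""

    species: str
    accession: str
    two_n: int
    x: int
    ploidy_multiplier: int
    aneuploid_extra: int = 0

    def __post_init__(self) -> None:
        if self.x < 1 or self.ploidy_multiplier < 1:
            raise ValueError("x and ploidy_multiplier must be >= 1")
        if self.aneuploid_extra < 0:
            raise ValueError("aneuploid_extra must be >= 0")
        expected = self.ploidy_multiplier * self.x + self.aneuploid_extra
        if self.two_n != expected:
            raise ValueError(
                f"2n = {self.two_n} != {self.ploidy_multiplier}*{self.x}"
                f" + {self.aneuploid_extra}"
            )

    @property
    def ploidy_expression(self) -> str:
        """Human-readable decomposition, e.g. ``6x + 10``."""
        if self.aneuploid_extra:
            return f"{self.ploidy_multiplier}x + {self.aneuploid_extra}"
        return f"{self.ploidy_multiplier}x"


@dataclass
class GenomeSizeEstimate:
    """Replicate-averaged 2C content with the derived 1Cx values."""

    two_c_pg_mean: float
    two_c_pg_se: float
    replicate_values: list[float] = field(default_factory=list)
    one_cx_pg: float | None = None
    one_cx_mbp: int | None = None
    low_confidence: bool = False


def estimate_two_c(
    sample_peak_mean: float,
    standard_peak_mean: float,
    standard: InternalStandard,
) -> float:
    """Sample 2C DNA content in pg from the two G0/G1 peak means.

    Returns ``(B / C) * D`` exactly; invariant under any common rescaling
    of the two peak means (so the gain setting cancels).
    """
    if sample_peak_mean <= 0:
        raise ValueError("sample peak mean must be positive")
    if standard_peak_mean <= 0:
        raise ValueError("standard peak mean must be positive")
    return sample_peak_mean / standard_peak_mean * standard.two_c_pg


def summarize_replicates(values: Sequence[float]) -> GenomeSizeEstimate:
    """Mean and standard error over replicate 2C estimates.

    SE is SD(ddof=1)/sqrt(n); a single replicate reports SE = 0.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("at least one replicate value is required")
    n = len(vals)
    mean = math.fsum(vals) / n
    if n == 1:
        se = 0.0
    else:
        var = math.fsum((v - mean) ** 2 for v in vals) / (n - 1)
        se = math.sqrt(var / n)
    return GenomeSizeEstimate(
        two_c_pg_mean=mean, two_c_pg_se=se, replicate_values=vals
    )


def derive_one_cx(
    two_c_pg: float, record: PloidyRecord | int
) -> tuple[float, int]:
    """Monoploid genome size in pg and Mbp.

    1Cx = 2C / ploidy multiplier; Mbp = round(1Cx * 978), half-up.  For
    aneuploid polyploids the divisor is the integer multiplier alone (the
    6 of ``6x + 10``); extra chromosomes do not enter.
    """
    m = record if isinstance(record, int) else record.ploidy_multiplier
    if m < 1:
        raise ValueError("ploidy multiplier must be >= 1")
    one_cx_pg = two_c_pg / m
    one_cx_mbp = int(round_half_up(one_cx_pg * PG_TO_MBP))
    return one_cx_pg, one_cx_mbp


def decompose_ploidy(
    two_n: int, x: int, species: str = "", accession: str = ""
) -> PloidyRecord:
    """Decompose a somatic count into ``m*x + extra`` with 0 <= extra < x.

    The canonical multiplier is floor-based; when the remainder reaches
    x/2 an alternative ``(m+1)x - deficit`` reading exists for reports, but
    the returned record always uses the floor decomposition.
    """
    if x < 1 or two_n < x:
        raise ValueError("need two_n >= x >= 1")
    multiplier = two_n // x
    extra = two_n - multiplier * x
    return PloidyRecord(
        species=species,
        accession=accession,
        two_n=two_n,
        x=x,
        ploidy_multiplier=multiplier,
        aneuploid_extra=extra,
    )


def complete_estimate(
    estimate: GenomeSizeEstimate, record: PloidyRecord | int
) -> GenomeSizeEstimate:
    """Fill in the 1Cx fields of a replicate summary."""
    pg, mbp = derive_one_cx(estimate.two_c_pg_mean, record)
    estimate.one_cx_pg = pg
    estimate.one_cx_mbp = mbp
    return estimate
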