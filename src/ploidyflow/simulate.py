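"""Synthetic flow-cytometry acquisitions of plant nuclei.

Real acquisitions of propidium-iodide stained nuclei produce, per nucleus,
one fluorescence value proportional to its DNA content.  A leaf parenchyma
sample therefore shows a ladder of Gaussian peaks at positions proportional
to the doubling series 2C, 4C, 8C, ... (endopolyploid nuclei), possibly
together with the G1 (and a small G2) peak of a co-chopped internal
reference species of known genome size, plus low-channel debris from
chopped cytoplasm and broken nuclei.

This module generates per-nucleus event streams with exactly that
statistical structure and known ground truth (each event carries its origin
label), so gating, genome-size estimation, and endopolyploidy profiling can
be validated end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

#: the DNA-content doubling series resolved by the analysis
C_LEVELS: tuple[str, ...] = ("2C", "4C", "8C", "16C", "32C", "64C")

#: relative DNA content of each level (2C == 1)
C_LEVEL_MULTIPLES: Mapping[str, int] = {
    level: 2**i for i, level in enumerate(C_LEVELS)
}

#: arbitrary-unit fluorescence of the sample 2C peak before gain rescaling.
#: Any positive anchor is equivalent; downstream quantities are ratios.
DEFAULT_ANCHOR = 1000.0

#: fraction of standard events placed in a G2 peak at twice the G1 mean
DEFAULT_STANDARD_G2_FRACTION = 0.08

#: share of a mixed acquisition's events that come from the standard
DEFAULT_STANDARD_SHARE = 0.30


class FractionError(ValueError):
    """C-level fractions are negative or do not sum to one."""


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground truth for one simulated species.

    Parameters
    ----------
    name :
        Taxon label carried through to reports.
    two_c_pg :
        2C nuclear DNA content in picograms; must be positive.
    c_level_fractions :
        Proportion of nuclei at each level of ``C_LEVELS``.  Missing levels
        mean zero.  Must be non-negative and sum to 1 within 1e-9; invalid
        fractions raise :class:`FractionError` rather than being
        renormalised silently.
    """

    name: str
    two_c_pg: float
    c_level_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"2C": 1.0}
    )

    def __post_init__(self) -> None:
        if not self.two_c_pg > 0:
            raise ValueError(f"two_c_pg must be > 0, got {self.two_c_pg}")
        unknown = set(self.c_level_fractions) - set(C_LEVELS)
        if unknown:
            raise FractionError(f"unknown C-levels: {sorted(unknown)}")
        fracs = [self.c_level_fractions.get(lv, 0.0) for lv in C_LEVELS]
        if any(f < 0 for f in fracs):
            raise FractionError("C-level fractions must be non-negative")
        total = math.fsum(fracs)
        if abs(total - 1.0) > 1e-9:
            raise FractionError(
                f"C-level fractions must sum to 1 (got {total!r})"
            )

    def fractions_array(self) -> np.ndarray:
        return np.array(
            [self.c_level_fractions.get(lv, 0.0) for lv in C_LEVELS]
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Settings of one simulated cytometer run.

    CV defaults sit mid-range of routine acquisitions of this kind
    (samples 3.83-4.98%, internal standards 2.80-3.72%).
    """

    n_events: int = 10_000
    cv_sample_percent: float = 4.4
    cv_standard_percent: float = 3.3
    debris_fraction: float = 0.05
    scale: str = "linear"
    n_channels: int = 250
    target_channel: int = 50
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris_fraction must be in [0, 1)")
        for cv in (self.cv_sample_percent, self.cv_standard_percent):
            if not 0 < cv < 20:
                raise ValueError(f"CV% must lie in (0, 20), got {cv}")
        if self.scale not in ("linear", "logarithmic"):
            raise ValueError("scale must be 'linear' or 'logarithmic'")
        if not 0 <= self.target_channel < self.n_channels:
            raise ValueError("target_channel must be < n_channels")


@dataclass
class EventSample:
    """A per-nucleus fluorescence event list, real or simulated.

    ``true_label`` is only present for simulated data and tags each event
    with its origin (a C-level, ``standard-G1``/``standard-G2`` or
    ``debris``).
    """

    intensities: np.ndarray
    true_label: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be one-dimensional")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.true_label is not None:
            self.true_label = np.asarray(self.true_label, dtype=object)
            if len(self.true_label) != len(self.intensities):
                raise ValueError("label/intensity length mismatch")

    def __len__(self) -> int:
        return len(self.intensities)

    def scaled(self, factor: float) -> "EventSample":
        """Return a copy with all intensities multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        out = EventSample(
            self.intensities * factor,
            None if self.true_label is None else self.true_label.copy(),
            dict(self.metadata),
        )
        return out


def _truncated_exponential(
    rng: np.random.Generator, n: int, scale: float, upper: float
) -> np.ndarray:
    # inverse-CDF sampling of Exp(scale) truncated to [0, upper)
    u = rng.random(n)
    cdf_upper = 1.0 - math.exp(-upper / scale)
    return -scale * np.log1p(-u * cdf_upper)


def _gaussian_peaks(
    rng: np.random.Generator,
    means: Sequence[float],
    counts: Sequence[int],
    cv_percent: float,
) -> tuple[np.ndarray, list[int]]:
    parts = []
    for mean, count in zip(means, counts):
        if count == 0:
            continue
        sigma = mean * cv_percent / 100.0
        draw = rng.normal(mean, sigma, size=count)
        parts.append(np.clip(draw, 0.0, None))
    if not parts:
        return np.empty(0), []
    return np.concatenate(parts), [c for c in counts if c]


def simulate_nuclei_events(
    truth: SpeciesTruth,
    config: AcquisitionConfig,
    *,
    anchor: float = DEFAULT_ANCHOR,
) -> EventSample:
    """Simulate a single-species acquisition (no internal standard).

    Each non-debris event is drawn from a Gaussian whose mean is
    proportional to its C-level DNA content (level k*2C has k times the 2C
    mean) and whose SD is ``mean * cv_sample_percent / 100``; C-level
    membership is multinomial on ``truth.c_level_fractions``.  Debris is an
    exponential tail truncated at the 2C mean.  Fixing ``rng_seed`` makes
    the output bit-identical across calls.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_events
    n_debris = rng.binomial(n, config.debris_fraction)
    level_counts = rng.multinomial(n - n_debris, truth.fractions_array())

    means = [anchor * C_LEVEL_MULTIPLES[lv] for lv in C_LEVELS]
    values, _ = _gaussian_peaks(
        rng, means, level_counts, config.cv_sample_percent
    )
    labels: list[str] = []
    for lv, count in zip(C_LEVELS, level_counts):
        labels.extend([lv] * count)

    if n_debris:
        debris = _truncated_exponential(
            rng, n_debris, scale=anchor / 4.0, upper=anchor
        )
        values = np.concatenate([values, debris]) if len(values) else debris
        labels.extend(["debris"] * n_debris)

    order = rng.permutation(len(values))
    return EventSample(
        values[order],
        np.array(labels, dtype=object)[order],
        metadata={
            "species": truth.name,
            "two_c_pg": truth.two_c_pg,
            "anchor": anchor,
            "config": config,
        },
    )


def simulate_mixed_run(
    sample: SpeciesTruth,
    standard: SpeciesTruth,
    config: AcquisitionConfig,
    *,
    anchor: float = DEFAULT_ANCHOR,
    standard_share: float = DEFAULT_STANDARD_SHARE,
    standard_g2_fraction: float = DEFAULT_STANDARD_G2_FRACTION,
    min_separation_sigmas: float = 3.0,
) -> EventSample:
    """Simulate a co-acquisition of sample nuclei with an internal standard.

    The standard contributes a G1 peak (CV ``cv_standard_percent``) placed
    so the expected sample-2C : standard-G1 intensity ratio equals the
    ``two_c_pg`` ratio exactly, plus a small G2 peak at twice the G1 mean.
    If any sample peak sits closer to a standard peak than
    ``min_separation_sigmas`` combined SDs, the returned sample carries an
    ``overlap_warning`` flag in its metadata (the run is still produced).
    """
    if not 0 < standard_share < 1:
        raise ValueError("standard_share must lie in (0, 1)")
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_events
    n_standard = min(int(round(n * standard_share)), n - 1) if n > 1 else 0
    n_sample = n - n_standard

    sample_cfg = replace(
        config, n_events=n_sample, rng_seed=int(rng.integers(2**31))
    )
    sample_events = simulate_nuclei_events(sample, sample_cfg, anchor=anchor)

    std_g1_mean = anchor * standard.two_c_pg / sample.two_c_pg
    n_g2 = rng.binomial(n_standard, standard_g2_fraction)
    std_values, _ = _gaussian_peaks(
        rng,
        [std_g1_mean, 2.0 * std_g1_mean],
        [n_standard - n_g2, n_g2],
        config.cv_standard_percent,
    )
    std_labels = ["standard-G1"] * (n_standard - n_g2) + ["standard-G2"] * n_g2

    values = np.concatenate([sample_events.intensities, std_values])
    labels = np.concatenate(
        [sample_events.true_label, np.array(std_labels, dtype=object)]
    )
    order = rng.permutation(len(values))

    # resolvability check on expected peak positions
    overlap = False
    sample_means = [
        anchor * C_LEVEL_MULTIPLES[lv]
        for lv in C_LEVELS
        if sample.c_level_fractions.get(lv, 0.0) > 0
    ]
    std_means = [std_g1_mean] + ([2 * std_g1_mean] if n_g2 else [])
    for sm in sample_means:
        s_sd = sm * config.cv_sample_percent / 100.0
        for tm in std_means:
            t_sd = tm * config.cv_standard_percent / 100.0
            if abs(sm - tm) < min_separation_sigmas * (s_sd + t_sd):
                overlap = True

    return EventSample(
        values[order],
        labels[order],
        metadata={
            "species": sample.name,
            "standard": standard.name,
            "two_c_pg": sample.two_c_pg,
            "standard_two_c_pg": standard.two_c_pg,
            "anchor": anchor,
            "overlap_warning": overlap,
            "config": config,
        },
    )
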