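"""Histogram construction, gain emulation, peak detection and gating.

Bench practice on a cytometer is to turn the gain knob until the reference
G1 peak sits in a fixed channel of the linear scale (here channel 50 of
250), then read peak means and CVs off gated windows.  This module
reproduces that workflow on event lists: a pure rescaling stands in for the
gain, peaks are found on a smoothed histogram, and per-peak statistics are
computed from the raw gated events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .simulate import EventSample

#: acquisition quality rule: peak CV% must be strictly below this
DEFAULT_MAX_CV_PERCENT = 5.00

#: default gate half-width in units of the peak SD
DEFAULT_K_SIGMA = 2.5

#: moving-average window (channels) for peak detection; about 2% of the
#: scale, well below the FWHM of the narrowest realistic peak
DEFAULT_SMOOTH_WINDOW = 5


@dataclass
class Histogram:
    """Binned fluorescence, linear or logarithmic in intensity."""

    scale: str
    channel_edges: np.ndarray  # len n_channels + 1, intensity units
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.channel_edges = np.asarray(self.channel_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.channel_edges) <= 0):
            raise ValueError("channel edges must be strictly increasing")
        if len(self.counts) != len(self.channel_edges) - 1:
            raise ValueError("counts/edges length mismatch")

    @property
    def n_channels(self) -> int:
        return len(self.counts)

    def channel_centers(self) -> np.ndarray:
        """Bin centers in intensity units (geometric on the log scale)."""
        edges = self.channel_edges
        if self.scale == "logarithmic":
            return np.sqrt(edges[:-1] * edges[1:])
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class Peak:
    """One gated histogram peak."""

    mean_position: float
    cv_percent: float
    nuclei_count: int
    gate: tuple[float, float]  # [low, high) intensity window
    label: Optional[str] = None
    qc_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.nuclei_count < 1:
            raise ValueError("a peak must contain at least one event")
        if self.cv_percent < 0:
            raise ValueError("cv_percent must be >= 0")
        low, high = self.gate
        if not low < high:
            raise ValueError("gate low must be < high")


def autoscale_gain(
    events: EventSample,
    reference_peak_mean: float,
    target_channel: int = 50,
    n_channels: int = 250,
) -> EventSample:
    """Rescale intensities so the reference peak lands in ``target_channel``.

    After rescaling, one channel is one intensity unit and the full linear
    scale spans ``[0, n_channels)``; the reference mean maps to the center
    of the (0-indexed) target channel, i.e. ``target_channel + 0.5``.  A
    pure rescaling: every downstream intensity ratio is unchanged, and
    applying the operation again with the recomputed reference mean is the
    identity.
    """
    if reference_peak_mean <= 0:
        raise ValueError("reference_peak_mean must be positive")
    factor = (target_channel + 0.5) / reference_peak_mean
    out = events.scaled(factor)
    out.metadata["gain_factor"] = factor * events.metadata.get(
        "gain_factor", 1.0
    )
    out.metadata["n_channels"] = n_channels
    return out


def build_histogram(
    events: EventSample,
    scale: str = "linear",
    n_channels: int = 250,
    upper: Optional[float] = None,
    decades: float = 3.0,
) -> Histogram:
    """Bin events on a 250-channel linear or logarithmic scale.

    Linear binning is uniform over ``[0, upper]`` (default: the largest
    event).  Logarithmic binning is uniform in log10 over ``decades``
    decades below ``upper``, which keeps the doubling series of C-level
    peaks equidistant.  Bins are half-open ``[low, high)`` with the top bin
    closed; the counts sum to the number of in-range events.
    """
    values = events.intensities
    if len(values) == 0:
        raise ValueError("cannot histogram an empty event list")
    if scale == "linear":
        top = float(values.max()) if upper is None else float(upper)
        if top <= 0:
            raise ValueError("no positive events in range")
        edges = np.linspace(0.0, top, n_channels + 1)
    elif scale == "logarithmic":
        positive = values[values > 0]
        if len(positive) == 0:
            raise ValueError("no positive events for a log-scale histogram")
        top = float(positive.max()) if upper is None else float(upper)
        edges = np.logspace(
            np.log10(top) - decades, np.log10(top), n_channels + 1
        )
    else:
        raise ValueError("scale must be 'linear' or 'logarithmic'")
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(scale=scale, channel_edges=edges, counts=counts)


def detect_peaks(
    hist: Histogram,
    min_prominence_fraction: float = 0.05,
    min_separation_channels: int = 5,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[float]:
    """Locate candidate peak positions (intensity units) in a histogram.

    The count profile is smoothed with a centred moving average, then local
    maxima taller than ``min_prominence_fraction`` times the tallest peak
    and at least ``min_separation_channels`` apart are returned, ordered by
    position.  May return an empty list (e.g. a flat histogram).
    """
    counts = hist.counts.astype(float)
    if counts.sum() == 0:
        return []
    window = max(1, int(smooth_window))
    kernel = np.ones(window) / window
    # edge padding avoids spurious maxima from boundary taper
    pad = window // 2
    padded = np.pad(counts, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")
    smoothed = smoothed[pad : pad + len(counts)] if pad else smoothed
    top = smoothed.max()
    if top <= 0:
        return []
    idx, _ = find_peaks(
        smoothed,
        height=min_prominence_fraction * top,
        distance=max(1, int(min_separation_channels)),
    )
    centers = hist.channel_centers()
    return [float(centers[i]) for i in idx]


def gate_peak(
    events: EventSample,
    center: float,
    k_sigma: float = DEFAULT_K_SIGMA,
    cv_prior_percent: float = DEFAULT_MAX_CV_PERCENT,
    label: Optional[str] = None,
    bounds: Optional[tuple[float, float]] = None,
) -> Peak:
    """Gate the events around ``center`` and report mean, CV% and count.

    The initial window is ``center ± k_sigma * center * cv_prior/100``.  It
    is refined exactly once by recomputing the mean and SD from the gated
    events and re-gating at ``mean ± k_sigma * SD`` (a single refinement
    keeps the operation deterministic).  Statistics come from the raw gated
    events, not from channel counts.  ``bounds``, when given, clips the
    window — the counterpart of manually setting a gate at the valley
    between two adjacent peaks.
    """
    if center <= 0:
        raise ValueError("gate center must be positive")
    values = events.intensities

    def _clip(lo: float, hi: float) -> tuple[float, float]:
        if bounds is not None:
            lo = max(lo, bounds[0])
            hi = min(hi, bounds[1])
        return lo, hi

    half = k_sigma * center * cv_prior_percent / 100.0
    low, high = _clip(center - half, center + half)
    first = values[(values >= low) & (values < high)]
    if len(first) == 0:
        raise ValueError(f"empty gate around {center}")

    mean, sd = float(first.mean()), float(first.std(ddof=0))
    if sd > 0:
        low, high = _clip(mean - k_sigma * sd, mean + k_sigma * sd)
        gated = values[(values >= low) & (values < high)]
        if len(gated) == 0:
            gated = first
    else:
        gated = first
    mean, sd = float(gated.mean()), float(gated.std(ddof=0))
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    return Peak(
        mean_position=mean,
        cv_percent=cv,
        nuclei_count=int(len(gated)),
        gate=(float(low), float(high)),
        label=label,
    )


def qc_cv(peak: Peak, max_cv_percent: float = DEFAULT_MAX_CV_PERCENT) -> bool:
    """Apply the acquisition quality rule: pass iff CV% < threshold.

    The inequality is strict (a CV of exactly 5.00% fails).  Failing peaks
    are flagged on the ``qc_pass`` attribute, never dropped.
    """
    ok = peak.cv_percent < max_cv_percent
    peak.qc_pass = ok
    return ok
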