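"""Per-cell-scaled frequency distributions of event features.

Event counts are binned per (threshold level, feature bin), divided by the
number of cells in the field of view and rescaled to a common recording
duration (default 600 s, the nominal 10-min acquisition), then averaged
across the recordings of a group — the recording is the statistical unit.
Bins are log-spaced because the features are heavy-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import DEFAULT_LADDER, EventTable, ThresholdLadder

__all__ = [
    "FEATURES",
    "DEFAULT_BINS",
    "FeatureHistogram",
    "CumulativeCurve",
    "accumulate_histograms",
    "cumulative_distribution",
    "marker_positive_fraction",
]

log = logging.getLogger(__name__)

FEATURES = ("max_size", "duration", "distance", "max_slope")

#: Log-spaced default bin edges per feature (32 bins each):
#: max_size 1-1e4 um^2, duration 0.2-600 s, distance 0.1-100 um,
#: max_slope 1e-3-1e2 1/s.
DEFAULT_BINS = {
    "max_size": np.logspace(0, 4, 33),
    "duration": np.logspace(np.log10(0.2), np.log10(600.0), 33),
    "distance": np.logspace(-1, 2, 33),
    "max_slope": np.logspace(-3, 2, 33),
}


@dataclass
class FeatureHistogram:
    """Frequency (events per cell per recording) over (level, feature bin)."""

    feature: str
    bin_edges: np.ndarray
    levels: tuple[float, ...]
    freq: np.ndarray  # (n_levels, n_bins)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.freq.shape != (len(self.levels), len(self.bin_edges) - 1):
            raise ValueError("freq shape inconsistent with levels/bins")
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be nonnegative")


@dataclass
class CumulativeCurve:
    """Cumulative relative frequency of one feature at one threshold level."""

    feature: str
    level: float
    x: np.ndarray
    cdf: np.ndarray
    degenerate: bool = False


def _single_recording_hist(
    table: EventTable,
    feature: str,
    edges: np.ndarray,
    levels: tuple[float, ...],
    ref_duration: float,
) -> np.ndarray:
    scale = 1.0 / table.n_cells
    if ref_duration is not None and table.duration_recorded > 0:
        scale *= ref_duration / table.duration_recorded
    out = np.zeros((len(levels), len(edges) - 1))
    clamped = 0
    for i, level in enumerate(levels):
        vals = np.array([getattr(e, feature) for e in table.at_level(level)])
        if len(vals) == 0:
            continue
        clamped += int(((vals < edges[0]) | (vals > edges[-1])).sum())
        vals = np.clip(vals, edges[0], np.nextafter(edges[-1], 0))
        counts, _ = np.histogram(vals, bins=edges)
        out[i] = counts * scale
    if clamped:
        log.info("histogram: %d values clamped to edge bins (%s)", clamped, feature)
    return out


def accumulate_histograms(
    tables: list[EventTable],
    bins: dict[str, np.ndarray] | None = None,
    ladder: ThresholdLadder | None = None,
    ref_duration: float | None = 600.0,
) -> dict[str, FeatureHistogram]:
    """Group-level 2-D histograms, one per feature.

    Per recording: counts per (level, bin) / n_cells, rescaled to
    ``ref_duration`` seconds (pass ``None`` to skip duration rescaling);
    values outside the bin range are clamped to the edge bins with a logged
    count.  The group value is the unweighted mean across recordings.
    """
    if not tables:
        raise ValueError("need at least one event table")
    if bins is None:
        bins = DEFAULT_BINS
    levels = (ladder or ThresholdLadder(DEFAULT_LADDER)).levels
    out = {}
    for feature in FEATURES:
        edges = np.asarray(bins[feature], dtype=float)
        per_rec = np.stack(
            [_single_recording_hist(t, feature, edges, levels, ref_duration) for t in tables]
        )
        out[feature] = FeatureHistogram(
            feature=feature, bin_edges=edges, levels=levels, freq=per_rec.mean(axis=0)
        )
    return out


def cumulative_distribution(hist: FeatureHistogram, level: float) -> CumulativeCurve:
    """Normalized running sum over feature bins at one threshold level."""
    try:
        i = hist.levels.index(float(level))
    except ValueError:
        raise ValueError(f"level {level} not in ladder {hist.levels}") from None
    f = hist.freq[i]
    total = f.sum()
    if total <= 0:
        return CumulativeCurve(
            feature=hist.feature,
            level=level,
            x=hist.bin_edges[1:],
            cdf=np.zeros_like(f),
            degenerate=True,
        )
    return CumulativeCurve(
        feature=hist.feature,
        level=level,
        x=hist.bin_edges[1:],
        cdf=np.cumsum(f) / total,
    )


def marker_positive_fraction(n_positive: int, n_total: int) -> float:
    """Percentage of marker-positive cells, reported to two decimals.

    Used for culture-purity counts such as Iba1+ microglia among all
    counted cells.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    return round(100.0 * n_positive / n_total, 2)
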