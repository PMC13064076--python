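"""Ratiometric dF/F_R normalization of two-channel Ca2+ movies.

The activity signal is defined as

    dF/F_R = (F - F_R) / F_R,

where ``F`` is the Ca2+-sensitive (GCaMP6s) fluorescence and ``F_R`` the
scaled Ca2+-insensitive (tdTomato) reference recorded from a 1:1 fusion
construct.  F_R is obtained from the red-channel baseline F0(red) by a
single global scale factor chosen so that F_R estimates the green
fluorescence at *zero* Ca2+:

    scale_k = median_cells[ F0(green) / F0(red) ] / B(basal_ca),

with ``B`` the Hill brightness model (F0(green) reflects brightness at
resting, not zero, Ca2+; dividing by B(basal_ca) removes that bias).  The
same factor is reused across all recordings of a dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .hill import HillParams, brightness

__all__ = [
    "TwoChannelMovie",
    "MixingMatrix",
    "BaselineMap",
    "ReferenceMap",
    "DffMovie",
    "unmix",
    "estimate_f0",
    "compute_scale_factor",
    "make_reference",
    "background_sigma",
    "analysis_mask",
    "compute_dff",
]

log = logging.getLogger(__name__)


@dataclass
class TwoChannelMovie:
    """Registered green (GCaMP6s) / red (tdTomato) stacks with calibration.

    Stacks are (T, H, W) arrays in arbitrary fluorescence units;
    ``pixel_size`` is in micrometers and ``frame_interval`` in seconds.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red stacks must share shape")
        if self.green.ndim != 3:
            raise ValueError("stacks must be (T, H, W)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class MixingMatrix:
    """2x2 spectral mixing: detected = matrix @ [true_green, true_red].

    Must be invertible; each fluorophore should be detected mostly in its
    own channel (diagonal dominance), which is warned about but not fatal.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("mixing matrix must be 2x2")
        if np.any(m < 0):
            raise ValueError("mixing coefficients must be nonnegative")
        if abs(np.linalg.det(m)) < 1e-12:
            raise np.linalg.LinAlgError("mixing matrix is singular")
        object.__setattr__(self, "matrix", m)
        if m[0, 0] <= m[0, 1] or m[1, 1] <= m[1, 0]:
            log.warning("mixing matrix is not diagonally dominant")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class BaselineMap:
    """Per-pixel approximated minimal fluorescence F0 (brightness at rest)."""

    f0: np.ndarray
    window: int
    percentile: float


@dataclass
class ReferenceMap:
    """Scaled reference F_R = scale_k * F0(red), static per pixel."""

    fr: np.ndarray
    scale_k: float


@dataclass
class DffMovie:
    """Per-pixel dF/F_R time series with the valid-pixel mask and calibration."""

    dff: np.ndarray
    mask: np.ndarray
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


def unmix(movie: TwoChannelMovie, mixing: MixingMatrix) -> TwoChannelMovie:
    """Invert spectral crosstalk between the channels.

    Applies the inverse mixing matrix pixelwise; negative results (possible
    under noise) are clipped to zero and counted in the log.
    """
    inv = mixing.inverse
    g = movie.green.astype(np.float64, copy=False)
    r = movie.red.astype(np.float64, copy=False)
    pure_g = inv[0, 0] * g + inv[0, 1] * r
    pure_r = inv[1, 0] * g + inv[1, 1] * r
    n_neg = int((pure_g < 0).sum() + (pure_r < 0).sum())
    if n_neg:
        log.info("unmix: clipped %d negative values to 0", n_neg)
    return TwoChannelMovie(
        green=np.clip(pure_g, 0, None).astype(np.float32),
        red=np.clip(pure_r, 0, None).astype(np.float32),
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
    )


def estimate_f0(
    stack: np.ndarray,
    window: int = 100,
    percentile: float = 8.0,
    smooth: int = 5,
    hop: int = 1,
) -> BaselineMap:
    """Per-pixel minimal-fluorescence baseline F0.

    A sliding-window low percentile is taken along time (window starts every
    ``hop`` frames), the resulting envelope is smoothed with a short moving
    average, and the temporal minimum of the envelope is returned.  For a
    constant trace this returns the constant; sparse transients are ignored
    as long as they occupy less than ``percentile`` percent of some window.
    """
    stack = np.asarray(stack)
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < percentile <= 50:
        raise ValueError("percentile must lie in (0, 50]")
    n = stack.shape[0]
    if window > n:
        raise ValueError(f"window ({window}) longer than the recording ({n} frames)")
    starts = range(0, n - window + 1, max(1, hop))
    env = np.empty((len(starts),) + stack.shape[1:], dtype=np.float32)
    for i, s in enumerate(starts):
        env[i] = np.percentile(stack[s : s + window], percentile, axis=0)
    if smooth and smooth > 1 and env.shape[0] > 1:
        env = ndi.uniform_filter1d(env, size=min(smooth, env.shape[0]), axis=0, mode="nearest")
    return BaselineMap(f0=env.min(axis=0), window=window, percentile=percentile)


def compute_scale_factor(
    f0_green: BaselineMap,
    f0_red: BaselineMap,
    hill: HillParams,
    cell_mask: np.ndarray,
) -> float:
    """Global F_R scale factor from designated control recordings.

    Median over cell pixels of F0(green)/F0(red), divided by the Hill
    brightness at the assumed basal Ca2+, so that ``scale_k * F0(red)``
    estimates green fluorescence at zero Ca2+.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell_mask is empty")
    fr = f0_red.f0[cell_mask]
    fg = f0_green.f0[cell_mask]
    if np.any(fr <= 0):
        raise ValueError("red baseline is nonpositive inside cell_mask")
    ratio = float(np.median(fg / fr))
    return ratio / float(brightness(hill.basal_ca, hill))


def make_reference(f0_red: BaselineMap, scale_k: float) -> ReferenceMap:
    """Static per-pixel reference F_R = scale_k * F0(red)."""
    if not scale_k > 0:
        raise ValueError("scale_k must be > 0")
    return ReferenceMap(fr=scale_k * f0_red.f0, scale_k=float(scale_k))


def background_sigma(f0_red: BaselineMap) -> float:
    """Robust red-channel background noise scale.

    Median absolute deviation (scaled to sigma) of the sub-median F0(red)
    pixels; zero for a noiseless rendering where the background is exactly 0.
    """
    f0 = f0_red.f0
    low = f0[f0 <= np.median(f0)]
    return float(1.4826 * np.median(np.abs(low - np.median(low))))


def analysis_mask(reference: ReferenceMap, floor: float | None = None) -> np.ndarray:
    """Valid-pixel mask: F_R strictly above a noise floor.

    ``floor`` defaults to 0 (pure morphological mask); callers typically use
    ``2 * background_sigma(...)`` to drop ratio-unstable near-zero pixels.
    """
    if floor is None:
        floor = 0.0
    return reference.fr > floor


def compute_dff(movie: TwoChannelMovie, reference: ReferenceMap,
                mask: np.ndarray | None = None) -> DffMovie:
    """Ratiometric activity signal dF/F_R = (F - F_R) / F_R.

    Defined only where the reference is positive (and inside ``mask`` if
    given); excluded pixels are NaN.  Nonpositive F_R inside the requested
    mask is masked out with a logged count.
    """
    fr = reference.fr
    valid = fr > 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        n_bad = int((mask & ~valid).sum())
        if n_bad:
            log.warning("compute_dff: %d masked pixels have nonpositive F_R; excluded", n_bad)
        valid &= mask
    dff = np.full(movie.green.shape, np.nan, dtype=np.float32)
    np.divide(movie.green - fr, fr, out=dff, where=valid)
    return DffMovie(dff=dff, mask=valid, pixel_size=movie.pixel_size,
                    frame_interval=movie.frame_interval)
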