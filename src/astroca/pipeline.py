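"""End-to-end normalization: movie -> unmix -> F0 -> F_R -> dF/F_R."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hill import HillParams
from .ratiometric import (
    BaselineMap,
    DffMovie,
    MixingMatrix,
    ReferenceMap,
    TwoChannelMovie,
    analysis_mask,
    background_sigma,
    compute_dff,
    compute_scale_factor,
    estimate_f0,
    make_reference,
    unmix,
)

__all__ = ["NormalizationResult", "process_recording"]


@dataclass
class NormalizationResult:
    dff: DffMovie
    reference: ReferenceMap
    f0_green: BaselineMap
    f0_red: BaselineMap
    scale_k: float
    cell_mask: np.ndarray


def process_recording(
    movie: TwoChannelMovie,
    mixing: MixingMatrix | None,
    hill: HillParams,
    f0_window: int = 100,
    f0_percentile: float = 8.0,
    f0_smooth: int = 5,
    scale_k: float | None = None,
) -> NormalizationResult:
    """Run the full ratiometric normalization on one recording.

    When ``scale_k`` is None the factor is calibrated from this recording
    (appropriate for a designated control); pass the dataset-wide factor
    otherwise, mirroring the single-scale-factor convention.  The cell mask
    excludes pixels whose reference falls below twice the red-channel
    background noise.
    """
    if mixing is not None:
        movie = unmix(movie, mixing)
    f0_g = estimate_f0(movie.green, window=f0_window, percentile=f0_percentile, smooth=f0_smooth)
    f0_r = estimate_f0(movie.red, window=f0_window, percentile=f0_percentile, smooth=f0_smooth)
    sigma = background_sigma(f0_r)
    cell_mask = f0_r.f0 > 2.0 * sigma
    if scale_k is None:
        scale_k = compute_scale_factor(f0_g, f0_r, hill, cell_mask)
    reference = make_reference(f0_r, scale_k)
    mask = analysis_mask(reference, floor=2.0 * sigma * scale_k)
    dff = compute_dff(movie, reference, mask=mask)
    return NormalizationResult(
        dff=dff,
        reference=reference,
        f0_green=f0_g,
        f0_red=f0_r,
        scale_k=float(scale_k),
        cell_mask=cell_mask,
    )
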