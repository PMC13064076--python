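"""Volume-fraction analysis and relative basal Ca2+ in the astrocyte periphery.

The Ca2+-insensitive reference channel reports per-pixel indicator
expression, which for a 1:1 fusion construct is proportional to the
occupied cell volume within the optical voxel.  The volume fraction (VF)
map normalizes the reference per cell to its robust maximum (99th
percentile), so the thickest soma reads ~100 % and thin peripheral
processes a few percent.

Basal Ca2+ is compared between conditions through the ratio

    basal_ratio = F0(green) / F_R

averaged over the peripheral band (VF <= 12.5 % by default): because F_R
is scaled to the zero-Ca2+ green brightness, this ratio equals the Hill
brightness at the resting concentration and is monotone in it.  An
optional Hill inversion converts the ratio into nanomolar — this depends
on the assumed sensor dynamic range, so the dimensionless ratio is the
primary readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hill import HillParams, hill_inverse
from .ratiometric import BaselineMap, ReferenceMap

__all__ = ["VFProfile", "compute_vf", "basal_level"]

log = logging.getLogger(__name__)


@dataclass
class VFProfile:
    """Per-cell basal readouts in the low-VF band.

    ``per_cell`` columns: cell_id, n_pixels, n_excluded, basal_ratio,
    basal_ca_est (NaN when the ratio implies saturation or a negative
    concentration).
    """

    vf_max: float
    per_cell: pd.DataFrame


def compute_vf(
    reference: ReferenceMap,
    cell_labels: np.ndarray,
    anchor_percentile: float = 99.0,
) -> np.ndarray:
    """Per-pixel volume fraction in percent, normalized per cell.

    vf = 100 * F_R / F_R_ref with F_R_ref the per-cell ``anchor_percentile``
    of that cell's reference pixels, capped at 100.  Background is 0.  A
    degenerate (uniform-reference) cell maps to 100 % with a warning.
    """
    fr = reference.fr
    labels = np.asarray(cell_labels)
    if not (labels > 0).any():
        raise ValueError("cell_labels contains no cells")
    vf = np.zeros_like(fr, dtype=np.float64)
    for cid in np.unique(labels[labels > 0]):
        sel = labels == cid
        px = fr[sel]
        ref = np.percentile(px, anchor_percentile)
        if ref <= 0:
            log.warning("compute_vf: cell %d has nonpositive reference; set to 100%%", cid)
            vf[sel] = 100.0
            continue
        if px.max() == px.min():
            log.warning("compute_vf: cell %d has uniform reference", cid)
        vf[sel] = np.minimum(100.0 * px / ref, 100.0)
    return vf


def basal_level(
    f0_green: BaselineMap,
    reference: ReferenceMap,
    vf_map: np.ndarray,
    cell_labels: np.ndarray,
    hill: HillParams,
    vf_max: float = 12.5,
) -> VFProfile:
    """Per-cell basal ratio and optional nM estimate in the VF <= vf_max band.

    For each cell, basal_ratio is the mean of F0(green)/F_R over its pixels
    with 0 < VF <= ``vf_max``.  Pixels whose ratio implies a Hill saturation
    outside [0, 1) are excluded and counted.  The nM estimate inverts
    theta = (ratio - 1) / (dyn_range - 1) through the Hill model.
    """
    labels = np.asarray(cell_labels)
    band = (vf_map > 0) & (vf_map <= vf_max) & (reference.fr > 0)
    if not band.any():
        raise ValueError(f"no pixels with 0 < VF <= {vf_max}")
    rows = []
    for cid in np.unique(labels[labels > 0]):
        sel = band & (labels == cid)
        if not sel.any():
            log.warning("basal_level: cell %d has no pixels in the VF band", cid)
            continue
        ratio_px = f0_green.f0[sel] / reference.fr[sel]
        theta_px = (ratio_px - 1.0) / (hill.dyn_range - 1.0)
        ok = (theta_px >= 0) & (theta_px < 1)
        n_excl = int((~ok).sum())
        if n_excl:
            log.info("basal_level: cell %d: %d pixels outside theta range excluded", cid, n_excl)
        if not ok.any():
            rows.append(dict(cell_id=int(cid), n_pixels=0, n_excluded=n_excl,
                             basal_ratio=np.nan, basal_ca_est=np.nan))
            continue
        ratio = float(ratio_px[ok].mean())
        theta = (ratio - 1.0) / (hill.dyn_range - 1.0)
        est = float(hill_inverse(theta, hill)) if 0 <= theta < 1 else np.nan
        rows.append(dict(cell_id=int(cid), n_pixels=int(ok.sum()), n_excluded=n_excl,
                         basal_ratio=ratio, basal_ca_est=est))
    return VFProfile(vf_max=float(vf_max), per_cell=pd.DataFrame(rows))
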