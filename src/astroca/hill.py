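"""Hill-model calibration of GCaMP6s brightness.

GCaMP-family indicators bind Ca2+ cooperatively; the occupied (bright)
fraction follows a Hill curve

    theta(ca) = ca**n / (Kd**n + ca**n),

with dissociation constant ``Kd`` and Hill coefficient ``n``.  Sensor
brightness per unit indicator is modelled as

    B(ca) = 1 + (dyn_range - 1) * theta(ca),

so ``B(0) = 1`` and ``B(inf) = dyn_range`` (the fluorescence ratio between
the saturated and the Ca2+-free sensor).  GCaMP6s literature values are
Kd = 144 nM and n = 2.45; resting astrocyte Ca2+ is taken as ~50 nM.  The
dynamic range in situ is not well constrained and is kept configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillParams",
    "hill_saturation",
    "hill_inverse",
    "brightness",
    "dff_of_ca",
]


@dataclass(frozen=True)
class HillParams:
    """GCaMP6s calibration constants.

    Parameters
    ----------
    kd : float
        Dissociation constant in nM (> 0).
    hill_n : float
        Hill coefficient, dimensionless (> 0).
    dyn_range : float
        Brightness ratio of the Ca2+-saturated vs the Ca2+-free sensor (> 1).
    basal_ca : float
        Assumed resting Ca2+ concentration in nM (>= 0).
    """

    kd: float = 144.0
    hill_n: float = 2.45
    dyn_range: float = 50.0
    basal_ca: float = 50.0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if not self.hill_n > 0:
            raise ValueError(f"hill_n must be > 0, got {self.hill_n}")
        if not self.dyn_range > 1:
            raise ValueError(f"dyn_range must be > 1, got {self.dyn_range}")
        if self.basal_ca < 0:
            raise ValueError(f"basal_ca must be >= 0, got {self.basal_ca}")


def hill_saturation(ca, params: HillParams):
    """Occupied-sensor fraction theta(ca) in [0, 1).

    ``ca`` may be a scalar or array of concentrations in nM; negative
    concentrations are rejected.  Evaluated as 1 / (1 + (Kd/ca)**n) for
    numerical stability at large ``ca``; theta(0) = 0 exactly.
    """
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise ValueError("ca must be >= 0")
    pos = ca_arr > 0
    ratio = np.full_like(ca_arr, np.inf)
    np.divide(params.kd, ca_arr, out=ratio, where=pos)
    theta = 1.0 / (1.0 + ratio**params.hill_n)
    return theta if theta.ndim else float(theta)


def hill_inverse(theta, params: HillParams):
    """Concentration (nM) whose saturation equals ``theta``.

    Exact analytic inverse ``Kd * (theta / (1 - theta))**(1/n)``.  Raises
    for theta outside [0, 1); theta -> 1 signals sensor saturation and has
    no finite preimage.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th >= 1):
        raise ValueError("theta must lie in [0, 1); theta = 1 means saturation")
    ca = params.kd * (th / (1.0 - th)) ** (1.0 / params.hill_n)
    return ca if ca.ndim else float(ca)


def brightness(ca, params: HillParams):
    """Per-unit-indicator brightness 1 + (dyn_range - 1) * theta(ca)."""
    return 1.0 + (params.dyn_range - 1.0) * hill_saturation(ca, params)


def dff_of_ca(ca, params: HillParams):
    """Noiseless dF/F_R at concentration ``ca``.

    With F_R scaled to the zero-Ca2+ GCaMP brightness, the ratiometric
    signal of an ideal recording is B(ca) - 1 = (dyn_range - 1) * theta(ca).
    """
    return (params.dyn_range - 1.0) * hill_saturation(ca, params)
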