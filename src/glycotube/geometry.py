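"""Fixed-area tube geometry.

The membrane patch (flat reference area A0 = pi*R0^2) deforms into a family of
cylinders of radius Rt and length Lt capped by a hemisphere of the same
radius.  The family is indexed by the dimensionless shape parameter
chi = Lt/Rt; chi = 0 is the hemispherical-cap (nontubular) reference state.
Conservation of the grafted area, 2*pi*Rt*Lt + 2*pi*Rt^2 = pi*R0^2, fixes the
radius to Rt = R0 / sqrt(2*(1+chi)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = ["tube_radius", "make_geometry", "TubeGeometry"]


def tube_radius(chi, R0):
    """Tube/cap radius Rt (nm) at shape parameter ``chi`` for patch radius ``R0``.

    Accepts scalar or array ``chi``; strictly decreasing in chi.
    """
    chi = np.asarray(chi, dtype=float)
    if np.any(chi < 0):
        raise ValueError("shape parameter chi must be >= 0")
    if not R0 > 0:
        raise ValueError(f"patch radius R0 must be > 0, got {R0}")
    Rt = R0 / np.sqrt(2.0 * (1.0 + chi))
    return float(Rt) if Rt.ndim == 0 else Rt


@dataclass(frozen=True)
class TubeGeometry:
    """Derived geometric quantities of the capped cylinder at one chi.

    All lengths in nm, areas in nm^2; chain counts are real-valued.
    """

    chi: float
    Rt: float
    Lt: float
    area_total: float
    excess_area: float
    boundary_length: float
    height_Z: float
    Np_cap: float
    Np_tube: float


def make_geometry(chi: float, params: ModelParams) -> TubeGeometry:
    """Geometry of the capped cylinder at shape parameter ``chi``.

    area_total is conserved at pi*R0^2; the excess area over the flat patch is
    (2*chi+1)*pi*Rt^2, the domain boundary has length 2*pi*Rt and the patch
    height is Z = Rt*(1+chi).  Chain counts follow from the grafting density:
    Np_cap = 2*pi*Rt^2/xi^2 on the cap, Np_tube = 2*pi*Rt*Lt/xi^2 on the tube.
    """
    R0 = params.geometry.R0
    xi = params.glyco.xi
    Rt = tube_radius(chi, R0)
    Lt = chi * Rt
    return TubeGeometry(
        chi=float(chi),
        Rt=Rt,
        Lt=Lt,
        area_total=2.0 * math.pi * Rt**2 * (1.0 + chi),
        excess_area=(2.0 * chi + 1.0) * math.pi * Rt**2,
        boundary_length=2.0 * math.pi * Rt,
        height_Z=Rt * (1.0 + chi),
        Np_cap=2.0 * math.pi * Rt**2 / xi**2,
        Np_tube=2.0 * math.pi * Rt * Lt / xi**2,
    )
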