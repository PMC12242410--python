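"""Free energy of the glycocalyx-membrane composite.

The total free energy of a capped cylinder at shape parameter chi is the sum
of four mechanical contributions and the brush free energy of the grafted
glycopolymer layer.  Everything is computed in kBT and reported normalized by
pi*kappa, the natural bending-energy scale: a bare hemispherical cap
(chi = 0, c0 = 0) then has bending energy 4, since the hemisphere integral of
(kappa/2)*(2/Rt)^2 over the cap area 2*pi*Rt^2 equals 4*pi*kappa for any Rt.

Mechanical part (units of pi*kappa)::

    bending      = chi*Rt^2*(1/Rt - c0)^2 + Rt^2*(2/Rt - c0)^2
    tension      = (sigma/kappa)*(2*chi + 1)*Rt^2
    line_tension = 2*(lam/kappa)*Rt
    force_work   = -f*Rt*(1 + chi)/(pi*kappa)

Brush part.  Each grafted chain occupies an area that widens with radial
distance r from the tube axis / cap centre: s(r) = xi^2*(r/Rt)^2 on the cap
and s(r) = xi^2*(r/Rt) on the tube.  Balancing Gaussian stretching against
pairwise (second-virial) monomer repulsion chain-by-chain gives the local
monomer line density g(r) = (3*s(r)/(v*a^2))^(1/3) and a free energy per unit
length of 9/(2*a^2*g(r)) kBT.  Integrating from the grafting surface to the
brush edge (fixed by the monomer budget N per chain) yields closed forms

    E_cap(Rt)  = (9*Rt/2)*Phi*[(1 + (5*N/(3*Rt))*x)^(1/5) - 1]   kBT/chain
    E_tube(Rt) = (9*Rt/4)*Phi*[(1 + (4*N/(3*Rt))*x)^(1/2) - 1]   kBT/chain

with x = (v*a^2/(3*xi^2))^(1/3) the flat-brush height per monomer (h0 = N*x)
and Phi = 3*x/a^2 = (9*v/(a^4*xi^2))^(1/3).  Both reduce, as Rt -> infinity,
to the flat-brush energy (3*N/2)*(3*v^2/(a^2*xi^4))^(1/3) kBT per chain;
curvature dilutes the brush and lowers the energy below that limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .geometry import tube_radius
from .params import GlycocalyxParams, ModelParams

__all__ = [
    "EnergyBreakdown",
    "MechanicalEnergy",
    "mechanical_energy",
    "brush_energy_cap_per_chain",
    "brush_energy_tube_per_chain",
    "flat_brush_energy_per_chain",
    "flat_brush_height",
    "glycocalyx_energy",
    "total_energy",
    "total_energy_grid",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Component-wise normalized energies (units of pi*kappa) at one chi."""

    chi: float
    bending: float
    tension: float
    line_tension: float
    force_work: float
    glyco_cap: float
    glyco_tube: float
    total: float
    pi_kappa: float  # conversion factor back to kBT

    @property
    def total_kBT(self) -> float:
        """Total free energy in kBT."""
        return self.total * self.pi_kappa


class MechanicalEnergy(NamedTuple):
    bending: float
    tension: float
    line_tension: float
    force_work: float


def mechanical_energy(chi, params: ModelParams) -> MechanicalEnergy:
    """Bending, tension, line-tension and force-work terms in units of pi*kappa.

    Vectorized over ``chi``.
    """
    m = params.membrane
    Rt = tube_radius(chi, params.geometry.R0)
    chi = np.asarray(chi, dtype=float)
    bending = chi * Rt**2 * (1.0 / Rt - m.c0) ** 2 + Rt**2 * (2.0 / Rt - m.c0) ** 2
    tension = (m.sigma / m.kappa) * (2.0 * chi + 1.0) * Rt**2
    line = 2.0 * (m.lam / m.kappa) * Rt
    work = -params.load.f * Rt * (1.0 + chi) / (math.pi * m.kappa)
    if chi.ndim == 0:
        return MechanicalEnergy(float(bending), float(tension), float(line), float(work))
    return MechanicalEnergy(bending, tension, line, work)


def _brush_x(glyco: GlycocalyxParams) -> float:
    # flat-brush height per monomer, h0 = N * x
    return (glyco.v * glyco.a**2 / (3.0 * glyco.xi**2)) ** (1.0 / 3.0)


def _brush_phi(glyco: GlycocalyxParams) -> float:
    # energy prefactor per unit length, (9 v / (a^4 xi^2))^(1/3), units 1/nm
    return 3.0 * _brush_x(glyco) / glyco.a**2


def flat_brush_height(glyco: GlycocalyxParams) -> float:
    """Equilibrium height h0 = N*(v*a^2/(3*xi^2))^(1/3) of a flat brush (nm)."""
    return glyco.N * _brush_x(glyco)


def flat_brush_energy_per_chain(glyco: GlycocalyxParams) -> float:
    """Flat-brush free energy per chain, (3N/2)*(3*v^2/(a^2*xi^4))^(1/3) kBT.

    Common large-Rt limit of the cap and tube brush energies.
    """
    return 1.5 * glyco.N * (3.0 * glyco.v**2 / (glyco.a**2 * glyco.xi**4)) ** (1.0 / 3.0)


def _check_Rt(Rt) -> np.ndarray:
    Rt = np.asarray(Rt, dtype=float)
    if np.any(Rt <= 0):
        raise ValueError("tube radius Rt must be > 0")
    return Rt


def brush_energy_cap_per_chain(Rt, glyco: GlycocalyxParams):
    """Brush free energy per chain grafted on the hemispherical cap (kBT)."""
    Rt = _check_Rt(Rt)
    x = _brush_x(glyco)
    out = (
        4.5
        * Rt
        * _brush_phi(glyco)
        * ((1.0 + (5.0 * glyco.N / (3.0 * Rt)) * x) ** 0.2 - 1.0)
    )
    return float(out) if out.ndim == 0 else out


def brush_energy_tube_per_chain(Rt, glyco: GlycocalyxParams):
    """Brush free energy per chain grafted on the cylindrical tube (kBT)."""
    Rt = _check_Rt(Rt)
    x = _brush_x(glyco)
    out = (
        2.25
        * Rt
        * _brush_phi(glyco)
        * (np.sqrt(1.0 + (4.0 * glyco.N / (3.0 * Rt)) * x) - 1.0)
    )
    return float(out) if out.ndim == 0 else out


def glycocalyx_energy(chi, params: ModelParams):
    """Cap and tube brush energies of the whole patch, in units of pi*kappa.

    Returns ``(glyco_cap, glyco_tube)``; vectorized over ``chi``.
    glyco_cap = Np_cap*E_cap/(pi*kappa) with Np_cap = 2*pi*Rt^2/xi^2, and
    glyco_tube = Np_tube*E_tube/(pi*kappa) with Np_tube = 2*pi*Rt*Lt/xi^2.
    """
    g = params.glyco
    kappa = params.membrane.kappa
    Rt = tube_radius(chi, params.geometry.R0)
    chi = np.asarray(chi, dtype=float)
    per_cap = brush_energy_cap_per_chain(Rt, g)
    per_tube = brush_energy_tube_per_chain(Rt, g)
    np_cap = 2.0 * math.pi * np.asarray(Rt) ** 2 / g.xi**2
    np_tube = np_cap * chi  # 2*pi*Rt*Lt/xi^2 with Lt = chi*Rt
    cap = np_cap * np.asarray(per_cap) / (math.pi * kappa)
    tube = np_tube * np.asarray(per_tube) / (math.pi * kappa)
    if chi.ndim == 0:
        return float(cap), float(tube)
    return cap, tube


def total_energy(chi: float, params: ModelParams) -> EnergyBreakdown:
    """Full component breakdown of the normalized free energy at one chi."""
    mech = mechanical_energy(chi, params)
    cap, tube = glycocalyx_energy(chi, params)
    total = mech.bending + mech.tension + mech.line_tension + mech.force_work + cap + tube
    return EnergyBreakdown(
        chi=float(chi),
        bending=mech.bending,
        tension=mech.tension,
        line_tension=mech.line_tension,
        force_work=mech.force_work,
        glyco_cap=cap,
        glyco_tube=tube,
        total=total,
        pi_kappa=math.pi * params.membrane.kappa,
    )


def total_energy_grid(chi, params: ModelParams) -> np.ndarray:
    """Total normalized free energy on an array of chi values (fast path)."""
    mech = mechanical_energy(chi, params)
    cap, tube = glycocalyx_energy(chi, params)
    return mech.bending + mech.tension + mech.line_tension + mech.force_work + cap + tube
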