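"""Independent reference implementations used only as test oracles.

Each oracle takes a different computational route from the library code it
checks: the brush energies are recomputed by numerical quadrature of the
per-chain energy density (no closed forms), the total energy by a single
monolithic expression, and landscape minima by exhaustive fine-grid search.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from glycotube.energy import total_energy_grid
from glycotube.params import GlycocalyxParams, ModelParams


def brush_energy_quadrature(Rt: float, glyco: GlycocalyxParams, surface: str) -> float:
    """Per-chain brush energy (kBT) by direct quadrature.

    The area per chain widens with radial distance as s(r) = xi^2*(r/Rt)^p
    with p = 2 on the spherical cap and p = 1 on the cylinder.  The local
    monomer line density follows the flat-brush stretching/excluded-volume
    balance g(r) = (3*s(r)/(v*a^2))**(1/3); the brush edge Rt + h is fixed by
    the monomer budget integral(g) = N, found by root bracketing; the energy
    is the integral of 3/(2*a^2*g) + v*g^2/s(r).
    """
    p = {"cap": 2.0, "tube": 1.0}[surface]
    a, v, xi, N = glyco.a, glyco.v, glyco.xi, glyco.N
    if N == 0:
        return 0.0

    def s(r):
        return xi**2 * (r / Rt) ** p

    def g(r):
        return (3.0 * s(r) / (v * a**2)) ** (1.0 / 3.0)

    def monomers(h):
        return quad(g, Rt, Rt + h, limit=200)[0] - N

    h_hi = 10.0 * N * (v * a**2 / (3 * xi**2)) ** (1 / 3) + Rt
    h = brentq(monomers, 1e-12, h_hi, xtol=1e-12, rtol=1e-14)

    def density(r):
        return 3.0 / (2.0 * a**2 * g(r)) + v * g(r) ** 2 / s(r)

    return quad(density, Rt, Rt + h, limit=200)[0]


def eq_total_closed_form(chi, d: dict[str, float]):
    """Monolithic transcription of the full normalized energy.

    ``d`` is a flat parameter dict (kappa, sigma, lam, c0, f, R0, xi, N, a, v).
    Uses the expanded polynomial form of the mechanical part and the
    consolidated brush block, written in one expression with no shared helper
    code.
    """
    chi = np.asarray(chi, dtype=float)
    kappa, sigma, lam, c0 = d["kappa"], d["sigma"], d["lam"], d["c0"]
    f, R0, xi, N, a, v = d["f"], d["R0"], d["xi"], d["N"], d["a"], d["v"]
    Rt = R0 / np.sqrt(2.0 * (1.0 + chi))
    x = (v * a**2 / (3.0 * xi**2)) ** (1.0 / 3.0)
    return (
        ((chi + 1.0) * c0**2 + (sigma / kappa) * (2.0 * chi + 1.0)) * Rt**2
        + 2.0 * Rt * (lam / kappa - chi * c0 - 2.0 * c0)
        + chi + 4.0
        - f * Rt * (1.0 + chi) / (math.pi * kappa)
        + (9.0 * Rt**3 / (2.0 * kappa * xi**2))
        * (9.0 * v / (a**4 * xi**2)) ** (1.0 / 3.0)
        * (
            2.0 * ((1.0 + (5.0 * N / (3.0 * Rt)) * x) ** 0.2 - 1.0)
            + chi * (np.sqrt(1.0 + (4.0 * N / (3.0 * Rt)) * x) - 1.0)
        )
    )


def mechanical_factored_form(chi, d: dict[str, float]):
    """Term-by-term (factored) form of the mechanical energy, units pi*kappa."""
    chi = np.asarray(chi, dtype=float)
    kappa, sigma, lam, c0, f, R0 = (d["kappa"], d["sigma"], d["lam"], d["c0"],
                                    d["f"], d["R0"])
    Rt = R0 / np.sqrt(2.0 * (1.0 + chi))
    return (
        chi * Rt**2 * (1.0 / Rt - c0) ** 2
        + Rt**2 * (2.0 / Rt - c0) ** 2
        + (sigma / kappa) * (2.0 * chi + 1.0) * Rt**2
        + 2.0 * (lam / kappa) * Rt
        - f * Rt * (1.0 + chi) / (math.pi * kappa)
    )


def brute_force_chi_min(params: ModelParams, chi_max: float, n: int = 1_000_000):
    """Exhaustive fine-grid global minimum of F(chi) on [0, chi_max]."""
    chi = np.linspace(0.0, chi_max, n)
    F = total_energy_grid(chi, params)
    i = int(np.argmin(F))
    return float(chi[i]), float(F[i])


def random_admissible_params(rng: np.random.Generator) -> ModelParams:
    """Draw one physically admissible parameter set (v pinned to a^3)."""
    from glycotube.params import (GeometryParams, LoadParams, MembraneParams,
                                  ModelParams)

    a = rng.uniform(5.0, 15.0)
    return ModelParams(
        membrane=MembraneParams(
            kappa=rng.uniform(5.0, 50.0),
            sigma=rng.uniform(0.0, 0.05),
            lam=rng.uniform(0.0, 1.0),
            c0=rng.uniform(0.0, 0.04),
        ),
        glyco=GlycocalyxParams(
            xi=rng.uniform(10.0, 40.0),
            N=rng.uniform(5.0, 50.0),
            a=a,
        ),
        load=LoadParams(f=rng.uniform(0.0, 2.0)),
        geometry=GeometryParams(R0=rng.uniform(60.0, 140.0)),
    )
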