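"""Scanning, refining and classifying the energy landscape F(chi).

For one parameter set the total normalized energy is sampled on a dense chi
grid, every interior local minimum is refined by bounded scalar minimization,
and the landscape is classified as nontubular, metastable-tubular,
coexistence or tubular by comparing the best tubular basin against the
chi = 0 (hemispherical cap) state.  The barrier separating the two basins is
the refined interior maximum between them, measured from F(0).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .energy import total_energy_grid
from .params import ModelParams

__all__ = [
    "StateLabel",
    "Landscape",
    "ChiRangeError",
    "scan_landscape",
    "classify",
    "energy_barrier",
    "COEXISTENCE_TOL",
]

logger = logging.getLogger(__name__)

#: Energy tolerance (units of pi*kappa) inside which the tubular and
#: nontubular basins are called degenerate ("coexistence").  Two orders of
#: magnitude below the unit bending scale, well above refinement error.
COEXISTENCE_TOL = 1e-3


class StateLabel(str, enum.Enum):
    """Thermodynamic classification of the membrane patch."""

    NONTUBULAR = "NONTUBULAR"
    METASTABLE_TUBULAR = "METASTABLE_TUBULAR"
    COEXISTENCE = "COEXISTENCE"
    TUBULAR = "TUBULAR"


class ChiRangeError(ValueError):
    """The energy still decreases at chi_max; the scan window truncates a basin."""


@dataclass(frozen=True)
class Landscape:
    """Sampled energy profile over chi with refined minima and classification.

    chi_grid / F_grid : dense samples of F(chi) in units of pi*kappa
    minima            : refined local minima as (chi*, F*) pairs, sorted by chi;
                        includes (0, F(0)) when chi = 0 is a one-sided minimum
    chi_min / F_min   : global-minimum location and value
    barrier           : Delta F from the chi = 0 basin to the best tubular
                        basin (None when no tubular minimum exists)
    barrier_chi       : location of the intervening maximum (None likewise)
    state             : StateLabel per `classify`
    """

    params: ModelParams
    chi_grid: np.ndarray
    F_grid: np.ndarray
    minima: tuple[tuple[float, float], ...]
    chi_min: float
    F_min: float
    barrier: float | None
    barrier_chi: float | None
    state: StateLabel

    @property
    def F0(self) -> float:
        """Energy of the nontubular (chi = 0) state, units of pi*kappa."""
        return float(self.F_grid[0])

    def tubular_minimum(self) -> tuple[float, float] | None:
        """Lowest-energy interior (chi > 0) minimum, or None."""
        interior = [(c, F) for c, F in self.minima if c > 0]
        if not interior:
            return None
        return min(interior, key=lambda m: m[1])

    def to_csv(self, path: str | Path) -> None:
        """Write the sampled profile as two-column CSV."""
        header = "chi,F_over_pi_kappa"
        np.savetxt(path, np.column_stack([self.chi_grid, self.F_grid]),
                   delimiter=",", header=header, comments="")

    def to_json(self, path: str | Path) -> None:
        """Write minima, barrier and state as a JSON sidecar."""
        payload = {
            "minima": [{"chi": c, "F_over_pi_kappa": F} for c, F in self.minima],
            "chi_min": self.chi_min,
            "F_min": self.F_min,
            "F0": self.F0,
            "barrier": self.barrier,
            "barrier_chi": self.barrier_chi,
            "state": self.state.value,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _refine_minimum(F, lo: float, hi: float, xatol: float = 1e-9) -> tuple[float, float]:
    res = minimize_scalar(F, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    return float(res.x), float(res.fun)


def scan_landscape(
    params: ModelParams,
    *,
    coexistence_tol: float = COEXISTENCE_TOL,
    auto_extend: bool = False,
    max_extensions: int = 6,
) -> Landscape:
    """Sample F(chi) on [0, chi_max], refine all minima and classify the state.

    The grid comes from ``params.geometry`` (chi_max, n_grid).  A landscape
    that is still decreasing at the right edge means the scan window cuts off
    a basin: by default this raises :class:`ChiRangeError` instructing the
    caller to enlarge chi_max; with ``auto_extend=True`` the window is doubled
    (keeping the grid spacing) up to ``max_extensions`` times.

    Interior minima are refined to |dchi| well below 1e-6 by bounded scalar
    minimization between their neighbouring grid points; chi = 0 is treated as
    a boundary candidate via a one-sided test F(delta) > F(0).
    """
    geo = params.geometry
    chi_max, n_grid = geo.chi_max, geo.n_grid
    spacing = chi_max / (n_grid - 1)
    for _ in range(max_extensions + 1):
        chi = np.linspace(0.0, chi_max, n_grid)
        F = total_energy_grid(chi, params)
        if F[-1] > F[-2]:
            break
        if not auto_extend:
            raise ChiRangeError(
                f"F(chi) is still decreasing at chi_max={chi_max:g}; enlarge "
                f"geometry.chi_max (e.g. to {2 * chi_max:g}) so the scan "
                "brackets every basin"
            )
        chi_max *= 2.0
        n_grid = int(round(chi_max / spacing)) + 1
        logger.debug("extending chi window to [0, %g] (%d points)", chi_max, n_grid)
    else:
        raise ChiRangeError(
            f"F(chi) still decreasing at chi_max={chi_max:g} after "
            f"{max_extensions} window doublings"
        )

    Ffun = lambda c: float(total_energy_grid(np.asarray(c, dtype=float), params))

    minima: list[tuple[float, float]] = []
    if F[1] > F[0]:  # one-sided boundary minimum at chi = 0
        minima.append((0.0, float(F[0])))
    interior = np.where((F[1:-1] < F[:-2]) & (F[1:-1] <= F[2:]))[0] + 1
    for i in interior:
        c_ref, F_ref = _refine_minimum(Ffun, chi[i - 1], chi[i + 1])
        # merge refinements that collapse onto an already-found minimum
        if minima and abs(c_ref - minima[-1][0]) < 2 * spacing * 1e-3:
            if F_ref < minima[-1][1]:
                minima[-1] = (c_ref, F_ref)
            continue
        minima.append((c_ref, F_ref))

    candidates = list(minima) if minima else [(0.0, float(F[0]))]
    best_F = min(Fv for _, Fv in candidates)
    best = [m for m in candidates if m[1] <= best_F + 1e-12]
    if len(best) > 1:
        logger.warning(
            "degenerate global minima at chi=%s; reporting the smallest chi",
            [round(c, 6) for c, _ in best],
        )
    chi_min, F_min = min(best, key=lambda m: m[0])

    landscape = Landscape(
        params=params,
        chi_grid=chi,
        F_grid=F,
        minima=tuple(sorted(minima, key=lambda m: m[0])),
        chi_min=chi_min,
        F_min=F_min,
        barrier=None,
        barrier_chi=None,
        state=StateLabel.NONTUBULAR,
    )
    barrier, barrier_chi = _compute_barrier(landscape, Ffun)
    state = classify(landscape, tol=coexistence_tol)
    return dataclasses.replace(landscape, barrier=barrier, barrier_chi=barrier_chi,
                               state=state)


def classify(landscape: Landscape, tol: float = COEXISTENCE_TOL) -> StateLabel:
    """Label a landscape by comparing the tubular basin with the chi=0 state.

    NONTUBULAR when no interior minimum exists; otherwise the best tubular
    minimum F_tub is compared with F(0): TUBULAR when F_tub < F(0) - tol,
    METASTABLE_TUBULAR when F_tub > F(0) + tol, COEXISTENCE within ``tol``
    (units of pi*kappa).
    """
    tub = landscape.tubular_minimum()
    if tub is None:
        return StateLabel.NONTUBULAR
    dF = tub[1] - landscape.F0
    if abs(dF) <= tol:
        return StateLabel.COEXISTENCE
    return StateLabel.TUBULAR if dF < 0 else StateLabel.METASTABLE_TUBULAR


def _compute_barrier(landscape: Landscape, Ffun) -> tuple[float | None, float | None]:
    tub = landscape.tubular_minimum()
    if tub is None:
        return None, None
    chi_tub = tub[0]
    chi, F = landscape.chi_grid, landscape.F_grid
    sel = chi <= chi_tub
    i = int(np.argmax(F[sel]))
    if 0 < i < sel.sum() - 1:
        res = minimize_scalar(lambda c: -Ffun(c), bounds=(chi[i - 1], chi[i + 1]),
                              method="bounded", options={"xatol": 1e-9})
        chi_b, F_b = float(res.x), float(-res.fun)
    else:
        chi_b, F_b = float(chi[sel][i]), float(F[sel][i])
    return max(F_b - float(F[0]), 0.0), chi_b


def energy_barrier(landscape: Landscape) -> float | None:
    """Barrier Delta F (units of pi*kappa) from chi=0 to the tubular basin.

    None when the landscape has no tubular minimum.
    """
    return landscape.barrier
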