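"""Critical grafting density and polymer length by bisection.

Two notions of "critical" are exposed, mirroring the two phenomena of a
first-order transition:

* BINODAL (coexistence): the parameter value at which the tubular basin's
  energy equals the chi = 0 energy.  Crossing it, the global minimum jumps
  discontinuously from chi = 0 to a finite tube.
* SPINODAL: the value at which a second (tubular) local minimum first
  appears, i.e. the edge of metastability.

Both are located by bisection on a monotone indicator: the sign of
F_tub - F(0) for the binodal (treated as positive while no tubular minimum
exists), and the existence of an interior minimum for the spinodal.  The
search variable is either the grafting density rho = 1/xi^2 (nm^-2) or the
real-valued chain length N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import Landscape, scan_landscape
from .params import ModelParams, with_param

__all__ = [
    "BINODAL",
    "SPINODAL",
    "CriticalPoint",
    "NoTransitionError",
    "critical_density",
    "critical_length",
    "critical_curve",
]

logger = logging.getLogger(__name__)

BINODAL = "BINODAL"
SPINODAL = "SPINODAL"


class NoTransitionError(RuntimeError):
    """No nontubular/tubular transition inside the searched bracket."""


@dataclass(frozen=True)
class CriticalPoint:
    """Result of a critical-parameter search.

    parameter_name    : 'rho' (nm^-2) or 'N' (monomers)
    kind              : 'BINODAL' or 'SPINODAL'
    value             : critical parameter value (midpoint of final bracket)
    bracket           : final bisection interval containing the root
    chi_at_transition : tubular-minimum location just above the critical point
    """

    parameter_name: str
    kind: str
    value: float
    bracket: tuple[float, float]
    chi_at_transition: float

    @property
    def value_ceil(self) -> int:
        """Integer ceiling, meaningful for chain-length criticals."""
        return math.ceil(self.value)


def _scan(params: ModelParams, name: str, value: float) -> Landscape:
    return scan_landscape(with_param(params, name, value), auto_extend=True)


def _indicator(params: ModelParams, name: str, value: float, kind: str) -> bool:
    """True when the state at this parameter value is past the critical point."""
    ls = _scan(params, name, value)
    tub = ls.tubular_minimum()
    if kind == SPINODAL:
        return tub is not None
    if kind == BINODAL:
        return tub is not None and tub[1] <= ls.F0
    raise ValueError(f"kind must be {BINODAL!r} or {SPINODAL!r}, got {kind!r}")


def _bisect(
    params: ModelParams,
    name: str,
    kind: str,
    lo: float,
    hi: float,
    tol: float,
    expand: bool,
) -> CriticalPoint:
    """Bisect the smallest parameter value whose indicator is True.

    Both indicators are monotone in rho and in N (denser/longer brushes only
    ever favour the tube), so a single boolean bisection locates either kind.
    """
    ind_lo = _indicator(params, name, lo, kind)
    ind_hi = _indicator(params, name, hi, kind)
    if ind_lo or not ind_hi:
        if expand:
            lo2, hi2 = lo / 2.0, hi * 2.0
            logger.info(
                "no %s transition of %s in [%g, %g]; expanding once to [%g, %g]",
                kind, name, lo, hi, lo2, hi2,
            )
            return _bisect(params, name, kind, lo2, hi2, tol, expand=False)
        raise NoTransitionError(
            f"no {kind} transition of {name} in bracket [{lo:g}, {hi:g}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _indicator(params, name, mid, kind):
            hi = mid
        else:
            lo = mid
    tub = _scan(params, name, hi).tubular_minimum()
    chi_at = tub[0] if tub is not None else float("nan")
    return CriticalPoint(
        parameter_name=name,
        kind=kind,
        value=0.5 * (lo + hi),
        bracket=(lo, hi),
        chi_at_transition=chi_at,
    )


def critical_density(
    params: ModelParams,
    kind: str = BINODAL,
    *,
    bracket: tuple[float, float] = (1e-4, 1e-2),
    tol: float = 1e-6,
) -> CriticalPoint:
    """Critical grafting density rho_c (nm^-2) at fixed chain length.

    The default bracket spans the Table-range grafting distances
    xi in [10, 100] nm.  The bracket is auto-expanded once before failing
    with :class:`NoTransitionError`.
    """
    return _bisect(params, "rho", kind, bracket[0], bracket[1], tol, expand=True)


def critical_length(
    params: ModelParams,
    kind: str = BINODAL,
    *,
    bracket: tuple[float, float] = (1.0, 60.0),
    tol: float = 1e-4,
) -> CriticalPoint:
    """Critical chain length N_c (monomers, continuous) at fixed density."""
    return _bisect(params, "N", kind, bracket[0], bracket[1], tol, expand=True)


def critical_curve(
    params: ModelParams,
    critical_kind: str,
    swept_parameter: str,
    grid,
    *,
    search: str = "rho",
    **search_kwargs,
) -> pd.DataFrame:
    """Critical value as a function of a facilitating parameter.

    ``swept_parameter`` is one of {'f', 'lam', 'c0'}; at each grid value the
    critical density (``search='rho'``) or length (``search='N'``) of kind
    ``critical_kind`` is located.  Points where the search fails are recorded
    as NaN and the sweep continues.

    Returns a DataFrame with columns (swept_value, critical_value,
    chi_at_transition).
    """
    if swept_parameter not in ("f", "lam", "c0"):
        raise ValueError("swept_parameter must be one of 'f', 'lam', 'c0'")
    finder = critical_density if search == "rho" else critical_length
    rows = []
    for value in np.asarray(grid, dtype=float):
        p = with_param(params, swept_parameter, float(value))
        try:
            cp = finder(p, critical_kind, **search_kwargs)
            rows.append((value, cp.value, cp.chi_at_transition))
        except NoTransitionError as err:
            logger.warning("%s=%g: %s", swept_parameter, value, err)
            rows.append((value, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["swept_value", "critical_value",
                                       "chi_at_transition"])
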