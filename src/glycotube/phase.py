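"""Parameter sweeps and 2D phase diagrams of the tubulation transition.

``sweep_1d`` scans one parameter and records the optimal shape parameter
chi_min and the state label at each point.  ``sweep_2d`` does the same on a
rectangular grid of two parameters and extracts the nontubular/tubular
boundary by marching over label changes between adjacent cells.

Sweepable names are the flat parameter keys (kappa, sigma, lam, c0, f, R0,
xi, N, a, v) plus the derived ``rho`` (grafting density, nm^-2) and ``Np``
(total chain count on the patch, Np = pi*R0^2/xi^2, the natural axis for
phase diagrams over brush coverage).

The whole pipeline is deterministic: repeated sweeps are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import ChiRangeError, StateLabel, scan_landscape
from .params import ModelParams, with_param

__all__ = ["PhaseMap", "sweep_1d", "sweep_2d", "TUBULAR_LABELS"]

logger = logging.getLogger(__name__)

#: Labels counted as "tubular region" when extracting phase boundaries: the
#: tube is the global minimum (degenerate at coexistence).
TUBULAR_LABELS = frozenset({StateLabel.TUBULAR, StateLabel.COEXISTENCE})

_AXIS_UNITS = {
    "kappa": "kBT", "sigma": "kBT/nm^2", "lam": "kBT/nm", "c0": "1/nm",
    "f": "kBT/nm", "R0": "nm", "xi": "nm", "N": "monomers", "a": "nm",
    "v": "nm^3", "rho": "nm^-2", "Np": "chains",
}


def _point(params: ModelParams, name: str, value: float):
    """(chi_min, state) at one parameter value; errors become NaN/None."""
    try:
        ls = scan_landscape(with_param(params, name, float(value)), auto_extend=True)
        return ls.chi_min, ls.state
    except (ChiRangeError, ValueError) as err:
        logger.warning("sweep point %s=%g failed: %s", name, value, err)
        return float("nan"), None


def sweep_1d(params: ModelParams, parameter_name: str, grid) -> pd.DataFrame:
    """Scan one parameter; returns columns (value, chi_min, state).

    Per-point landscape failures are recorded as NaN and the sweep continues.
    """
    rows = []
    for value in np.asarray(grid, dtype=float):
        chi_min, state = _point(params, parameter_name, value)
        rows.append((value, chi_min, state.value if state is not None else None))
        logger.info("%s=%g -> chi_min=%s", parameter_name, value, chi_min)
    df = pd.DataFrame(rows, columns=["value", "chi_min", "state"])
    df.attrs["parameter"] = parameter_name
    df.attrs["units"] = _AXIS_UNITS.get(parameter_name, "")
    return df


@dataclass(frozen=True)
class PhaseMap:
    """chi_min and state maps over a 2D parameter grid.

    chi_min_grid and state_grid are indexed [iy, ix] (rows = y axis), the
    layout matplotlib's pcolormesh expects.  ``boundary`` holds midpoints of
    grid edges whose two cells carry different tubular/nontubular labels.
    """

    x_name: str
    y_name: str
    x_units: str
    y_units: str
    x_values: np.ndarray
    y_values: np.ndarray
    chi_min_grid: np.ndarray
    state_grid: np.ndarray  # dtype=object of StateLabel (or None on failure)
    boundary: tuple[tuple[float, float], ...]

    def tubular_mask(self) -> np.ndarray:
        """Boolean grid: True where the tubular state is the global minimum."""
        return np.vectorize(lambda s: s in TUBULAR_LABELS)(self.state_grid)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per grid cell."""
        rows = []
        for iy, y in enumerate(self.y_values):
            for ix, x in enumerate(self.x_values):
                s = self.state_grid[iy, ix]
                rows.append((x, y, self.chi_min_grid[iy, ix],
                             s.value if s is not None else None))
        return pd.DataFrame(rows, columns=[self.x_name, self.y_name,
                                           "chi_min", "state"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        meta = {
            "x": {"name": self.x_name, "units": self.x_units,
                  "values": self.x_values.tolist()},
            "y": {"name": self.y_name, "units": self.y_units,
                  "values": self.y_values.tolist()},
            "boundary": [list(p) for p in self.boundary],
        }
        Path(path).write_text(json.dumps(meta, indent=2) + "\n")

    def plot(self, path: str | Path | None = None, ax=None):
        """Render the chi_min field as a heatmap with the phase boundary."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        mesh = ax.pcolormesh(self.x_values, self.y_values, self.chi_min_grid,
                             shading="nearest", cmap="viridis")
        plt.colorbar(mesh, ax=ax, label=r"$\chi_\mathrm{min}$")
        if self.boundary:
            bx, by = zip(*self.boundary)
            ax.plot(bx, by, "w.", ms=3)
        ax.set_xlabel(f"{self.x_name} ({self.x_units})")
        ax.set_ylabel(f"{self.y_name} ({self.y_units})")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def _edge_boundary(x, y, tubular) -> tuple[tuple[float, float], ...]:
    pts = []
    ny, nx = tubular.shape
    for iy in range(ny):
        for ix in range(nx - 1):
            if tubular[iy, ix] != tubular[iy, ix + 1]:
                pts.append((0.5 * (x[ix] + x[ix + 1]), float(y[iy])))
    for iy in range(ny - 1):
        for ix in range(nx):
            if tubular[iy, ix] != tubular[iy + 1, ix]:
                pts.append((float(x[ix]), 0.5 * (y[iy] + y[iy + 1])))
    return tuple(pts)


def sweep_2d(
    params: ModelParams,
    x_axis: str,
    y_axis: str,
    x_grid,
    y_grid,
) -> PhaseMap:
    """Full chi_min / state map over a rectangular parameter grid."""
    x = np.asarray(x_grid, dtype=float)
    y = np.asarray(y_grid, dtype=float)
    chi_min = np.empty((y.size, x.size))
    states = np.empty((y.size, x.size), dtype=object)
    for iy, yv in enumerate(y):
        p_row = with_param(params, y_axis, float(yv))
        for ix, xv in enumerate(x):
            cm, st = _point(p_row, x_axis, xv)
            chi_min[iy, ix] = cm
            states[iy, ix] = st
        logger.info("%s=%g row done (%d/%d)", y_axis, yv, iy + 1, y.size)
    tubular = np.vectorize(lambda s: s in TUBULAR_LABELS)(states)
    return PhaseMap(
        x_name=x_axis,
        y_name=y_axis,
        x_units=_AXIS_UNITS.get(x_axis, ""),
        y_units=_AXIS_UNITS.get(y_axis, ""),
        x_values=x,
        y_values=y,
        chi_min_grid=chi_min,
        state_grid=states,
        boundary=_edge_boundary(x, y, tubular),
    )
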