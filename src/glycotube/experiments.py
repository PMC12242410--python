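"""Reproducible experiment drivers.

An :class:`ExperimentSpec` bundles a named analysis (landscape family, 1D or
2D sweep, critical point, critical curve), a base parameter set and the sweep
definitions, and ``run_experiment`` executes it into a directory of CSV/JSON
outputs plus a run-metadata file.  Everything is deterministic: re-running a
spec yields byte-identical CSVs.

``builtin_scenarios`` returns ready-made specs for the standard analyses:
energy-profile families over grafting density and chain length, chi_min
sweeps, critical-value curves against force / line tension / spontaneous
curvature, and the four (Np, N) phase diagrams with the facilitating terms
switched on and off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .criticality import BINODAL, critical_curve, critical_density, critical_length
from .landscape import scan_landscape
from .params import PARAM_NAMES, ModelParams, bare_params, with_param
from .phase import sweep_1d, sweep_2d

__all__ = ["ExperimentSpec", "run_experiment", "builtin_scenarios"]

_KINDS = ("landscape", "sweep1d", "sweep2d", "critical", "critical-curve")
_SWEEPABLE = set(PARAM_NAMES) | {"rho", "Np"}


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one runnable experiment.

    name    : identifier, used as the output subdirectory
    kind    : one of landscape | sweep1d | sweep2d | critical | critical-curve
    params  : base parameter set
    sweeps  : kind-specific definitions:
              landscape      -> {"parameter": str, "values": [..]}
              sweep1d        -> {"parameter": str, "grid": [..]}
              sweep2d        -> {"x_axis": str, "y_axis": str,
                                 "x_grid": [..], "y_grid": [..]}
              critical       -> {"search": "rho"|"N", "kind": BINODAL|SPINODAL}
              critical-curve -> {"curves": [{"search": .., "kind": ..,
                                 "swept_parameter": .., "grid": [..]}, ..]}
    coexistence_tol : optional override of the coexistence tolerance (pi*kappa)
    """

    name: str
    kind: str
    params: ModelParams
    sweeps: dict[str, Any] = field(default_factory=dict)
    coexistence_tol: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        self._validate()

    def _validate(self) -> None:
        s = self.sweeps

        def check_param(name: str) -> None:
            if name not in _SWEEPABLE:
                raise ValueError(f"unknown parameter name {name!r} in spec "
                                 f"{self.name!r}")

        def check_grid(grid) -> None:
            grid = list(grid)
            if not grid:
                raise ValueError(f"empty grid in spec {self.name!r}")
            if any(b < a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"grid not sorted in spec {self.name!r}")

        if self.kind == "landscape":
            check_param(s["parameter"])
            check_grid(s["values"])
        elif self.kind == "sweep1d":
            check_param(s["parameter"])
            check_grid(s["grid"])
        elif self.kind == "sweep2d":
            check_param(s["x_axis"])
            check_param(s["y_axis"])
            check_grid(s["x_grid"])
            check_grid(s["y_grid"])
        elif self.kind == "critical":
            if s["search"] not in ("rho", "N"):
                raise ValueError(f"search must be 'rho' or 'N' in {self.name!r}")
        elif self.kind == "critical-curve":
            for curve in s["curves"]:
                if curve["search"] not in ("rho", "N"):
                    raise ValueError(f"search must be 'rho' or 'N' in {self.name!r}")
                check_param(curve["swept_parameter"])
                check_grid(curve["grid"])
                for name in curve.get("base_overrides", {}):
                    check_param(name)

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "kind": self.kind,
            "params": self.params.to_dict(),
            "sweeps": json.loads(json.dumps(self.sweeps)),
        }
        if self.coexistence_tol is not None:
            d["coexistence_tol"] = self.coexistence_tol
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            params=ModelParams.from_dict(d["params"]),
            sweeps=d.get("sweeps", {}),
            coexistence_tol=d.get("coexistence_tol"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def run_experiment(spec: ExperimentSpec, outdir: str | Path) -> Path:
    """Execute a spec into ``outdir/<spec.name>/``; returns that directory."""
    out = Path(outdir) / spec.name
    out.mkdir(parents=True, exist_ok=True)
    s = spec.sweeps

    if spec.kind == "landscape":
        name = s["parameter"]
        summary = {}
        for value in s["values"]:
            tol = spec.coexistence_tol
            ls = scan_landscape(
                with_param(spec.params, name, float(value)),
                auto_extend=True,
                **({"coexistence_tol": tol} if tol is not None else {}),
            )
            tag = f"{name}_{value:g}".replace(".", "p")
            ls.to_csv(out / f"landscape_{tag}.csv")
            summary[f"{value:g}"] = {
                "chi_min": ls.chi_min,
                "F_min": ls.F_min,
                "F0": ls.F0,
                "barrier": ls.barrier,
                "state": ls.state.value,
            }
        (out / "classification.json").write_text(json.dumps(summary, indent=2) + "\n")
    elif spec.kind == "sweep1d":
        df = sweep_1d(spec.params, s["parameter"], s["grid"])
        units = df.attrs["units"]
        df = df.rename(columns={"value": f"{s['parameter']}_{units}".rstrip("_")})
        df.to_csv(out / "sweep1d.csv", index=False)
    elif spec.kind == "sweep2d":
        pm = sweep_2d(spec.params, s["x_axis"], s["y_axis"], s["x_grid"], s["y_grid"])
        pm.to_csv(out / "phase_map.csv")
        pm.to_json(out / "phase_map.json")
        pm.plot(out / "phase_map.png")
    elif spec.kind == "critical":
        finder = critical_density if s["search"] == "rho" else critical_length
        cp = finder(spec.params, s.get("kind", BINODAL))
        (out / "critical.json").write_text(json.dumps({
            "parameter_name": cp.parameter_name,
            "kind": cp.kind,
            "value": cp.value,
            "bracket": list(cp.bracket),
            "chi_at_transition": cp.chi_at_transition,
        }, indent=2) + "\n")
    elif spec.kind == "critical-curve":
        for curve in s["curves"]:
            p = spec.params
            for name, value in curve.get("base_overrides", {}).items():
                p = with_param(p, name, float(value))
            df = critical_curve(
                p,
                curve.get("kind", BINODAL),
                curve["swept_parameter"],
                curve["grid"],
                search=curve["search"],
            )
            tag = f"{curve['search']}c_vs_{curve['swept_parameter']}"
            df.to_csv(out / f"{tag}.csv", index=False)

    (out / "run_metadata.json").write_text(json.dumps({
        "package": "glycotube",
        "version": __version__,
        "spec": spec.to_dict(),
    }, indent=2) + "\n")
    return out


def _fig4_window(R0: float = 100.0, a: float = 10.0, n: int = 41):
    """Default (Np, N) window for phase diagrams.

    N spans the physiological chain-length range [10, 50].  The chain-count
    axis spans grafting distances from xi = a (monomer-size spacing, densest
    sensible brush) down in density to the mushroom-brush crossover of the
    shortest chains, xi = a*sqrt(N_min): beyond that spacing the chains no
    longer overlap and the brush description itself lapses.
    """
    xi_hi = a * math.sqrt(10.0)
    np_lo = math.pi * R0**2 / xi_hi**2
    np_hi = math.pi * R0**2 / a**2
    return (np.linspace(np_lo, np_hi, n).tolist(),
            np.linspace(10.0, 50.0, n).tolist())


def builtin_scenarios(*, grid_n: int = 41) -> list[ExperimentSpec]:
    """Ready-made experiment specs for the standard analyses.

    fig2a/fig2b : energy-profile families over grafting density / chain length
    fig3a/fig3b : chi_min sweeps showing the discontinuous jump
    fig3cd      : binodal critical density and length vs f, lam, c0
    fig4a-d     : (Np, N) phase maps with the facilitating terms off/on
    """
    base = bare_params()  # kappa=10 kBT, sigma=0.012 kBT/nm^2, lam=c0=f=0
    rho_0064 = with_param(base, "rho", 0.0064)
    np_grid, n_grid = _fig4_window(base.geometry.R0, base.glyco.a, grid_n)

    def facilitated(p: ModelParams, lam=0.0, c0=0.0, f=0.0) -> ModelParams:
        p = with_param(p, "lam", lam)
        p = with_param(p, "c0", c0)
        return with_param(p, "f", f)

    specs = [
        ExperimentSpec(
            name="fig2a", kind="landscape", params=base,
            sweeps={"parameter": "rho",
                    "values": [0.0047, 0.0055, 0.0064, 0.0077, 0.009]},
        ),
        ExperimentSpec(
            name="fig2b", kind="landscape", params=rho_0064,
            sweeps={"parameter": "N", "values": [10, 20, 30, 40, 50]},
        ),
        ExperimentSpec(
            name="fig3a", kind="sweep1d", params=base,
            sweeps={"parameter": "rho",
                    "grid": np.linspace(0.004, 0.010, 61).tolist()},
        ),
        ExperimentSpec(
            name="fig3b", kind="sweep1d", params=rho_0064,
            sweeps={"parameter": "N", "grid": np.linspace(10, 50, 41).tolist()},
        ),
        ExperimentSpec(
            name="fig3cd", kind="critical-curve", params=base,
            sweeps={"curves": [
                {"search": "rho", "kind": BINODAL, "swept_parameter": sp,
                 "grid": grid}
                for sp, grid in [("f", np.linspace(0, 1, 5).tolist()),
                                 ("lam", np.linspace(0, 0.5, 5).tolist()),
                                 ("c0", np.linspace(0, 0.02, 5).tolist())]
            ] + [
                {"search": "N", "kind": BINODAL, "swept_parameter": sp,
                 "grid": grid, "base_overrides": {"rho": 0.0064}}
                for sp, grid in [("f", np.linspace(0, 1, 5).tolist()),
                                 ("lam", np.linspace(0, 0.5, 5).tolist()),
                                 ("c0", np.linspace(0, 0.02, 5).tolist())]
            ]},
        ),
    ]
    fig4_conditions = {
        "fig4a": dict(lam=0.0, c0=0.0, f=0.0),
        "fig4b": dict(lam=0.0, c0=0.0, f=1.0),
        "fig4c": dict(lam=0.5, c0=0.02, f=0.0),
        "fig4d": dict(lam=0.5, c0=0.02, f=1.0),
    }
    for name, cond in fig4_conditions.items():
        specs.append(ExperimentSpec(
            name=name, kind="sweep2d", params=facilitated(base, **cond),
            sweeps={"x_axis": "Np", "y_axis": "N",
                    "x_grid": np_grid, "y_grid": n_grid},
        ))
    return specs
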