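"""Parameter sets for the glycocalyx-membrane composite.

All quantities are carried in a single consistent unit system: lengths in
nanometres and energies in units of the thermal energy kBT.  The bending
rigidity ``kappa`` is therefore a pure number (kBT), the membrane tension
``sigma`` is kBT/nm^2, the line tension ``lam`` is kBT/nm, the spontaneous
curvature ``c0`` is 1/nm and the point force ``f`` is kBT/nm.

The glycocalyx brush is described by the mean grafting distance ``xi`` (nm),
the number of monomers per chain ``N`` (real-valued so that critical chain
lengths can be located by continuous root finding), the monomer size ``a``
(nm) and the monomer excluded volume ``v`` (nm^3, defaulting to ``a**3`` for a
neutral brush).  The grafting density ``rho = 1/xi**2`` (chains per nm^2) is
exposed as a derived quantity and as an alternative constructor, since sweeps
are most naturally phrased in terms of density.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "MembraneParams",
    "GlycocalyxParams",
    "LoadParams",
    "GeometryParams",
    "ModelParams",
    "default_params",
    "load_params",
    "save_params",
    "with_param",
    "PARAM_NAMES",
]


@dataclass(frozen=True)
class MembraneParams:
    """Elastic constants of the lipid bilayer patch.

    kappa : bending rigidity (kBT), > 0
    sigma : membrane tension (kBT/nm^2), >= 0
    lam   : line tension of the brush-domain boundary (kBT/nm), >= 0
    c0    : spontaneous curvature from bilayer asymmetry (1/nm), >= 0
    """

    kappa: float = 10.0
    sigma: float = 0.012
    lam: float = 0.0
    c0: float = 0.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"bending rigidity kappa must be > 0, got {self.kappa}")
        if self.sigma < 0:
            raise ValueError(f"membrane tension sigma must be >= 0, got {self.sigma}")
        if self.lam < 0:
            raise ValueError(f"line tension lam must be >= 0, got {self.lam}")
        if self.c0 < 0:
            raise ValueError(f"spontaneous curvature c0 must be >= 0, got {self.c0}")


@dataclass(frozen=True)
class GlycocalyxParams:
    """Brush parameters of the grafted glycopolymer layer.

    xi : grafting distance (nm), > 0; density rho = 1/xi**2
    N  : monomers per chain (dimensionless real), >= 0
    a  : monomer size (nm), > 0
    v  : excluded volume (nm^3), > 0; None selects the neutral-brush default a**3
    """

    xi: float = 15.0
    N: float = 20.0
    a: float = 10.0
    v: float | None = None

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError(f"grafting distance xi must be > 0, got {self.xi}")
        if self.N < 0:
            raise ValueError(f"monomer count N must be >= 0, got {self.N}")
        if not self.a > 0:
            raise ValueError(f"monomer size a must be > 0, got {self.a}")
        if self.v is None:
            object.__setattr__(self, "v", self.a**3)
        elif not self.v > 0:
            raise ValueError(f"excluded volume v must be > 0, got {self.v}")

    @property
    def rho(self) -> float:
        """Grafting density in chains/nm^2."""
        return 1.0 / self.xi**2

    @classmethod
    def from_density(cls, rho: float, **kwargs: Any) -> "GlycocalyxParams":
        """Construct from a grafting density rho (nm^-2) instead of xi."""
        if not rho > 0:
            raise ValueError(f"grafting density rho must be > 0, got {rho}")
        return cls(xi=1.0 / math.sqrt(rho), **kwargs)


@dataclass(frozen=True)
class LoadParams:
    """External load: vertical point force f (kBT/nm) from the F-actin core."""

    f: float = 0.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError(f"actin force f must be >= 0, got {self.f}")


@dataclass(frozen=True)
class GeometryParams:
    """Patch geometry and shape-parameter scan settings.

    R0      : radius of the flat reference patch (nm); the deformed shapes all
              conserve the area pi*R0**2
    chi_max : upper edge of the chi scan (dimensionless)
    n_grid  : number of chi samples on [0, chi_max]
    """

    R0: float = 100.0
    chi_max: float = 30.0
    n_grid: int = 3001

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError(f"patch radius R0 must be > 0, got {self.R0}")
        if not self.chi_max > 0:
            raise ValueError(f"chi_max must be > 0, got {self.chi_max}")
        if self.n_grid < 3:
            raise ValueError(f"n_grid must be >= 3, got {self.n_grid}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the glycocalyx-membrane system."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    glyco: GlycocalyxParams = field(default_factory=GlycocalyxParams)
    load: LoadParams = field(default_factory=LoadParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def to_dict(self) -> dict[str, float]:
        """Flat key/value view with the canonical parameter names."""
        return {
            "kappa": self.membrane.kappa,
            "sigma": self.membrane.sigma,
            "lam": self.membrane.lam,
            "c0": self.membrane.c0,
            "f": self.load.f,
            "R0": self.geometry.R0,
            "xi": self.glyco.xi,
            "N": self.glyco.N,
            "a": self.glyco.a,
            "v": self.glyco.v,
            "chi_max": self.geometry.chi_max,
            "n_grid": self.geometry.n_grid,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        d = dict(d)
        if "rho" in d:
            if "xi" in d:
                raise ValueError("give either 'rho' or 'xi', not both")
            d["xi"] = 1.0 / math.sqrt(float(d.pop("rho")))
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        mem = {k: float(d[k]) for k in ("kappa", "sigma", "lam", "c0") if k in d}
        gly = {k: float(d[k]) for k in ("xi", "N", "a", "v") if k in d}
        load = {k: float(d[k]) for k in ("f",) if k in d}
        geo: dict[str, Any] = {k: float(d[k]) for k in ("R0", "chi_max") if k in d}
        if "n_grid" in d:
            geo["n_grid"] = int(d["n_grid"])
        return cls(
            membrane=MembraneParams(**mem),
            glyco=GlycocalyxParams(**gly),
            load=LoadParams(**load),
            geometry=GeometryParams(**geo),
        )


#: Canonical flat config keys (Table-style parameter names plus scan plumbing).
PARAM_NAMES = (
    "kappa",
    "sigma",
    "lam",
    "c0",
    "f",
    "R0",
    "xi",
    "N",
    "a",
    "v",
    "chi_max",
    "n_grid",
)


def default_params() -> ModelParams:
    """Biologically motivated defaults.

    kappa=10 kBT, sigma=0.012 kBT/nm^2, lam=0.5 kBT/nm, c0=0.02 nm^-1,
    f=1 kBT/nm, R0=100 nm, xi=15 nm, a=10 nm, N=20, v=a^3.
    """
    return ModelParams(
        membrane=MembraneParams(kappa=10.0, sigma=0.012, lam=0.5, c0=0.02),
        glyco=GlycocalyxParams(xi=15.0, N=20.0, a=10.0),
        load=LoadParams(f=1.0),
        geometry=GeometryParams(R0=100.0),
    )


def bare_params() -> ModelParams:
    """Defaults with line tension, spontaneous curvature and force switched off.

    This is the baseline condition used for the density/length landscape
    analyses (kappa=10 kBT, sigma=0.012 kBT/nm^2, lam=c0=f=0).
    """
    return ModelParams(
        membrane=MembraneParams(kappa=10.0, sigma=0.012, lam=0.0, c0=0.0),
        glyco=GlycocalyxParams(xi=15.0, N=20.0, a=10.0),
        load=LoadParams(f=0.0),
        geometry=GeometryParams(R0=100.0),
    )


def with_param(params: ModelParams, name: str, value: float) -> ModelParams:
    """Return a copy of ``params`` with one named parameter replaced.

    Accepts every key of :data:`PARAM_NAMES` plus the derived names ``rho``
    (grafting density, nm^-2) and ``Np`` (total chain count on the patch,
    converted through Np = pi*R0^2/xi^2).
    """
    if name == "rho":
        return with_param(params, "xi", 1.0 / math.sqrt(value))
    if name == "Np":
        if not value > 0:
            raise ValueError(f"chain count Np must be > 0, got {value}")
        xi = params.geometry.R0 * math.sqrt(math.pi / value)
        return with_param(params, "xi", xi)
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter name: {name!r}")
    if name in ("kappa", "sigma", "lam", "c0"):
        membrane = dataclasses.replace(params.membrane, **{name: value})
        return dataclasses.replace(params, membrane=membrane)
    if name in ("xi", "N", "a", "v"):
        glyco = dataclasses.replace(params.glyco, **{name: value})
        return dataclasses.replace(params, glyco=glyco)
    if name == "f":
        return dataclasses.replace(params, load=LoadParams(f=value))
    if name == "n_grid":
        value = int(value)
    geometry = dataclasses.replace(params.geometry, **{name: value})
    return dataclasses.replace(params, geometry=geometry)


def load_params(path: str | Path) -> ModelParams:
    """Read a flat JSON or YAML config file into a :class:`ModelParams`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    return ModelParams.from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write the flat parameter mapping as JSON or YAML (by extension)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
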