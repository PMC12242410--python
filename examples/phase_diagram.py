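"""Phase diagram over chain count and chain length.

Builds a small (Np, N) phase map -- total grafted chains on the patch versus
monomers per chain -- for a bare membrane and for one with actin force, line
tension and spontaneous curvature switched on, and reports how the tubular
region grows.
"""

import numpy as np

from glycotube import bare_params, sweep_2d, with_param

np_grid = np.linspace(40, 314, 13)   # chains on the patch (xi from ~28 to 10 nm)
n_grid = np.linspace(10, 50, 13)     # monomers per chain

base = bare_params()
bare_map = sweep_2d(base, "Np", "N", np_grid, n_grid)

facilitated = with_param(with_param(with_param(base, "lam", 0.5),
                                    "c0", 0.02), "f", 1.0)
fac_map = sweep_2d(facilitated, "Np", "N", np_grid, n_grid)

n_cells = bare_map.tubular_mask().size
print(f"bare membrane:      {bare_map.tubular_mask().sum():3d}/{n_cells} "
      "cells tubular")
print(f"lam, c0, f all on:  {fac_map.tubular_mask().sum():3d}/{n_cells} "
      "cells tubular")

print("\nchi_min along the densest column (Np = %.0f):" % np_grid[-1])
for N, chi in zip(n_grid, bare_map.chi_min_grid[:, -1]):
    print(f"  N = {N:4.0f}: chi_min = {chi:6.2f}")

print("\nDense, long brushes drive long thin tubes (large chi_min); the "
      "facilitating terms enlarge the tubular region toward sparser and "
      "shorter brushes.  Export with PhaseMap.to_csv()/to_json()/plot().")
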