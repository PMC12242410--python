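"""Critical grafting density and chain length of the tubulation transition.

Locates, by bisection on the energy landscape, the binodal (equal basin
energies) and spinodal (first appearance of a tubular minimum) grafting
densities for 20-monomer chains, and the critical chain length at the default
grafting spacing with the facilitating terms (line tension, spontaneous
curvature, actin force) switched on.
"""

from glycotube import (
    BINODAL,
    SPINODAL,
    bare_params,
    critical_density,
    critical_length,
    default_params,
)

base = bare_params()  # kappa=10 kBT, sigma=0.012 kBT/nm^2, lam=c0=f=0, N=20

binodal = critical_density(base, BINODAL)
spinodal = critical_density(base, SPINODAL)
print(f"binodal  rho_c = {binodal.value:.6f} nm^-2  "
      f"(tube appears at chi = {binodal.chi_at_transition:.2f})")
print(f"spinodal rho*  = {spinodal.value:.6f} nm^-2")
print(f"metastable window: {spinodal.value:.4f} .. {binodal.value:.4f} nm^-2")

nc = critical_length(default_params(), BINODAL)
print(f"\nwith lam=0.5 kBT/nm, c0=0.02 nm^-1, f=1 kBT/nm at xi=15 nm:")
print(f"binodal chain length N_c = {nc.value:.2f} monomers "
      f"(integer ceiling {nc.value_ceil})")

print("\nAbove rho_c (or N_c) the tubular state is the global free-energy "
      "minimum; between spinodal and binodal it exists but is metastable.")
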