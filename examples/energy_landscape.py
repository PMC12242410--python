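"""Energy landscapes across the tubulation transition.

Scans the total free energy F(chi) of a glycocalyx-coated membrane patch
(kappa=10 kBT, sigma=0.012 kBT/nm^2, N=20 monomers, no line tension,
spontaneous curvature or actin force) at three grafting densities and prints
the minima, the state label and the barrier separating cap from tube.
"""

from glycotube import bare_params, scan_landscape, with_param

params = bare_params()
for rho in (0.0047, 0.0064, 0.009):
    ls = scan_landscape(with_param(params, "rho", rho))
    tub = ls.tubular_minimum()
    print(f"rho = {rho:.4f} nm^-2: state = {ls.state.value}")
    print(f"  F(0) = {ls.F0:8.3f} pi*kappa   chi_min = {ls.chi_min:.3f}")
    if tub is not None:
        print(f"  tubular minimum: chi = {tub[0]:6.3f}, F = {tub[1]:8.3f} pi*kappa"
              f"   barrier = {ls.barrier:.3f} pi*kappa")

print()
print("Below ~0.0048 nm^-2 the profile is monotonic (no tube can form); in "
      "the metastable window a tubular minimum exists above F(0); past the "
      "coexistence density ~0.0076 nm^-2 the tube becomes the global minimum "
      "but still sits behind a positive nucleation barrier.")
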