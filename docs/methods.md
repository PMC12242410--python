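# Methods

## Model

`glycotube` computes the equilibrium shape of a membrane patch coated with a
grafted glycopolymer brush (the glycocalyx) by minimizing a total free energy
over a one-parameter family of shapes. The patch, of fixed area
A0 = πR0², deforms into a cylinder of radius Rt and length Lt closed by a
hemispherical cap of the same radius. The family is indexed by the shape
parameter χ = Lt/Rt; χ = 0 is the hemispherical-cap (nontubular) reference
state, not a flat membrane. Area conservation,
2πRtLt + 2πRt² = πR0², fixes Rt = R0/√(2(1+χ)); the printed
radius relation is taken from this constraint, which is the authoritative
statement of the geometry.

The total energy, normalized by πκ, is

    F(χ) = χRt²(1/Rt − c0)² + Rt²(2/Rt − c0)²        (bending)
         + (σ/κ)(2χ+1)Rt²                            (tension, excess area)
         + 2(λ/κ)Rt                                  (domain line tension)
         − f·Rt(1+χ)/(πκ)                            (work of the actin force)
         + [Np_cap·E_cap(Rt) + Np_tube·E_tube(Rt)]/(πκ)   (brush)

with chain counts Np_cap = 2πRt²/ξ² and Np_tube = 2πRtLt/ξ² set by the
grafting density ρ = 1/ξ².

## Brush free energy on curved substrates

Each chain of N monomers (size a, excluded volume v) is treated at the
Alexander mean-field level: Gaussian stretching with line energy
3/(2a²g) per unit length, where g(r) = dn/dr is the local monomer line
density, plus pairwise monomer repulsion v·c², with c the local
concentration. On a curved substrate the area available to a chain widens
with radial distance, s(r) = ξ²(r/Rt)^p with p = 2 on the spherical cap and
p = 1 on the cylinder. Minimizing the per-chain energy with the monomer
budget ∫g dr = N fixed gives the flat-brush balance g³ = 3s/(va²) applied
locally, an energy density of 9/(2a²g(r)) kBT per unit length, and on
integration the closed forms

    E_cap(Rt)  = (9Rt/2)·Φ·[(1 + (5N/3Rt)·x)^(1/5) − 1]   kBT/chain
    E_tube(Rt) = (9Rt/4)·Φ·[(1 + (4N/3Rt)·x)^(1/2) − 1]   kBT/chain

with x = (va²/3ξ²)^(1/3) (the flat-brush height per monomer, h0 = N·x) and
Φ = 3x/a² = (9v/(a⁴ξ²))^(1/3). The prefactor Φ is fixed by dimensional
analysis (the bracketed factors are pure numbers, so Φ must carry 1/length to
make E an energy); with the neutral-brush default v = a³ it can equivalently
be read as the dimensionless combination (3v/ξa²)^(2/3) evaluated with all
lengths in monomer units. Both expressions converge, as Rt → ∞, to the flat
Alexander brush energy (3N/2)·(3v²/(a²ξ⁴))^(1/3) kBT per chain; curvature
dilutes the brush with height and always lowers the per-chain energy below
this limit, which is the thermodynamic driving force for tubulation. The
closed forms are validated in the test suite against direct numerical
quadrature of the stretching + excluded-volume density.

Only the second virial coefficient is kept (ternary interactions neglected),
chains are neutral and monodisperse, and grafting is laterally uniform.

## Parameters

| name  | meaning                    | units   | default | rationale |
|-------|----------------------------|---------|---------|-----------|
| kappa | bending rigidity           | kBT     | 10      | soft end of the physiological 10–400 kBT range |
| sigma | membrane tension           | kBT/nm² | 0.012   | ≈5·10⁻⁵ N/m, mid physiological range |
| lam   | domain line tension        | kBT/nm  | 0.5     | ≈2 pN, modest phase-boundary cost |
| c0    | spontaneous curvature      | 1/nm    | 0.02    | bilayer-asymmetry scale, tens of nm |
| f     | vertical actin point force | kBT/nm  | 1       | ≈4 pN, single-filament polymerization scale |
| R0    | patch radius               | nm      | 100     | glycocalyx domain / microvillus footprint |
| xi    | grafting distance          | nm      | 15      | mucin spacing; ρ = 1/ξ² ≈ 4.4·10⁻³ nm⁻² |
| N     | monomers per chain         | –       | 20      | mucin tandem-repeat range 10–50 |
| a     | monomer size               | nm      | 10      | glycosylated repeat unit |
| v     | excluded volume            | nm³     | a³      | neutral-brush second virial |

`bare_params()` is the same set with lam = c0 = f = 0 — the baseline for the
density/length analyses, which isolates what the brush alone can do. N is a
non-negative real so that critical chain lengths can be found by continuous
bisection; ξ is the canonical stored parameter, with ρ (and the total chain
count Np = πR0²/ξ²) exposed as derived names in sweeps and configs.

## Numerics

* **Landscape scan.** F(χ) is evaluated vectorized on a uniform grid over
  [0, χ_max] (default χ_max = 30, 3001 points, spacing 0.01). Each interior
  grid minimum is refined by bounded scalar minimization between its
  neighbouring grid points (absolute tolerance 10⁻⁹ in χ); χ = 0 is a
  boundary candidate accepted by the one-sided test F(δ) > F(0). If F is
  still decreasing at the right edge the scan either raises an error asking
  for a larger window or, with `auto_extend=True` (used by all sweep and
  root-finding drivers), doubles χ_max at fixed spacing up to six times.
* **Classification.** The lowest interior minimum F_tub is compared with
  F(0): tubular if F_tub < F(0) − tol, metastable if F_tub > F(0) + tol,
  coexistence within tol = 10⁻³ πκ (two orders below the unit bending scale,
  well above refinement error). A degenerate tie between tubular minima
  reports the smaller χ and logs a warning.
* **Barrier.** ΔF = max F on [0, χ_tub] − F(0), with the interior maximum
  refined the same way; it is non-negative by construction.
* **Critical points.** Both the binodal (F_tub = F(0)) and the spinodal
  (first appearance of an interior minimum) are monotone indicators in ρ and
  in N, so a single boolean bisection locates either: default tolerances
  10⁻⁶ nm⁻² in ρ and 10⁻⁴ monomers in N, initial brackets
  ρ ∈ [10⁻⁴, 10⁻²] nm⁻² (ξ from 100 down to 10 nm) and N ∈ [1, 60],
  auto-expanded once before raising. Both kinds are exposed because "critical
  value" can mean either phenomenon depending on context.
* **Phase maps.** Per-cell landscape scan + classification on rectangular
  grids (default 41×41); coexistence cells count as tubular when extracting
  the phase boundary, which is marked at midpoints of label-changing edges
  with no sub-grid polishing. The pipeline contains no randomness; repeated
  runs are byte-identical.

## Phase-map window

The (Np, N) window used by the builtin phase-map scenarios spans N ∈ [10, 50]
and grafting spacings from ξ = a (densest sensible packing) to
ξ = a√N_min ≈ 31.6 nm, i.e. Np ∈ [πR0²/(a²N_min), πR0²/a²] ≈ [31, 314]
chains. The upper spacing is the mushroom-to-brush crossover of the shortest
chains: beyond it neighbouring chains no longer overlap and the brush energy
used here is not meaningful. The chain-length landscape scenarios fix
ρ = 0.0064 nm⁻² (inside the metastable window of the 20-mer baseline), the
density at which the length dependence is most informative.

## What the analyses show, and their limits

Under the baseline conditions the model produces the signature of a
first-order transition: a monotonic landscape at low density, a metastable
tubular minimum at intermediate density, equal basin energies at the
coexistence (binodal) density, and a discontinuous jump of χ_min from 0 to a
finite tube with a positive nucleation barrier. The acceptance script
recomputes the binodal and spinodal densities of the 20-mer baseline from
scratch by bisection; the test suite further checks that force, line tension
and spontaneous curvature individually never raise the critical density or
length, and only enlarge the tubular region of the phase maps.

These results are statements about the model, not about cells: the shape
family is prescribed (no free-boundary or arclength shape solving), the
glycocalyx is uncharged and laterally uniform, ternary monomer interactions
and membrane–cortex attachment are neglected, and the treatment is purely
equilibrium (the barrier is reported as an energy, with no rate theory on
top). The problem sizes used by the tests and the acceptance script —
3001-point landscape grids, 21×21 acceptance phase maps, 10⁶-point
brute-force verification grids — are the package's default working
resolutions and reproduce each other's results to the stated tolerances.
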