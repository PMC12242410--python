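import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotube import (
    GlycocalyxParams,
    ModelParams,
    brush_energy_cap_per_chain,
    brush_energy_tube_per_chain,
    flat_brush_energy_per_chain,
    flat_brush_height,
    glycocalyx_energy,
    make_geometry,
    mechanical_energy,
    total_energy,
    total_energy_grid,
    with_param,
)

from .oracles import (
    brush_energy_quadrature,
    eq_total_closed_form,
    mechanical_factored_form,
    random_admissible_params,
)

# ---------------------------------------------------------------------------
# mechanical part


def test_bare_hemisphere_bending_is_four_pi_kappa(baseline):
    mech = mechanical_energy(0.0, baseline)
    assert mech.bending == pytest.approx(4.0, rel=1e-12)


def test_tension_term_at_reference_state(baseline):
    # (sigma/kappa) * Rt^2 with Rt^2 = R0^2/2 = 5000 nm^2
    mech = mechanical_energy(0.0, baseline)
    assert mech.tension == pytest.approx(0.0012 * 5000.0, rel=1e-12)


@settings(max_examples=100, derandomize=True)
@given(chi=st.floats(0.0, 50.0), data=st.data())
def test_factored_and_expanded_mechanical_forms_agree(chi, data):
    """The term-by-term mechanical energy equals its expanded polynomial:
    [(chi+1)c0^2 + (sigma/kappa)(2chi+1)]Rt^2 + 2Rt(lam/kappa - chi*c0 - 2c0)
    + chi + 4 - f*Rt*(1+chi)/(pi*kappa)."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    p = random_admissible_params(rng)
    d = p.to_dict()
    mech = mechanical_energy(chi, p)
    total_mech = sum(mech)
    Rt = d["R0"] / math.sqrt(2.0 * (1.0 + chi))
    expanded = (
        ((chi + 1.0) * d["c0"] ** 2 + (d["sigma"] / d["kappa"]) * (2 * chi + 1)) * Rt**2
        + 2.0 * Rt * (d["lam"] / d["kappa"] - chi * d["c0"] - 2.0 * d["c0"])
        + chi + 4.0
        - d["f"] * Rt * (1.0 + chi) / (math.pi * d["kappa"])
    )
    assert total_mech == pytest.approx(expanded, rel=1e-10)
    assert total_mech == pytest.approx(
        float(mechanical_factored_form(chi, d)), rel=1e-12
    )


# ---------------------------------------------------------------------------
# brush energies


def test_brush_energy_vanishes_without_monomers():
    g = GlycocalyxParams(N=0.0)
    assert brush_energy_cap_per_chain(50.0, g) == 0.0
    assert brush_energy_tube_per_chain(50.0, g) == 0.0
    assert flat_brush_energy_per_chain(g) == 0.0


def test_brush_energy_rejects_nonpositive_radius():
    g = GlycocalyxParams()
    with pytest.raises(ValueError):
        brush_energy_cap_per_chain(0.0, g)
    with pytest.raises(ValueError):
        brush_energy_tube_per_chain(-1.0, g)


def test_cap_and_tube_share_the_flat_brush_limit():
    """As Rt -> infinity both grafting geometries flatten out and the
    per-chain energy converges to (3N/2)*(3*v^2/(a^2*xi^4))^(1/3) kBT."""
    g = GlycocalyxParams(xi=15.0, N=20.0, a=10.0)
    flat = flat_brush_energy_per_chain(g)
    assert flat == pytest.approx(
        1.5 * 20.0 * (3.0 * 1000.0**2 / (100.0 * 15.0**4)) ** (1 / 3), rel=1e-12
    )
    Rt = 1e6
    assert brush_energy_cap_per_chain(Rt, g) == pytest.approx(flat, rel=1e-3)
    assert brush_energy_tube_per_chain(Rt, g) == pytest.approx(flat, rel=1e-3)


def test_curvature_relieves_crowding():
    """On a strongly curved substrate the brush dilutes with height, so the
    per-chain energy lies strictly below the flat-brush limit."""
    g = GlycocalyxParams(xi=15.0, N=20.0, a=10.0)
    flat = flat_brush_energy_per_chain(g)
    assert brush_energy_cap_per_chain(50.0, g) < flat
    assert brush_energy_tube_per_chain(50.0, g) < flat
    # and the sphere relieves crowding more than the cylinder
    assert brush_energy_cap_per_chain(50.0, g) < brush_energy_tube_per_chain(50.0, g)


@pytest.mark.parametrize("surface, fn", [
    ("cap", brush_energy_cap_per_chain),
    ("tube", brush_energy_tube_per_chain),
])
@pytest.mark.parametrize("Rt, xi, N, a", [
    (100.0 / math.sqrt(2.0), 15.0, 20.0, 10.0),
    (50.0, 12.5, 35.0, 10.0),
    (30.0, 20.0, 10.0, 8.0),
])
def test_closed_forms_match_quadrature_oracle(surface, fn, Rt, xi, N, a):
    """The closed-form per-chain energies equal a direct numerical
    integration of the stretching + excluded-volume density over the brush."""
    g = GlycocalyxParams(xi=xi, N=N, a=a)
    assert fn(Rt, g) == pytest.approx(
        brush_energy_quadrature(Rt, g, surface), rel=1e-8
    )


def test_flat_brush_height():
    g = GlycocalyxParams(xi=15.0, N=20.0, a=10.0)
    assert flat_brush_height(g) == pytest.approx(
        20.0 * (1000.0 * 100.0 / (3.0 * 225.0)) ** (1 / 3), rel=1e-12
    )


@settings(max_examples=50, derandomize=True)
@given(
    chi=st.floats(0.0, 30.0),
    n1=st.floats(1.0, 30.0),
    dn=st.floats(0.1, 20.0),
    rho1=st.floats(5e-4, 5e-3),
    drho=st.floats(1e-4, 5e-3),
)
def test_brush_patch_energy_monotone_in_length_and_density(chi, n1, dn, rho1, drho):
    base = ModelParams()
    p_n1 = with_param(base, "N", n1)
    p_n2 = with_param(base, "N", n1 + dn)
    cap1, tube1 = glycocalyx_energy(chi, p_n1)
    cap2, tube2 = glycocalyx_energy(chi, p_n2)
    assert cap2 >= cap1 and tube2 >= tube1
    p_r1 = with_param(base, "rho", rho1)
    p_r2 = with_param(base, "rho", rho1 + drho)
    cap1, tube1 = glycocalyx_energy(chi, p_r1)
    cap2, tube2 = glycocalyx_energy(chi, p_r2)
    assert cap2 >= cap1 and tube2 >= tube1


# ---------------------------------------------------------------------------
# total energy


def test_tube_brush_absent_at_chi_zero(baseline):
    cap, tube = glycocalyx_energy(0.0, baseline)
    assert tube == 0.0
    assert cap > 0.0


def test_brush_terms_vanish_at_infinite_spacing(baseline):
    p = with_param(baseline, "xi", 1e6)
    cap, tube = glycocalyx_energy(2.0, p)
    assert cap == pytest.approx(0.0, abs=1e-10)
    assert tube == pytest.approx(0.0, abs=1e-10)


def test_per_chain_times_count_equals_consolidated_block(baseline):
    """Chain-resolved route (per-chain energy x chain count) equals the
    consolidated patch-level brush block, for every chi."""
    for chi in (0.0, 0.5, 2.0, 10.0):
        geom = make_geometry(chi, baseline)
        per_route = (
            geom.Np_cap * brush_energy_cap_per_chain(geom.Rt, baseline.glyco)
            + geom.Np_tube * brush_energy_tube_per_chain(geom.Rt, baseline.glyco)
        ) / (math.pi * baseline.membrane.kappa)
        cap, tube = glycocalyx_energy(chi, baseline)
        assert cap + tube == pytest.approx(per_route, rel=1e-10)


def test_breakdown_components_sum_to_total(baseline):
    bd = total_energy(2.0, baseline)
    assert bd.total == pytest.approx(
        bd.bending + bd.tension + bd.line_tension + bd.force_work
        + bd.glyco_cap + bd.glyco_tube,
        rel=1e-10,
    )
    assert bd.glyco_cap >= 0 and bd.glyco_tube >= 0
    assert bd.total_kBT == pytest.approx(bd.total * math.pi * 10.0, rel=1e-12)


def test_tension_only_reference_energy(baseline):
    """With no brush, line tension, curvature or force, the chi=0 cap costs
    4 (bending) + (sigma/kappa)*R0^2/2 (tension)."""
    p = with_param(baseline, "N", 0.0)
    bd = total_energy(0.0, p)
    expected = 4.0 + (0.012 / 10.0) * 100.0**2 / 2.0
    assert bd.total == pytest.approx(expected, rel=1e-12)


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_total_energy_matches_monolithic_transcription(seed):
    """Component-wise evaluation equals one independent single-expression
    transcription of the full normalized energy, on random admissible
    parameter sets."""
    rng = np.random.default_rng(seed)
    p = random_admissible_params(rng)
    chi = np.linspace(0.0, 30.0, 7)
    ours = total_energy_grid(chi, p)
    oracle = eq_total_closed_form(chi, p.to_dict())
    np.testing.assert_allclose(ours, oracle, rtol=1e-10)


def test_pure_membrane_landscape_is_strictly_increasing(baseline):
    """With brush, line tension, curvature and force all off, stretching the
    patch into a tube only costs energy: dF/dchi = 1 +
    (sigma*R0^2/(2*kappa))/(1+chi)^2 > 0."""
    p = with_param(baseline, "N", 0.0)
    chi = np.linspace(0.0, 30.0, 3001)
    F = total_energy_grid(chi, p)
    assert np.all(np.diff(F) > 0)


@settings(max_examples=40, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), scale=st.floats(0.2, 5.0))
def test_normalized_energy_is_scale_invariant(seed, scale):
    """Scaling all lengths by s (and v by s^3, sigma by 1/s^2, lam by 1/s,
    c0 by 1/s, f by 1/s) leaves the normalized energy unchanged."""
    rng = np.random.default_rng(seed)
    p = random_admissible_params(rng)
    d = p.to_dict()
    s = scale
    scaled = dict(
        d,
        R0=d["R0"] * s, xi=d["xi"] * s, a=d["a"] * s, v=d["v"] * s**3,
        sigma=d["sigma"] / s**2, lam=d["lam"] / s, c0=d["c0"] / s,
        f=d["f"] / s,
    )
    p2 = ModelParams.from_dict({k: scaled[k] for k in
                                ("kappa", "sigma", "lam", "c0", "f", "R0",
                                 "xi", "N", "a", "v")})
    chi = np.linspace(0.0, 20.0, 5)
    np.testing.assert_allclose(
        total_energy_grid(chi, p), total_energy_grid(chi, p2), rtol=1e-9
    )
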