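import numpy as np
import pytest

from glycotube import (
    ChiRangeError,
    Landscape,
    StateLabel,
    classify,
    energy_barrier,
    scan_landscape,
    with_param,
)
from glycotube.landscape import COEXISTENCE_TOL

from .oracles import brute_force_chi_min, random_admissible_params


def test_sparse_brush_landscape_is_nontubular(at_density):
    """At grafting density 0.0047 nm^-2 (N=20, bare membrane terms) the
    profile is monotonic with its only minimum at chi=0."""
    ls = scan_landscape(at_density(0.0047))
    assert ls.state is StateLabel.NONTUBULAR
    assert ls.chi_min == 0.0
    assert ls.tubular_minimum() is None
    assert np.all(np.diff(ls.F_grid) > 0)
    assert ls.barrier is None and energy_barrier(ls) is None


def test_bare_membrane_is_nontubular(baseline):
    ls = scan_landscape(with_param(baseline, "N", 0.0))
    assert ls.state is StateLabel.NONTUBULAR
    assert ls.chi_min == 0.0


def test_dense_brush_landscape_is_tubular_with_barrier(at_density):
    ls = scan_landscape(at_density(0.009))
    assert ls.state is StateLabel.TUBULAR
    tub = ls.tubular_minimum()
    assert tub is not None and tub[1] < ls.F0
    assert ls.chi_min == pytest.approx(tub[0])
    # the cap must climb over a positive barrier to reach the tube
    assert ls.barrier > 0
    assert ls.barrier >= tub[1] - ls.F0
    assert 0 < ls.barrier_chi < tub[0]


def test_metastable_window_between_spinodal_and_binodal(at_density):
    ls = scan_landscape(at_density(0.006))
    assert ls.state is StateLabel.METASTABLE_TUBULAR
    tub = ls.tubular_minimum()
    assert tub[1] > ls.F0
    assert ls.chi_min == 0.0


def test_right_edge_truncation_raises(at_density):
    p = with_param(at_density(0.009), "chi_max", 5.0)
    with pytest.raises(ChiRangeError, match="chi_max"):
        scan_landscape(p)
    # auto_extend recovers the full basin instead
    ls = scan_landscape(p, auto_extend=True)
    assert ls.state is StateLabel.TUBULAR
    assert ls.chi_min == pytest.approx(scan_landscape(at_density(0.009)).chi_min,
                                       abs=1e-4)


def test_refined_minima_match_brute_force_grid(at_density):
    """Grid scan + bounded refinement reproduces an exhaustive 10^6-point
    argmin to |dchi| < 1e-4, across the transition region."""
    for rho in (0.0047, 0.006, 0.0077, 0.009):
        ls = scan_landscape(at_density(rho))
        chi_bf, F_bf = brute_force_chi_min(at_density(rho), float(ls.chi_grid[-1]))
        assert ls.chi_min == pytest.approx(chi_bf, abs=1e-4)
        assert ls.F_min <= F_bf + 1e-10


def test_brute_force_agreement_on_random_parameter_sets():
    rng = np.random.default_rng(20241201)
    for _ in range(10):
        p = random_admissible_params(rng)
        ls = scan_landscape(p, auto_extend=True)
        chi_bf, _ = brute_force_chi_min(p, float(ls.chi_grid[-1]))
        assert ls.chi_min == pytest.approx(chi_bf, abs=1e-4)


def test_classification_invariant_under_grid_refinement(at_density):
    for rho in (0.0047, 0.006, 0.009):
        p = at_density(rho)
        coarse = scan_landscape(p)
        fine = scan_landscape(with_param(p, "n_grid", 2 * p.geometry.n_grid - 1))
        assert coarse.state is fine.state


# ---------------------------------------------------------------------------
# classification and barrier on a constructed double-well landscape


def _synthetic_landscape(chi, F, params):
    """Assemble a Landscape directly from sampled values (no refinement)."""
    F = np.asarray(F, dtype=float)
    minima = []
    if F[1] > F[0]:
        minima.append((float(chi[0]), float(F[0])))
    idx = np.where((F[1:-1] < F[:-2]) & (F[1:-1] <= F[2:]))[0] + 1
    minima += [(float(chi[i]), float(F[i])) for i in idx]
    chi_min, F_min = min(minima, key=lambda m: (m[1], m[0]))
    return Landscape(
        params=params, chi_grid=np.asarray(chi), F_grid=F,
        minima=tuple(minima), chi_min=chi_min, F_min=F_min,
        barrier=None, barrier_chi=None, state=StateLabel.NONTUBULAR,
    )


@pytest.mark.parametrize(
    "offset, expected",
    [
        (0.0, StateLabel.COEXISTENCE),
        (0.5 * COEXISTENCE_TOL, StateLabel.COEXISTENCE),
        (10.0 * COEXISTENCE_TOL, StateLabel.METASTABLE_TUBULAR),
        (-10.0 * COEXISTENCE_TOL, StateLabel.TUBULAR),
    ],
)
def test_classify_double_well_against_offset(baseline, offset, expected):
    chi = np.linspace(0.0, 10.0, 2001)
    # double well: boundary minimum (0, 0), tubular minimum near chi=2 at
    # height `offset`, separated by a hump of height 2
    F = 2.0 - 2.0 * np.exp(-((chi - 2.0) ** 2) / 0.1) + offset * (chi > 1.0)
    F[0] = 0.0
    F[1] = 0.5  # one-sided boundary minimum at chi=0
    ls = _synthetic_landscape(chi, F, baseline)
    assert classify(ls) is expected


def test_single_minimum_classifies_nontubular(baseline):
    chi = np.linspace(0.0, 10.0, 101)
    ls = _synthetic_landscape(chi, chi**2 + 1.0, baseline)
    assert classify(ls) is StateLabel.NONTUBULAR


def test_landscape_export_round_trip(tmp_path, at_density):
    ls = scan_landscape(at_density(0.009))
    csv = tmp_path / "profile.csv"
    sidecar = tmp_path / "profile.json"
    ls.to_csv(csv)
    ls.to_json(sidecar)
    data = np.loadtxt(csv, delimiter=",", skiprows=1)
    np.testing.assert_allclose(data[:, 0], ls.chi_grid)
    np.testing.assert_allclose(data[:, 1], ls.F_grid)
    import json

    meta = json.loads(sidecar.read_text())
    assert meta["state"] == "TUBULAR"
    assert meta["barrier"] == pytest.approx(ls.barrier)
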