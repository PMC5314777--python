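"""Mass-action model construction, integration and steady-state behaviour."""

import numpy as np
import pytest

from capscaffold.kinetics import (
    RateParameterSet,
    ScanResult,
    TotalsConfig,
    abundance_scan,
    build_model,
    rate_control_coefficient,
    simulate_timecourse,
    steady_state,
)

from oracles import rk4_integrate, toy_rhs

TOY_ORDER = ["G()", "R()", "A(free)", "G.A(g)", "G.R.A(gr)", "R.A(r)",
             "S43", "EL", "S40", "PEP"]
TOY_KEYS = ["G", "R", "A", "GA", "GRA", "RA", "S43", "EL", "S40", "PEP"]


def test_state_and_parameter_counts(final_network, shipped_params, shipped_totals):
    model = build_model(final_network, shipped_params, shipped_totals)
    assert model.n_states == 213
    assert shipped_params.n_parameters == 30


def test_toy_rhs_matches_hand_written_odes(toy_network, toy_params, toy_totals):
    """The compiled right-hand side equals explicitly written mass-action ODEs
    for the 10-species one-ligand model, at a random positive state."""
    model = build_model(toy_network, toy_params, toy_totals)
    assert [s.label for s in toy_network.species] == TOY_ORDER
    rng = np.random.default_rng(42)
    x = rng.uniform(10.0, 1_000.0, 10)
    p = {"kon_G": 1e-4, "koff_G": 1.0, "kon_R": 1e-4, "koff_R": 1.0,
         "k_init": 5e-6, "k_elong": 2.0}
    expected = toy_rhs(dict(zip(TOY_KEYS, x)), p)
    got = model.rhs(x)
    assert np.allclose(got, [expected[k] for k in TOY_KEYS], rtol=1e-12)


def test_jacobian_matches_finite_differences(toy_network, toy_params, toy_totals):
    model = build_model(toy_network, toy_params, toy_totals)
    rng = np.random.default_rng(3)
    x = rng.uniform(10.0, 1_000.0, 10)
    J = model.jacobian(x)
    eps = 1e-3
    for j in range(10):
        dx = np.zeros(10)
        dx[j] = eps
        fd = (model.rhs(x + dx) - model.rhs(x - dx)) / (2 * eps)
        assert np.allclose(J[:, j], fd, rtol=1e-6, atol=1e-9)


def test_trajectory_matches_rk4_oracle(toy_network, toy_params, toy_totals):
    """Adaptive stiff integration agrees with a fixed-step RK4 reference."""
    model = build_model(toy_network, toy_params, toy_totals)
    t_end = 5.0
    traj = simulate_timecourse(model, t_end, n_out=2)
    ref = rk4_integrate(model.rhs, model.x0, t_end, dt=5e-4)
    scale = np.abs(ref) + 1.0
    assert np.max(np.abs(traj.x[-1] - ref) / scale) <= 1e-4


def test_conservation_along_trajectory(final_network, shipped_params, shipped_totals):
    model = build_model(final_network, shipped_params, shipped_totals)
    traj = simulate_timecourse(model, 1_000.0, n_out=5)
    totals0 = model.conserved_totals(traj.x[0])
    for x in traj.x:
        assert np.allclose(model.conserved_totals(x), totals0, rtol=1e-6)


def test_zero_timecourse_and_zero_kon(toy_network, toy_params, toy_totals):
    model = build_model(toy_network, toy_params, toy_totals)
    traj = simulate_timecourse(model, 0.0)
    assert np.array_equal(traj.x[0], model.x0)
    frozen = RateParameterSet.symmetric(ligands=("A",), kon=0.0, koff=1.0,
                                        kc=0.0, k_init=0.0)
    m0 = build_model(toy_network, frozen, toy_totals)
    assert np.allclose(m0.rhs(m0.x0), 0.0)


def test_steady_state_flux_identities(toy_network, toy_params, toy_totals):
    model = build_model(toy_network, toy_params, toy_totals)
    ss = steady_state(model)
    assert ss.converged
    assert ss.flux > 0
    assert ss.flux_gap(model) <= 1e-6
    assert ss.amounts.min() >= 0
    # coarse mode lands on the same root
    ss2 = steady_state(model, coarse=True)
    assert np.isclose(ss2.flux, ss.flux, rtol=1e-8)


def test_degenerate_steady_states(toy_network, toy_params):
    no_init = RateParameterSet.from_dict({**toy_params.to_dict(), "k_init": 0.0})
    totals = TotalsConfig(totals={"G": 22_000.0, "R": 60_000.0, "A": 25_000.0})
    ss = steady_state(build_model(toy_network, no_init, totals))
    assert ss.flux == 0.0
    no_mrna = TotalsConfig(totals={"G": 22_000.0, "R": 0.0, "A": 25_000.0})
    ss = steady_state(build_model(toy_network, toy_params, no_mrna))
    assert ss.flux <= 1e-9
    assert np.isclose(ss.amount("A(free)") + ss.amount("G.A(g)"), 25_000.0)


def test_missing_parameter_and_negative_total(toy_network, toy_params):
    incomplete = {k: v for k, v in toy_params.to_dict().items() if k != "k_init"}
    with pytest.raises(TypeError):
        RateParameterSet.from_dict(incomplete)
    with pytest.raises(ValueError, match="negative total"):
        TotalsConfig(totals={"G": -1.0, "R": 1.0, "A": 1.0})


def test_scan_contains_normalized_nominal_point(toy_network, toy_params, toy_totals):
    scan = abundance_scan(toy_network, toy_params, toy_totals, "G", [50.0, 200.0])
    i = list(scan.abundance_pct).index(100.0)
    assert scan.flux_pct[i] == 100.0


def test_rate_control_coefficient_limits():
    grid = np.linspace(50, 150, 11)
    flat = ScanResult("G", grid, np.full(11, 100.0), np.ones(11),
                      np.zeros((11, 1)), np.ones(11, dtype=bool))
    assert rate_control_coefficient(flat, 100.0) == pytest.approx(0.0)
    linear = ScanResult("G", grid, grid.copy(), grid / 100,
                        np.zeros((11, 1)), np.ones(11, dtype=bool))
    assert rate_control_coefficient(linear, 100.0) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="outside"):
        rate_control_coefficient(flat, 10.0)


def test_rate_control_vanishes_at_scan_maximum(toy_network, toy_params, toy_totals):
    scan = abundance_scan(toy_network, toy_params, toy_totals, "G",
                          np.linspace(100, 400, 13))
    peak = scan.abundance_pct[int(np.argmax(scan.flux_pct))]
    if scan.abundance_pct[0] < peak < scan.abundance_pct[-1]:
        assert abs(rate_control_coefficient(scan, peak)) <= 0.15
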