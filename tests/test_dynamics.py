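"""Rate laws, RHS assembly, integration, events and conservation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amparcycle.dynamics import (
    CompiledNetwork,
    Scenario,
    apply_scenario,
    evaluate_rate,
    initial_state,
    simulate,
    steady_state,
)
from amparcycle.network import RateLawKind, build_network
from amparcycle.states import PhosphoState, PKC, PKC_ACTIVE
from helpers import naive_rhs


# ---------------------------------------------------------------------------
# single-reaction rate laws
# ---------------------------------------------------------------------------

def _reaction(network, kind):
    for r in network.reactions:
        if r.rate_law.kind is kind:
            return r
    raise AssertionError


def test_zero_substrate_gives_zero_flux(network, default_params):
    for kind in RateLawKind:
        r = _reaction(network, kind)
        assert evaluate_rate(r, {}, default_params) == 0.0


def test_michaelis_menten_half_saturation_identity(network, default_params):
    r = next(x for x in network.reactions
             if x.rate_law.kind is RateLawKind.MICHAELIS_MENTEN)
    law = r.rate_law
    km = default_params[law.km] * default_params.volume
    amounts = {r.reactants[0]: km, law.enzyme: 7.0}
    flux = evaluate_rate(r, amounts, default_params)
    assert flux == pytest.approx(default_params[law.kcat] * 7.0 / 2.0)


def test_michaelis_menten_saturation_limit(network, default_params):
    r = next(x for x in network.reactions
             if x.rate_law.kind is RateLawKind.MICHAELIS_MENTEN)
    law = r.rate_law
    km = default_params[law.km] * default_params.volume
    amounts = {r.reactants[0]: 1e7 * km, law.enzyme: 3.0}
    flux = evaluate_rate(r, amounts, default_params)
    assert flux == pytest.approx(default_params[law.kcat] * 3.0, rel=1e-5)


def test_bimolecular_mass_action_is_volume_corrected(network, default_params):
    r = next(x for x in network.reactions if len(x.reactants) == 2)
    amounts = {r.reactants[0]: 2.0, r.reactants[1]: 5.0}
    flux = evaluate_rate(r, amounts, default_params)
    k = default_params[r.rate_law.k]
    assert flux == pytest.approx(k * 2.0 * 5.0 / default_params.volume)


def test_negative_amount_beyond_tolerance_rejected(network, default_params):
    r = network.reactions[0]
    with pytest.raises(ValueError, match="negative"):
        evaluate_rate(r, {r.reactants[0]: -1e-3}, default_params)


# ---------------------------------------------------------------------------
# assembled RHS vs the brute-force oracle
# ---------------------------------------------------------------------------

@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rhs_matches_naive_oracle_at_random_states(seed):
    params = build_rhs_fixtures.params
    net = build_rhs_fixtures.net
    comp = build_rhs_fixtures.comp
    y = np.random.default_rng(seed).uniform(0.0, 30.0, size=len(net.species))
    np.testing.assert_allclose(comp.rhs(0.0, y), naive_rhs(net, params, y),
                               rtol=1e-12, atol=1e-12)


class build_rhs_fixtures:
    """Module-level cache so the hypothesis test avoids per-example builds."""
    params = None
    net = None
    comp = None


@pytest.fixture(autouse=True, scope="module")
def _fill_rhs_cache(default_params, network):
    build_rhs_fixtures.params = default_params
    build_rhs_fixtures.net = network
    build_rhs_fixtures.comp = CompiledNetwork(network, default_params)
    yield


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_receptor_sum_derivative_is_zero(seed):
    """Receptor-number conservation holds for the RHS by construction."""
    net, comp = build_rhs_fixtures.net, build_rhs_fixtures.comp
    y = np.random.default_rng(seed).uniform(0.0, 50.0, size=len(net.species))
    dy = comp.rhs(0.0, y)
    assert abs(dy[: net.species.n_receptor].sum()) < 1e-10


def test_two_state_subnetwork_matches_analytic_solution(network,
                                                        default_params):
    """An isolated reversible GRIP-binding reaction pair relaxes as the
    closed-form two-state exponential."""
    pair = [r for r in network.reactions
            if r.id in ("r01.u.psd", "r02.u.psd")]
    assert len(pair) == 2
    sub = dataclasses.replace(network, reactions=pair)
    comp = CompiledNetwork(sub, default_params)
    k_on = default_params["k.ampar-grip.on"] * default_params["init.grip"]
    k_off = default_params["k.ampar-grip.off"]
    y0 = np.zeros(len(network.species))
    ia = network.species.index("AMPAR@PSD")
    y0[ia] = 100.0
    from scipy.integrate import solve_ivp
    t_eval = np.linspace(0.0, 600.0, 40)
    sol = solve_ivp(comp.rhs, (0, 600.0), y0, t_eval=t_eval, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    lam = k_on + k_off
    a_eq = 100.0 * k_off / lam
    expected = a_eq + (100.0 - a_eq) * np.exp(-lam * t_eval)
    np.testing.assert_allclose(sol.y[ia], expected, rtol=1e-6, atol=1e-8)


def test_subnetwork_trajectory_matches_rk4_oracle(network, default_params):
    """LSODA on the vectorised RHS agrees with a fixed-step 4th-order
    integrator driving the brute-force scalar-rate oracle (independent
    integration and flux-evaluation paths)."""
    keep = [r for r in network.reactions
            if r.template in (1, 2, 3, 4, 15, 18)
            and network.species.state(r.reactants[0]).phospho
            is PhosphoState.UNPHOS]
    sub = dataclasses.replace(network, reactions=keep)
    comp = CompiledNetwork(sub, default_params)
    y0 = np.zeros(len(network.species))
    y0[network.species.index("AMPAR@PSD")] = 60.0
    y0[network.species.index("AMPAR@endo")] = 40.0

    t_end, dt = 20.0, 1e-3
    y = y0.copy()
    for _ in range(int(t_end / dt)):
        k1 = naive_rhs(sub, default_params, y)
        k2 = naive_rhs(sub, default_params, y + 0.5 * dt * k1)
        k3 = naive_rhs(sub, default_params, y + 0.5 * dt * k2)
        k4 = naive_rhs(sub, default_params, y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    from scipy.integrate import solve_ivp
    sol = solve_ivp(comp.rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    ref = sol.y[:, -1]
    scale = np.max(np.abs(ref))
    assert np.max(np.abs(ref - y)) / scale < 1e-5


# ---------------------------------------------------------------------------
# scenarios, events and full simulations
# ---------------------------------------------------------------------------

def test_apply_scenario_default_is_identity(default_params):
    q, events = apply_scenario(default_params, Scenario())
    assert q.values == default_params.values
    assert events == []


def test_apply_scenario_pp2a_inhibition_scales_amount(default_params):
    q, _ = apply_scenario(default_params, Scenario(pp2a_inhibition=0.6))
    assert q["init.pp2a"] == pytest.approx(default_params["init.pp2a"] * 0.4)


def test_apply_scenario_knockouts_and_blocks(default_params):
    s = Scenario(ptpmeg_present=False, exocytosis_blocked=True,
                 sfk_multiplier=2.5, ez_escape_override=0.02)
    q, _ = apply_scenario(default_params, s)
    assert q["init.ptpmeg"] == 0.0
    assert q["k.exo"] == 0.0
    assert q["init.sfk"] == pytest.approx(default_params["init.sfk"] * 2.5)
    assert q["k.diff.ez-x"] == 0.02


@pytest.mark.parametrize("bad", [
    dict(pp2a_inhibition=1.5),
    dict(pp2a_inhibition=-0.1),
    dict(sfk_multiplier=-1.0),
    dict(t_end=0.0),
    dict(ez_escape_override=-0.5),
])
def test_invalid_scenarios_rejected(bad):
    with pytest.raises(ValueError):
        Scenario(**bad).validate()


def test_conservation_and_nonnegativity_in_simulation(default_params):
    traj = simulate(default_params, Scenario(t_end=1500.0))
    total = traj.receptor_total()
    assert np.max(np.abs(total - 250.0)) / 250.0 < 1e-6
    assert traj.y.min() > -1e-9


def test_pkc_step_transfers_pool_once(default_params):
    traj = simulate(default_params,
                    Scenario(pkc_step_time=200.0, t_end=400.0))
    pkc = traj.amount(PKC)
    act = traj.amount(PKC_ACTIVE)
    i = np.searchsorted(traj.times, 200.0, side="right")
    assert pkc[i - 1] == pytest.approx(default_params["init.pkc"], rel=1e-6)
    assert act[i - 1] == pytest.approx(0.0, abs=1e-9)
    # after the step the pool is fully active and stays active
    assert pkc[i:].max() < 1e-9
    total = pkc + act  # PKC not yet sequestered on PICK1 or receptors
    assert total[0] == pytest.approx(default_params["init.pkc"])


def test_pkc_step_is_idempotent(default_params):
    """Applying the activation step to an already-activated state changes
    nothing: the inactive pool is empty."""
    from amparcycle.protocols import _activate_pkc
    s = Scenario()
    net = build_network(default_params)
    y = initial_state(default_params, net.species)
    once = _activate_pkc(default_params, s, y)
    twice = _activate_pkc(default_params, s, once)
    np.testing.assert_array_equal(once, twice)


def test_y876f_keeps_py_exactly_zero(default_params):
    traj = simulate(default_params,
                    Scenario(y876f=True, pkc_step_time=100.0, t_end=600.0))
    idx = traj.species.receptor_indices(phospho=PhosphoState.P_Y876)
    assert np.abs(traj.y[:, idx]).max() == 0.0


def test_halving_tolerances_leaves_observables_stable(calibrated_params):
    from amparcycle.protocols import ltd_scenario, relative_psd_at
    s = ltd_scenario(pkc_step_time=100.0, t_end=1300.0)
    a = simulate(calibrated_params, s, rtol=1e-8, atol=1e-10)
    b = simulate(calibrated_params, s, rtol=5e-9, atol=5e-11)
    ra, rb = relative_psd_at(a), relative_psd_at(b)
    assert abs(ra - rb) / ra < 1e-3


def test_steady_state_requires_eventless_scenario(default_params):
    with pytest.raises(ValueError, match="pending"):
        steady_state(default_params, Scenario(pkc_step_time=10.0))


def test_steady_state_derivative_below_threshold(basal_state):
    y, comp = basal_state
    assert np.max(np.abs(comp.rhs(0.0, y))) < 1e-6


def test_steady_state_independent_of_initial_binding(calibrated_params,
                                                     basal_state):
    """Burn-in from an all-GRIP-bound start reaches the same basal steady
    state as the canonical all-free start."""
    y_ref, comp = basal_state
    net = build_network(calibrated_params)
    y0 = initial_state(calibrated_params, net.species)
    ia, ib = net.species.index("AMPAR@PSD"), net.species.index("AMPAR-GRIP@PSD")
    ja, jb = net.species.index("AMPAR@endo"), net.species.index("AMPAR-GRIP@endo")
    y0[ib], y0[ia] = y0[ia], 0.0
    y0[jb], y0[ja] = y0[ja], 0.0
    y_alt, _ = steady_state(calibrated_params, Scenario(), y0=y0)
    np.testing.assert_allclose(y_alt, y_ref, rtol=2e-4, atol=1e-4)
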