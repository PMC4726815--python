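"""Named in-silico experiments and their observables."""

import numpy as np
import pytest

from amparcycle.dynamics import Scenario, Trajectory
from amparcycle.protocols import (
    TWENTY_MIN,
    ez_escape_scan,
    internalisation_fraction,
    membrane_flux,
    mobile_fraction,
    phospho_fractions,
    relative_psd_at,
    run_scenario,
    sweep_pp2a,
    sweep_sfk,
)
from amparcycle.states import PhosphoState


def onset_index(traj):
    return int(np.searchsorted(traj.times, traj.scenario.pkc_step_time or 0.0))


def test_unknown_scenario_name_rejected(calibrated_params):
    with pytest.raises(ValueError, match="unknown scenario"):
        run_scenario("nonsense", calibrated_params)


def test_basal_run_is_stable(basal_traj):
    psd = basal_traj.y[:, basal_traj.species.receptor_indices()].sum(axis=1)
    rel_psd = 100.0 * basal_traj.surface() / basal_traj.surface()[0]
    assert np.all(np.abs(rel_psd - 100.0) < 1.0)
    ph = phospho_fractions(basal_traj, "psd")
    assert ph["pS880"].abs().max() < 0.5  # no S880 phosphorylation basally
    assert np.ptp(psd) / psd[0] < 1e-6  # conservation


def test_basal_mobile_fraction_low(basal_traj):
    assert mobile_fraction(basal_traj).max() < 6.0


def test_ltd_expression_and_mobilisation(ltd_traj):
    i0 = onset_index(ltd_traj)
    mob = mobile_fraction(ltd_traj)
    assert relative_psd_at(ltd_traj) < 60.0          # >= 40 % depression
    assert mob[:i0].max() < 6.0                       # basal window quiet
    assert mob[-1] > 2.0 * mob[i0 - 1]                # marked mobilisation
    ph = phospho_fractions(ltd_traj, "psd")
    assert ph["pS880"].iloc[-1] > 5.0                 # pS pool established
    assert ph["pY876"].iloc[-1] < ph["pY876"].iloc[i0 - 1]  # pY declines


def test_phospho_fractions_sum_to_100(ltd_traj):
    ph = phospho_fractions(ltd_traj, "psd")
    total = ph[["unphos", "pS880", "pY876"]].sum(axis=1)
    np.testing.assert_allclose(total, 100.0, atol=1e-6)


def test_ptpmeg_null_blocks_ltd(calibrated_params):
    traj, _ = run_scenario("ltd_ptpmeg_null", calibrated_params)
    assert relative_psd_at(traj) > 90.0               # < 10 % depression
    mob = mobile_fraction(traj)
    assert mob[-1] < 1.5 * mob[onset_index(traj) - 1]  # no mobilisation burst


def test_surface_stable_without_pkc_step(calibrated_params):
    """Whatever the PTPMEG/SFK setting, the surface population stays within
    2 % of baseline when PKC is never activated."""
    for ov in (dict(), dict(ptpmeg_present=False), dict(sfk_multiplier=0.0)):
        traj, _ = run_scenario("basal", calibrated_params, ov)
        surf = traj.surface()
        assert np.max(np.abs(surf / surf[0] - 1.0)) < 0.02


def test_sfk_null_enhances_ltd(calibrated_params, ltd_traj):
    traj, _ = run_scenario("sfk_null", calibrated_params)
    assert relative_psd_at(traj) <= relative_psd_at(ltd_traj)
    ph = phospho_fractions(traj, "psd")
    assert np.abs(ph["pY876"]).max() < 1e-9


def test_y876f_rescue_equals_sfk_null_limit(calibrated_params, ltd_traj):
    """Blocking Y876 phosphorylation rescues LTD in a PTPMEG-null system;
    the rescued response is the SFK-null limit and is as strong as
    wild-type LTD."""
    rescue, _ = run_scenario("y876f_rescue", calibrated_params)
    null, _ = run_scenario("sfk_null", calibrated_params)
    r, n = relative_psd_at(rescue), relative_psd_at(null)
    assert r == pytest.approx(n, abs=1.0)
    assert r < 60.0  # LTD fully expressed despite PTPMEG knockout
    assert abs(r - relative_psd_at(ltd_traj)) < 10.0


def test_internalisation_assay_factorial(calibrated_params):
    base, _ = run_scenario("internalisation_assay", calibrated_params)
    pkc, _ = run_scenario("internalisation_assay", calibrated_params,
                          dict(pkc_active=True, ptpmeg_present=False))
    both, _ = run_scenario("internalisation_assay", calibrated_params,
                           dict(pkc_active=True, ptpmeg_present=True))
    f0 = internalisation_fraction(base)
    f1 = internalisation_fraction(pkc)
    f2 = internalisation_fraction(both)
    assert f0 == pytest.approx(40.0, abs=2.0)
    assert f0 < f1 < f2          # PKC alone a slight boost, PTPMEG gates
    assert f2 > 1.5 * f1         # cooperation is strong


def test_internalisation_fraction_requires_blocked_exocytosis(ltd_traj):
    with pytest.raises(ValueError, match="exocytosis-blocked"):
        internalisation_fraction(ltd_traj)


def test_mobile_fraction_zero_for_all_grip_bound_state(basal_traj):
    y = np.zeros((1, len(basal_traj.species)))
    y[0, basal_traj.species.index("AMPAR-GRIP@PSD")] = 100.0
    synthetic = Trajectory(np.array([0.0]), y, basal_traj.species,
                           basal_traj.compiled, Scenario(), basal_traj.params)
    assert mobile_fraction(synthetic)[0] == 0.0


def test_basal_traffic_carries_only_u_and_py_forms(basal_traj):
    """Basally, unphosphorylated and Y876-phosphorylated receptors recycle
    in both directions at comparable rates; no S880-phosphorylated receptor
    is trafficked (phospho interconversion along the loop means the two
    directions need not balance form-by-form, only in total)."""
    for form in (PhosphoState.UNPHOS, PhosphoState.P_Y876):
        fin = membrane_flux(basal_traj, form, "in")[-1]
        fout = membrane_flux(basal_traj, form, "out")[-1]
        assert fin > 0.0 and fout > 0.0
        assert 0.5 < fin / fout < 2.0
    assert membrane_flux(basal_traj, PhosphoState.P_S880, "in")[-1] < 1e-6


def test_ltd_switches_on_ps_trafficking(ltd_traj):
    """During the LTD steady state the S880-phosphorylated form, absent from
    basal traffic, is trafficked at substantial rates in both directions."""
    ps_in = membrane_flux(ltd_traj, PhosphoState.P_S880, "in")[-1]
    ps_out = membrane_flux(ltd_traj, PhosphoState.P_S880, "out")[-1]
    assert ps_in > 0.05 and ps_out > 0.05


def test_exocytic_flux_zero_when_blocked(calibrated_params):
    traj, _ = run_scenario("internalisation_assay", calibrated_params)
    assert np.abs(membrane_flux(traj, direction="out")).max() == 0.0


def test_pp2a_sweep_monotone(calibrated_params):
    table = sweep_pp2a(calibrated_params)
    remaining = table["relative_psd_20min_pct"].to_numpy()
    assert len(table) == 6
    assert np.all(np.diff(remaining) < 0)  # more inhibition, deeper LTD


def test_pp2a_sweep_60pct_row_equals_ltd_scenario(calibrated_params,
                                                  ltd_traj):
    table = sweep_pp2a(calibrated_params, levels=(0.6,))
    assert table["relative_psd_20min_pct"].iloc[0] == pytest.approx(
        relative_psd_at(ltd_traj), abs=0.1)


def test_sfk_sweep_monotone(calibrated_params):
    table = sweep_sfk(calibrated_params)
    remaining = table["relative_psd_20min_pct"].to_numpy()
    py = table["pY876_pct_psd_20min"].to_numpy()
    assert np.all(np.diff(remaining) > 0)  # SFK limits LTD expression
    assert np.all(np.diff(py) > 0)         # via Y876 phosphorylation
    assert py[0] == pytest.approx(0.0, abs=1e-6)


def test_ez_escape_scan_gates_ltd(calibrated_params):
    table = ez_escape_scan(calibrated_params)
    mag = table["ltd_magnitude_pct"].to_numpy()
    rates = table["k.diff.ez-x"].to_numpy()
    assert np.all(np.diff(mag) <= 1e-6)      # monotone non-increasing
    assert mag[0] == mag.max()               # zero escape: maximal LTD
    fast = mag[rates > 0.01].max()
    slow = mag[rates <= 0.01].min()
    assert fast < slow                       # fast escape degrades LTD
    assert mag[-1] < 0.6 * mag[0]


def test_observable_series_columns(ltd_traj):
    from amparcycle.protocols import observables
    obs = observables(ltd_traj)
    for col in ("psd", "surface", "relative_psd", "mobile_pct",
                "pS880_pct_psd", "pY876_pct_psd", "flux_in", "flux_out"):
        assert col in obs.columns
    i0 = onset_index(ltd_traj)
    assert obs["relative_psd"].iloc[i0] == pytest.approx(100.0, abs=0.2)
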