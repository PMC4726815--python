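"""In-silico experiments and their observables.

Every named protocol follows the same scheme as the published simulation
experiments: the system is first relaxed to the basal steady state of the
scenario's t=0 parameters (the burn-in; receptor distributions are
insensitive to the initial populations), then a 3000-second run is performed
in which PKC is activated by a step function after 1000 seconds of basal
conditions.  Relative readouts are normalised to the PSD (or surface)
population at the instant before the PKC step, and "20 minutes" means 1200 s
after the perturbation onset.

Observables: the PSD and total surface populations, the mobile fraction
(surface receptors not bound to GRIP), per-form phosphorylation fractions,
and windowed endocytic/exocytic membrane fluxes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .dynamics import (
    CompiledNetwork,
    Scenario,
    Trajectory,
    apply_scenario,
    build_network,
    initial_state,
    simulate,
    steady_state,
)
from .parameters import ParameterSet
from .states import (
    MEMBRANE,
    PKC,
    PKC_ACTIVE,
    GRIP_BOUND,
    Location,
    PhosphoState,
)

#: twenty simulated minutes, in seconds
TWENTY_MIN = 1200.0

SCENARIOS = ("basal", "ltd", "ltd_ptpmeg_null", "sfk_null", "sfk_scaled",
             "y876f_rescue", "internalisation_assay", "pp2a_level")

_REGIONS = {
    "psd": frozenset({Location.PSD}),
    "surface": MEMBRANE,
    "all": frozenset(Location),
}


def ltd_scenario(**overrides) -> Scenario:
    """Standard LTD induction: PKC step at 1000 s, 60 % PP2A inhibition
    (applied throughout).

    The 4x high-calcium PICK1 association enters through the PICK1-PKC*
    binding reaction, which only exists once PKC is active, so calcium
    elevation is implicit in the PKC step; pass ``calcium_high=True`` to
    additionally switch the plain PICK1 association rate.
    """
    base = dict(pkc_step_time=1000.0, pp2a_inhibition=0.6, t_end=3000.0)
    base.update(overrides)
    return Scenario(**base)


def burn_in(p: ParameterSet, s: Scenario = Scenario(), **kw) -> np.ndarray:
    """Basal steady state of the scenario's t=0 parameters (no PKC step)."""
    s0 = replace(s, pkc_step_time=None, calcium_high=False, t_end=3000.0)
    y, _ = steady_state(p, s0, **kw)
    return y


def _activate_pkc(p: ParameterSet, s: Scenario, y: np.ndarray) -> np.ndarray:
    """Move the whole PKC pool to its active form in a state vector."""
    q, _ = apply_scenario(p, s)
    net = build_network(q, y876f=s.y876f)
    y = y.copy()
    i_pkc, i_act = net.species.index(PKC), net.species.index(PKC_ACTIVE)
    y[i_act] += y[i_pkc]
    y[i_pkc] = 0.0
    return y


def run_scenario(name: str, p: ParameterSet, overrides: dict | None = None,
                 **sim_kw) -> tuple[Trajectory, pd.DataFrame]:
    """Run a named in-silico experiment; returns (trajectory, observables).

    ``overrides``: scenario-field overrides, plus protocol knobs
    ``sfk_multiplier`` (sfk_scaled), ``pp2a_inhibition`` (pp2a_level) and,
    for the internalisation assay, ``pkc_active`` and ``ptpmeg_present``.
    """
    ov = dict(overrides or {})
    if name == "basal":
        s = Scenario(t_end=ov.pop("t_end", 3000.0), **ov)
    elif name == "ltd":
        s = ltd_scenario(**ov)
    elif name == "ltd_ptpmeg_null":
        s = ltd_scenario(ptpmeg_present=False, **ov)
    elif name == "sfk_null":
        s = ltd_scenario(sfk_multiplier=0.0, **ov)
    elif name == "sfk_scaled":
        s = ltd_scenario(sfk_multiplier=ov.pop("sfk_multiplier", 2.0), **ov)
    elif name == "y876f_rescue":
        s = ltd_scenario(y876f=True, ptpmeg_present=False, **ov)
    elif name == "pp2a_level":
        s = ltd_scenario(pp2a_inhibition=ov.pop("pp2a_inhibition", 0.6), **ov)
    elif name == "internalisation_assay":
        return _internalisation_assay(p, **ov, **sim_kw)
    else:
        raise ValueError(f"unknown scenario name: {name!r} "
                         f"(expected one of {SCENARIOS})")
    y0 = burn_in(p, s)
    traj = simulate(p, s, y0=y0, **sim_kw)
    return traj, observables(traj)


def _internalisation_assay(p: ParameterSet, *, pkc_active: bool = False,
                           ptpmeg_present: bool = True,
                           pp2a_inhibition: float = 0.0,
                           calcium_high: bool = False,
                           t_end: float = TWENTY_MIN,
                           **sim_kw) -> tuple[Trajectory, pd.DataFrame]:
    """Selective exocytosis block from a burnt-in basal state.

    The system is relaxed to the basal steady state (exocytosis active and
    the requested PTPMEG setting), then exocytosis is blocked at t=0 and,
    when ``pkc_active``, the PKC pool is stepped to its active form at t=0.
    PP2A is uninhibited by default in this assay.
    """
    s_pre = Scenario(ptpmeg_present=ptpmeg_present)
    y0 = burn_in(p, s_pre)
    s = Scenario(exocytosis_blocked=True, ptpmeg_present=ptpmeg_present,
                 pp2a_inhibition=pp2a_inhibition, calcium_high=calcium_high,
                 t_end=t_end)
    if pkc_active:
        y0 = _activate_pkc(p, s, y0)
    traj = simulate(p, s, y0=y0, **sim_kw)
    return traj, observables(traj, baseline_time=0.0)


def ltd_steady_state(p: ParameterSet, s: Scenario | None = None, *,
                     deriv_tol: float = 1e-6):
    """Steady state reached during the LTD PKC-activation window.

    Burns in to the scenario's basal steady state, applies the PKC step
    instantaneously, and relaxes the activated system to its steady state.
    Returns ``(state, compiled_network)``.
    """
    from dataclasses import replace as _replace
    from .dynamics import CompiledNetwork, relax_to_steady, _apply_pkc_step
    s = s if s is not None else ltd_scenario()
    y0 = burn_in(p, s, deriv_tol=deriv_tol)
    q, _ = apply_scenario(p, _replace(s, pkc_step_time=None,
                                      calcium_high=False))
    q = _apply_pkc_step(q, s)
    net = build_network(q, y876f=s.y876f)
    comp = CompiledNetwork(net, q)
    y0 = y0.copy()
    i_pkc, i_act = net.species.index(PKC), net.species.index(PKC_ACTIVE)
    y0[i_act] += y0[i_pkc]
    y0[i_pkc] = 0.0
    y = relax_to_steady(comp, y0, deriv_tol=deriv_tol)
    return y, comp


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def _region_sum(traj: Trajectory, locations, *, phospho=None,
                grip_bound=None) -> np.ndarray:
    idx = []
    for i, s in enumerate(traj.species.receptor_states):
        if s.location not in locations:
            continue
        if phospho is not None and s.phospho is not phospho:
            continue
        if grip_bound is not None and (s.binding in GRIP_BOUND) != grip_bound:
            continue
        idx.append(i)
    return traj.group_sum(idx)


def mobile_fraction(traj: Trajectory) -> np.ndarray:
    """% of surface receptors not bound to GRIP (mobile), per time point."""
    surf = traj.surface()
    mobile = _region_sum(traj, MEMBRANE, grip_bound=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(surf > 0, 100.0 * mobile / surf, 0.0)


def phospho_fractions(traj: Trajectory, region: str = "psd") -> pd.DataFrame:
    """% of receptors in the region in each phospho-form (columns sum to 100)."""
    locs = _REGIONS[region]
    total = _region_sum(traj, locs)
    out = {"time": traj.times}
    for ph, col in ((PhosphoState.UNPHOS, "unphos"),
                    (PhosphoState.P_S880, "pS880"),
                    (PhosphoState.P_Y876, "pY876")):
        amt = _region_sum(traj, locs, phospho=ph)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[col] = np.where(total > 0, 100.0 * amt / total, 0.0)
    return pd.DataFrame(out)


def internalisation_fraction(traj: Trajectory, t: float = TWENTY_MIN) -> float:
    """% of the initial surface population internalised by time ``t``.

    Only meaningful when exocytosis is blocked (raises otherwise).
    """
    if not traj.scenario.exocytosis_blocked:
        raise ValueError("internalisation fraction requires an "
                         "exocytosis-blocked trajectory")
    surf = traj.surface()
    i = int(np.searchsorted(traj.times, t, side="left"))
    i = min(i, len(traj.times) - 1)
    return float(100.0 * (1.0 - surf[i] / surf[0]))


def _flux_matrix(traj: Trajectory) -> np.ndarray:
    comp: CompiledNetwork = traj.compiled
    return np.vstack([comp.flux(y) for y in traj.y])


def membrane_flux(traj: Trajectory, form: PhosphoState | None = None,
                  direction: str = "in", window: float = 100.0) -> np.ndarray:
    """Trans-membrane receptor flow (receptors/s), per phospho-form.

    ``direction='in'`` sums the endocytic reactions (EZ -> endosome),
    ``'out'`` the exocytic reaction (endosome -> extra-synaptic membrane).
    The instantaneous reaction fluxes are averaged over a trailing window
    (cumulative extent over the window divided by its length); the endo- and
    exocytosis rate constants are event-independent, so the final-segment
    rates used here are exact for these reactions.
    """
    comp = traj.compiled
    if direction == "in":
        sel = np.isin(comp.templates, (27, 28))
    elif direction == "out":
        sel = comp.templates == 29
    else:
        raise ValueError("direction must be 'in' or 'out'")
    if form is not None:
        sel &= np.array([ph is form for ph in comp._phospho])
    f = _flux_matrix(traj)[:, sel].sum(axis=1)
    t = traj.times
    # trailing-window average of the cumulative extent
    ext = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(t))])
    out = np.empty_like(f)
    for i, ti in enumerate(t):
        j = int(np.searchsorted(t, ti - window, side="left"))
        dt = ti - t[j]
        out[i] = (ext[i] - ext[j]) / dt if dt > 0 else f[i]
    return out


def observables(traj: Trajectory, baseline_time: float | None = None
                ) -> pd.DataFrame:
    """Tidy per-time-point observable table for one trajectory.

    ``baseline_time`` defaults to the PKC step time (or t=0 without a step);
    relative populations are % of the PSD/surface population at that instant.
    """
    if baseline_time is None:
        baseline_time = traj.scenario.pkc_step_time or 0.0
    i0 = int(np.searchsorted(traj.times, baseline_time, side="left"))
    i0 = min(i0, len(traj.times) - 1)
    psd = _region_sum(traj, {Location.PSD})
    surf = traj.surface()
    ph = phospho_fractions(traj, "psd")
    df = pd.DataFrame({
        "time": traj.times,
        "psd": psd,
        "surface": surf,
        "relative_psd": 100.0 * psd / psd[i0],
        "relative_surface": 100.0 * surf / surf[i0],
        "mobile_pct": mobile_fraction(traj),
        "pS880_pct_psd": ph["pS880"].to_numpy(),
        "pY876_pct_psd": ph["pY876"].to_numpy(),
        "flux_in": membrane_flux(traj, direction="in"),
        "flux_out": membrane_flux(traj, direction="out"),
    })
    return df


def relative_psd_at(traj: Trajectory, dt_after_onset: float = TWENTY_MIN,
                    region: str = "psd") -> float:
    """PSD (or surface) population ``dt`` after the perturbation onset, as %
    of the population at the onset instant."""
    onset = traj.scenario.pkc_step_time or 0.0
    pop = (_region_sum(traj, {Location.PSD}) if region == "psd"
           else traj.surface())
    i0 = int(np.searchsorted(traj.times, onset, side="left"))
    i1 = int(np.searchsorted(traj.times, onset + dt_after_onset, side="left"))
    i1 = min(i1, len(traj.times) - 1)
    return float(100.0 * pop[i1] / pop[i0])


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def sweep_pp2a(p: ParameterSet,
               levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0)) -> pd.DataFrame:
    """LTD expression vs PP2A inhibition: one LTD run per inhibition level,
    20-minute relative PSD population per row."""
    rows = []
    for level in levels:
        traj, _ = run_scenario("pp2a_level", p, {"pp2a_inhibition": level})
        rows.append({
            "pp2a_inhibition_pct": 100.0 * level,
            "relative_psd_20min_pct": relative_psd_at(traj),
        })
    return pd.DataFrame(rows)


def sweep_sfk(p: ParameterSet, multipliers=(0.0, 1.0, 2.0, 5.0)) -> pd.DataFrame:
    """LTD expression vs SFK concentration: 20-minute relative PSD population
    and remaining PSD Y876-phosphorylated fraction per multiplier."""
    rows = []
    for m in multipliers:
        traj, _ = run_scenario("ltd", p, {"sfk_multiplier": m})
        onset = traj.scenario.pkc_step_time or 0.0
        ph = phospho_fractions(traj, "psd")
        i1 = min(int(np.searchsorted(traj.times, onset + TWENTY_MIN)),
                 len(traj.times) - 1)
        rows.append({
            "sfk_multiplier": m,
            "relative_psd_20min_pct": relative_psd_at(traj),
            "pY876_pct_psd_20min": float(ph["pY876"].iloc[i1]),
        })
    return pd.DataFrame(rows)


def ez_escape_scan(p: ParameterSet,
                   rates=(0.0, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1)) -> pd.DataFrame:
    """LTD magnitude (% depression at 20 min) vs the EZ escape rate
    k.diff.ez-x; LTD is well expressed only at very low escape rates."""
    rows = []
    for rate in rates:
        traj, _ = run_scenario("ltd", p, {"ez_escape_override": rate})
        rows.append({
            "k.diff.ez-x": rate,
            "ltd_magnitude_pct": 100.0 - relative_psd_at(traj),
        })
    return pd.DataFrame(rows)
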