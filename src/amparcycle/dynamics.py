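"""Deterministic stiff-ODE integration of the expanded network.

The state vector holds particle numbers for every dynamic species.  Fluxes
are evaluated in particles/second:

* mass action: ``k x product of reactant amounts``, with bimolecular
  concentration-based constants divided by the compartment volume and
  fixed-pool partners contributing their constant concentration;
* Michaelis-Menten (per substrate species, no competition between
  substrates): ``kcat x E x S / (Km.V + S)``;
* first order (receptor-bound PKC turnover): ``kcat x complex``.

Timed perturbations (the PKC activation step) are handled by
stop-modify-restart: integration halts at the event time, the PKC pool is
transferred to its active form (and the PICK1 association rate switched to
its high-calcium value when requested), rates are recompiled and integration
resumes.  The solver is LSODA with tight tolerances; receptor-number
conservation is checked on every output point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    POOL_CONC,
    RateLawKind,
    Reaction,
    ReactionNetwork,
    build_network,
)
from .parameters import ParameterSet
from .states import MEMBRANE, PKC, PKC_ACTIVE, PP2A, PTPMEG, SFK, SpeciesTable


class IntegrationError(RuntimeError):
    """Integrator failure or conservation-tolerance violation."""


@dataclass(frozen=True)
class Scenario:
    """A perturbation schedule applied on top of a parameter set.

    ``pkc_step_time`` schedules the instantaneous activation of the whole PKC
    pool (the step function used for LTD induction); ``pp2a_inhibition``
    removes that fraction of PP2A from t=0; ``calcium_high`` switches the
    PICK1 association rate to its 4x high-calcium value (from the PKC step
    when one is scheduled, otherwise from t=0).  ``y876f`` removes the
    Y876-phosphorylation reactions (phospho-null mutant), ``ptpmeg_present``
    / ``sfk_multiplier`` scale the phosphatase/kinase amounts, and
    ``exocytosis_blocked`` zeroes the exocytosis rate.
    """

    pkc_step_time: float | None = None
    pp2a_inhibition: float = 0.0
    sfk_multiplier: float = 1.0
    ptpmeg_present: bool = True
    y876f: bool = False
    exocytosis_blocked: bool = False
    calcium_high: bool = False
    ez_escape_override: float | None = None
    t_end: float = 3000.0

    def validate(self) -> None:
        if not 0.0 <= self.pp2a_inhibition <= 1.0:
            raise ValueError("pp2a_inhibition must be in [0, 1]")
        if self.sfk_multiplier < 0:
            raise ValueError("sfk_multiplier must be >= 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.ez_escape_override is not None and self.ez_escape_override < 0:
            raise ValueError("ez_escape_override must be >= 0")
        if self.pkc_step_time is not None and self.pkc_step_time < 0:
            raise ValueError("pkc_step_time must be >= 0")


BASAL = Scenario()


@dataclass(frozen=True)
class Event:
    """A timed perturbation: instantaneous state/parameter modification."""

    time: float
    kind: str  # currently only "pkc_step"


def apply_scenario(p: ParameterSet, s: Scenario) -> tuple[ParameterSet, list[Event]]:
    """Resolve a scenario into a modified parameter set and an event schedule.

    All t=0 perturbations (PP2A removal, SFK scaling, PTPMEG knockout,
    exocytosis block, EZ-escape override, immediate calcium elevation) are
    folded into the returned parameter copy; the PKC step remains a scheduled
    event.  A default scenario returns the parameters unchanged.
    """
    s.validate()
    q = p.copy()
    if s.pp2a_inhibition:
        q.values["init.pp2a"] = p["init.pp2a"] * (1.0 - s.pp2a_inhibition)
    if s.sfk_multiplier != 1.0:
        q.values["init.sfk"] = p["init.sfk"] * s.sfk_multiplier
    if not s.ptpmeg_present:
        q.values["init.ptpmeg"] = 0.0
    if s.exocytosis_blocked:
        q.values["k.exo"] = 0.0
    if s.ez_escape_override is not None:
        q.values["k.diff.ez-x"] = s.ez_escape_override
    events: list[Event] = []
    if s.pkc_step_time is not None:
        events.append(Event(s.pkc_step_time, "pkc_step"))
    elif s.calcium_high:
        q.values["k.ampar-pick.on"] = q["k.ampar-pick.on*"]
    return q, events


def _apply_pkc_step(p: ParameterSet, s: Scenario) -> ParameterSet:
    """Parameter changes accompanying the PKC activation step."""
    q = p.copy()
    q.values["pkc.deact"] = 0.0  # activation held for the whole window
    if s.calcium_high:
        q.values["k.ampar-pick.on"] = q["k.ampar-pick.on*"]
    return q


class CompiledNetwork:
    """Vectorised flux/RHS evaluation for one (network, parameter) pair."""

    def __init__(self, net: ReactionNetwork, p: ParameterSet) -> None:
        self.net = net
        self.species: SpeciesTable = net.species
        self.volume = p.volume
        idx = self.species.index
        n_s, n_r = len(self.species), len(net.reactions)
        self.stoich = np.zeros((n_s, n_r))
        self.i1 = np.zeros(n_r, dtype=np.intp)
        self.i2 = np.full(n_r, -1, dtype=np.intp)
        self.ienz = np.full(n_r, -1, dtype=np.intp)
        self.keff = np.zeros(n_r)
        self.km_v = np.zeros(n_r)  # Km x V, in particles; 0 for non-MM
        self._mm = np.zeros(n_r, dtype=bool)
        self._bi = np.zeros(n_r, dtype=bool)
        for j, r in enumerate(net.reactions):
            for name in r.reactants:
                self.stoich[idx(name), j] -= 1.0
            for name in r.products:
                self.stoich[idx(name), j] += 1.0
            law = r.rate_law
            self.i1[j] = idx(r.reactants[0])
            if law.kind is RateLawKind.MICHAELIS_MENTEN:
                self._mm[j] = True
                self.ienz[j] = idx(law.enzyme)
                self.keff[j] = p[law.kcat]
                self.km_v[j] = p[law.km] * self.volume
            else:
                k = p[law.k]
                for pool in r.pool_reactants:
                    k *= p[POOL_CONC[pool]]
                if len(r.reactants) == 2:
                    self._bi[j] = True
                    self.i2[j] = idx(r.reactants[1])
                    k /= self.volume
                self.keff[j] = k
        self.templates = np.array([r.template for r in net.reactions])
        self._phospho = np.array(
            [self.species.state(r.reactants[0]).phospho
             if self.species.is_receptor(r.reactants[0]) else None
             for r in net.reactions], dtype=object)

    def flux(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction flux (particles/s) at non-negative-clipped state y."""
        yc = np.maximum(y, 0.0)
        f = self.keff * yc[self.i1]
        bi = self._bi
        f[bi] *= yc[self.i2[bi]]
        mm = self._mm
        f[mm] = (self.keff[mm] * yc[self.ienz[mm]] * yc[self.i1[mm]]
                 / (self.km_v[mm] + yc[self.i1[mm]]))
        return f

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.stoich @ self.flux(y)


def evaluate_rate(r: Reaction, amounts: dict[str, float], p: ParameterSet,
                  *, tolerance: float = 1e-9) -> float:
    """Flux (particles/s) of a single reaction at the given species amounts.

    Scalar reference path, independent of the vectorised evaluator.  Amounts
    below ``-tolerance`` are rejected; smaller negatives are clipped to 0.
    """
    V = p.volume

    def amt(name: str) -> float:
        a = amounts.get(name, 0.0)
        if a < -tolerance:
            raise ValueError(f"negative amount for {name}: {a}")
        return max(a, 0.0)

    law = r.rate_law
    if law.kind is RateLawKind.MICHAELIS_MENTEN:
        s = amt(r.reactants[0])
        e = amt(law.enzyme)
        return p[law.kcat] * e * s / (p[law.km] * V + s)
    k = p[law.k]
    for pool in r.pool_reactants:
        k *= p[POOL_CONC[pool]]
    f = k
    for name in r.reactants:
        f *= amt(name)
    if law.kind is RateLawKind.MASS_ACTION and len(r.reactants) == 2:
        f /= V
    return f


def assemble_rhs(net: ReactionNetwork, p: ParameterSet):
    """Derivative function (t, state) -> d(state)/dt for the whole network."""
    return CompiledNetwork(net, p).rhs


def initial_state(p: ParameterSet, species: SpeciesTable) -> np.ndarray:
    """All receptors free and unphosphorylated: the membrane population at
    the PSD, the rest at the endosome; PKC fully inactive."""
    y = np.zeros(len(species))
    y[species.index("AMPAR@PSD")] = p["init.ampar.membrane"]
    y[species.index("AMPAR@endo")] = p["init.ampar.endosome"]
    y[species.index(PKC)] = p["init.pkc"]
    y[species.index(PP2A)] = p["init.pp2a"]
    y[species.index(SFK)] = p["init.sfk"]
    y[species.index(PTPMEG)] = p["init.ptpmeg"]
    return y


@dataclass
class Trajectory:
    """Time-resolved particle numbers for every species of one simulation."""

    times: np.ndarray            # seconds, monotone increasing
    y: np.ndarray                # (n_times, n_species)
    species: SpeciesTable
    compiled: CompiledNetwork    # network/rates of the final segment
    scenario: Scenario
    params: ParameterSet         # post-scenario parameters (final segment)

    def amount(self, name: str) -> np.ndarray:
        return self.y[:, self.species.index(name)]

    def group_sum(self, indices) -> np.ndarray:
        return self.y[:, list(indices)].sum(axis=1)

    def receptor_total(self) -> np.ndarray:
        return self.y[:, : self.species.n_receptor].sum(axis=1)

    def surface(self) -> np.ndarray:
        return self.group_sum(self.species.receptor_indices(locations=MEMBRANE))

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.searchsorted(self.times, t, side="left"))
        i = min(i, len(self.times) - 1)
        return self.y[i]


def simulate(p: ParameterSet, s: Scenario = BASAL, *, y0: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10, grid_dt: float = 1.0,
             conservation_rtol: float = 1e-6) -> Trajectory:
    """Integrate the scenario with LSODA, stopping and restarting at events.

    ``y0`` continues from a previous state (e.g. a burnt-in basal steady
    state); by default the canonical initial populations are used.  Output is
    on a regular grid of spacing ``grid_dt`` (the grid always contains 0 and
    ``t_end``).  Raises :class:`IntegrationError` on solver failure or if the
    total receptor number drifts beyond ``conservation_rtol`` (relative).
    """
    q, events = apply_scenario(p, s)
    net = build_network(q, y876f=s.y876f)
    comp = CompiledNetwork(net, q)
    if y0 is None:
        y = initial_state(q, net.species)
    else:
        y = np.asarray(y0, dtype=float).copy()
        if y.shape != (len(net.species),):
            raise ValueError("y0 has wrong length for this network")

    t_grid = np.arange(0.0, s.t_end + 0.5 * grid_dt, grid_dt)
    if t_grid[-1] < s.t_end:
        t_grid = np.append(t_grid, s.t_end)
    breaks = sorted({e.time for e in events if 0.0 < e.time < s.t_end})
    if breaks:  # event times are always output points
        t_grid = np.unique(np.concatenate([t_grid, np.asarray(breaks)]))
    seg_edges = [0.0] + breaks + [s.t_end]

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    scen_params = q
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        mask = (t_grid >= a) & (t_grid <= b) if not out_t else \
               (t_grid > a) & (t_grid <= b)
        t_eval = t_grid[mask]
        sol = solve_ivp(comp.rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, max_step=np.inf)
        if not sol.success:
            raise IntegrationError(f"LSODA failed on [{a}, {b}]: {sol.message}")
        if sol.t.size:
            out_t.append(sol.t)
            out_y.append(sol.y.T)
        # endpoint state for the next segment (copy: the event modification
        # below must not leak into the recorded output)
        y = sol.y[:, -1].copy() if (sol.t.size and sol.t[-1] == b) else \
            solve_ivp(comp.rhs, (a, b), y, method="LSODA",
                      rtol=rtol, atol=atol).y[:, -1].copy()
        for e in events:
            if e.time == b and e.kind == "pkc_step":
                i_pkc, i_act = net.species.index(PKC), net.species.index(PKC_ACTIVE)
                y[i_act] += y[i_pkc]
                y[i_pkc] = 0.0
                scen_params = _apply_pkc_step(scen_params, s)
                comp = CompiledNetwork(net, scen_params)
    times = np.concatenate(out_t)
    ys = np.vstack(out_y)

    total = ys[:, : net.species.n_receptor].sum(axis=1)
    ref = float(total[0])
    if ref > 0 and np.max(np.abs(total - ref)) > conservation_rtol * ref:
        raise IntegrationError(
            "receptor-number conservation violated: "
            f"max drift {np.max(np.abs(total - ref)) / ref:.2e} relative")
    return Trajectory(times, ys, net.species, comp, s, scen_params)


def relax_to_steady(comp: CompiledNetwork, y0: np.ndarray, *,
                    deriv_tol: float = 1e-6, chunk: float = 2000.0,
                    t_cap: float = 2e5, rtol: float = 1e-8,
                    atol: float = 1e-10) -> np.ndarray:
    """Integrate in chunks until max |dy/dt| < ``deriv_tol`` (particles/s)."""
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    while t < t_cap:
        sol = solve_ivp(comp.rhs, (0.0, chunk), y, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"LSODA failed during relaxation: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(comp.rhs(0.0, y))) < deriv_tol:
            return y
    raise IntegrationError(
        f"no steady state within {t_cap} s "
        f"(max |dy/dt| = {np.max(np.abs(comp.rhs(0.0, y))):.3e})")


def steady_state(p: ParameterSet, s: Scenario = BASAL, *,
                 y0: np.ndarray | None = None, deriv_tol: float = 1e-6,
                 chunk: float = 2000.0, t_cap: float = 2e5,
                 rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate until every species derivative is below ``deriv_tol``.

    The scenario must have no pending events (use the protocol helpers for
    post-step LTD steady states).  Returns ``(state, compiled_network)``.
    """
    if s.pkc_step_time is not None:
        raise ValueError("steady_state requires a scenario without pending "
                         "events; apply the PKC step first")
    q, _ = apply_scenario(p, s)
    net = build_network(q, y876f=s.y876f)
    comp = CompiledNetwork(net, q)
    y = initial_state(q, net.species) if y0 is None else \
        np.asarray(y0, dtype=float).copy()
    y = relax_to_steady(comp, y, deriv_tol=deriv_tol, chunk=chunk,
                        t_cap=t_cap, rtol=rtol, atol=atol)
    return y, comp
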