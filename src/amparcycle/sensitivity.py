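"""Scaled sensitivity of the LTD steady-state membrane population.

For each rate parameter r the scaled sensitivity coefficient

    SSC(r) = (dn/dr) * (r / n)

is estimated by central finite differences at a 1 % relative perturbation,
where n is the steady-state plasma-membrane (surface) AMPAR population
during LTD induction (PSD-only variant available).  The steady state is
re-detected for every perturbed parameter set, including the basal burn-in,
so the coefficient reflects the full operating-point shift.  Perturbing the
PICK1 association rate co-scales its derived 4x high-calcium variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Scenario
from .parameters import ParameterSet
from .protocols import ltd_scenario, ltd_steady_state
from .states import MEMBRANE, Location

#: parameters of the sensitivity table, grouped as in the model's rate table.
#: The PKC activation-switch rates are excluded: during the activation window
#: the pool is fully active and they have no effect.
PARAMETER_CATEGORIES: dict[str, tuple[str, ...]] = {
    "binding": ("k.ampar-grip.on", "k.ampar-grip.off", "k.ampar-grip.offpS",
                "k.ampar-pick.on", "k.ampar-pick.off",
                "k.grip-pick.on", "k.grip-pick.off",
                "k.pick-pkc.on", "k.pick-pkc.off",
                "k.ansf.on", "k.ansf.off"),
    "diffusion": ("k.diff.x-psd", "k.diff.psd-x", "k.diff.x-ez",
                  "k.diff.ez-x"),
    "kinase_phosphatase": ("kcat.ptpmeg", "kcat.pkc", "kcat.pp2a", "kcat.sfk",
                           "km.ptpmeg", "km.pkc", "km.pp2a", "km.sfk"),
    "endo_exo": ("k.endo", "k.exo"),
}


@dataclass
class SensitivityReport:
    """Per-parameter scaled sensitivity coefficients and the reference n."""

    table: pd.DataFrame            # columns: category, parameter, ssc
    n_reference: float             # LTD steady-state membrane population
    rel_step: float
    region: str = "surface"

    def sensitive_parameters(self, threshold: float = 0.1) -> list[str]:
        t = self.table
        return list(t.loc[t["ssc"].abs() > threshold, "parameter"])


def _population(y: np.ndarray, species, region: str) -> float:
    locs = MEMBRANE if region == "surface" else frozenset({Location.PSD})
    return float(y[species.receptor_indices(locations=locs)].sum())


def ltd_steady_population(p: ParameterSet, scenario: Scenario | None = None,
                          region: str = "surface",
                          deriv_tol: float = 1e-5) -> float:
    """Steady-state membrane AMPAR population n during LTD induction."""
    y, comp = ltd_steady_state(p, scenario, deriv_tol=deriv_tol)
    return _population(y, comp.species, region)


def scaled_sensitivity(p: ParameterSet, param_name: str,
                       rel_step: float = 0.01, *,
                       scenario: Scenario | None = None,
                       region: str = "surface",
                       n0: float | None = None) -> float:
    """Central-difference SSC of the LTD membrane population w.r.t. one rate.

    A parameter whose reactions are absent from the scenario (e.g. the
    exocytosis rate with exocytosis blocked, or a zero-valued rate) has no
    influence and returns 0 exactly.
    """
    if p[param_name] == 0.0:
        return 0.0
    if scenario is not None and scenario.exocytosis_blocked \
            and param_name == "k.exo":
        return 0.0
    if n0 is None:
        n0 = ltd_steady_population(p, scenario, region)
    n_hi = ltd_steady_population(p.scaled(param_name, 1.0 + rel_step),
                                 scenario, region)
    n_lo = ltd_steady_population(p.scaled(param_name, 1.0 - rel_step),
                                 scenario, region)
    # (dn/dr)(r/n) with dr = 2 * rel_step * r: the r factors cancel
    return float((n_hi - n_lo) / (2.0 * rel_step * n0))


def sensitivity_table(p: ParameterSet, rel_step: float = 0.01, *,
                      scenario: Scenario | None = None,
                      region: str = "surface") -> SensitivityReport:
    """SSC for every rate parameter, grouped by category."""
    scenario = scenario if scenario is not None else ltd_scenario()
    n0 = ltd_steady_population(p, scenario, region)
    rows = []
    for category, names in PARAMETER_CATEGORIES.items():
        for name in names:
            ssc = scaled_sensitivity(p, name, rel_step, scenario=scenario,
                                     region=region, n0=n0)
            rows.append({"category": category, "parameter": name, "ssc": ssc})
    return SensitivityReport(pd.DataFrame(rows), n0, rel_step, region)
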