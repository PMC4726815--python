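"""Configuration loading and result export.

Parameter files are flat YAML whose keys are exactly the model's rate names
(e.g. ``k.ampar-grip.offpS``) plus the ``init.*`` and ``geometry.*``
namespaces; entries may be plain numbers or ``{value, provenance}`` maps.
Unknown or missing keys are errors that name the offending keys.

Trajectories and tables are written as CSV with a ``#``-prefixed header
block recording the scenario and parameter provenance, in tidy
(time, species, count) or wide (one column per species) layout.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .dynamics import Trajectory
from .parameters import ParameterSet, Provenance
from .protocols import observables


def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter file (errors list unknown/missing keys)."""
    return ParameterSet.from_yaml(path)


def save_parameters(p: ParameterSet, path) -> None:
    p.to_yaml(path)


def default_parameters() -> ParameterSet:
    """The shipped default parameter set."""
    return ParameterSet.default()


def _header_lines(traj: Trajectory) -> list[str]:
    s = traj.scenario
    lines = [f"# scenario: pkc_step_time={s.pkc_step_time} "
             f"pp2a_inhibition={s.pp2a_inhibition} "
             f"sfk_multiplier={s.sfk_multiplier} "
             f"ptpmeg_present={s.ptpmeg_present} y876f={s.y876f} "
             f"exocytosis_blocked={s.exocytosis_blocked} "
             f"calcium_high={s.calcium_high} t_end={s.t_end}"]
    calibrated = sorted(n for n, prov in traj.params.provenance.items()
                        if prov is Provenance.CALIBRATED)
    lines.append("# calibrated parameters: " + (", ".join(calibrated) or "none"))
    return lines


def trajectory_frame(traj: Trajectory, layout: str = "wide") -> pd.DataFrame:
    """Trajectory as a DataFrame; ``layout`` is 'wide' or 'tidy'."""
    wide = pd.DataFrame(traj.y, columns=traj.species.names)
    wide.insert(0, "time", traj.times)
    if layout == "wide":
        return wide
    if layout == "tidy":
        return wide.melt(id_vars="time", var_name="species",
                         value_name="count")
    raise ValueError("layout must be 'wide' or 'tidy'")


def write_trajectory(traj: Trajectory, path, layout: str = "wide") -> None:
    """CSV export with a header block recording scenario and provenance."""
    frame = trajectory_frame(traj, layout)
    with open(path, "w") as fh:
        for line in _header_lines(traj):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_trajectory` (header lines skipped)."""
    return pd.read_csv(path, comment="#")


def write_observables(traj: Trajectory, path) -> None:
    frame = observables(traj)
    with open(path, "w") as fh:
        for line in _header_lines(traj):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def write_table(frame: pd.DataFrame, path, header: list[str] | None = None) -> None:
    """CSV export of a sweep/sensitivity table with optional header lines."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
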