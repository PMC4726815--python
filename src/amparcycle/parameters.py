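"""Named model parameters: rate constants, pools, initial populations, geometry.

Units
-----
Amounts are particle numbers.  The sub-membrane and sub-endosome compartments
have equal volume ``V = depth x area`` (default 1 um^3, from a 120 nm depth),
and concentrations are particles/um^3.  First-order rate constants are s^-1;
bimolecular constants are per-(particles/um^3) per second and are converted to
particle-number propensities through ``V``; Michaelis constants are
particles/um^3.

Every entry carries a provenance label: a shipped default, a value taken from
a published parameter table, or a value produced by the calibration loop.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml


class Provenance(enum.Enum):
    DEFAULT = "default"
    S1_TABLE = "s1_table"
    CALIBRATED = "calibrated"


#: every named rate constant of the reaction table
RATE_NAMES: tuple[str, ...] = (
    "k.ampar-grip.on",
    "k.ampar-grip.off",
    "k.ampar-grip.offpS",
    "k.ampar-pick.on",
    "k.ampar-pick.on*",
    "k.ampar-pick.off",
    "k.grip-pick.on",
    "k.grip-pick.off",
    "k.ansf.on",
    "k.ansf.off",
    "k.diff.psd-x",
    "k.diff.x-psd",
    "k.diff.x-ez",
    "k.diff.ez-x",
    "k.endo",
    "k.exo",
    "pkc.act",
    "pkc.deact",
    "k.pick-pkc.on",
    "k.pick-pkc.off",
    "kcat.pkc",
    "km.pkc",
    "kcat.pp2a",
    "km.pp2a",
    "kcat.sfk",
    "km.sfk",
    "kcat.ptpmeg",
    "km.ptpmeg",
)

#: initial amounts (particles) and fixed pool concentrations (particles/um^3)
INIT_NAMES: tuple[str, ...] = (
    "init.ampar.membrane",
    "init.ampar.endosome",
    "init.pkc",
    "init.pp2a",
    "init.sfk",
    "init.ptpmeg",
    "init.grip",
    "init.pick1",
    "init.nsf",
)

GEOMETRY_NAMES: tuple[str, ...] = ("geometry.depth", "geometry.area")

ALL_NAMES: tuple[str, ...] = RATE_NAMES + INIT_NAMES + GEOMETRY_NAMES

#: Michaelis-Menten constant pairs (kcat, Km) per enzyme
MM_PAIRS = {
    "pkc": ("kcat.pkc", "km.pkc"),
    "pp2a": ("kcat.pp2a", "km.pp2a"),
    "sfk": ("kcat.sfk", "km.sfk"),
    "ptpmeg": ("kcat.ptpmeg", "km.ptpmeg"),
}


@dataclass(frozen=True)
class Compartment:
    """A well-mixed box; sub-membrane boxes extend 120 nm below the membrane."""

    name: str
    depth: float  # um
    area: float  # um^2

    @property
    def volume(self) -> float:  # um^3
        v = self.depth * self.area
        if v <= 0:
            raise ValueError(f"compartment {self.name}: volume must be positive")
        return v


class ParameterError(KeyError):
    """Missing or unknown parameter name."""


@dataclass
class ParameterSet:
    """Complete, validated parameter vector with per-entry provenance."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, Provenance] = field(default_factory=dict)

    # -- access ---------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"missing parameter: {name!r}") from None

    def set(self, name: str, value: float,
            provenance: Provenance = Provenance.DEFAULT) -> None:
        if name not in ALL_NAMES:
            raise ParameterError(f"unknown parameter: {name!r}")
        self.values[name] = float(value)
        self.provenance[name] = provenance

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.provenance))

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        """Copy with one parameter multiplied by ``factor``.

        Scaling ``k.ampar-pick.on`` co-scales the derived high-calcium rate
        ``k.ampar-pick.on*`` so the 4x relation is preserved.
        """
        p = self.copy()
        p.set(name, self[name] * factor, self.provenance.get(name, Provenance.DEFAULT))
        if name == "k.ampar-pick.on":
            p.set("k.ampar-pick.on*", p["k.ampar-pick.on"] * 4.0,
                  self.provenance.get("k.ampar-pick.on*", Provenance.DEFAULT))
        return p

    # -- derived --------------------------------------------------------
    @property
    def volume(self) -> float:
        """Volume (um^3) of each compartment (sub-endosome equals sub-membrane)."""
        return Compartment("sub-membrane", self["geometry.depth"],
                           self["geometry.area"]).volume

    def compartments(self) -> tuple[Compartment, Compartment]:
        d, a = self["geometry.depth"], self["geometry.area"]
        return (Compartment("sub-membrane", d, a), Compartment("sub-endosome", d, a))

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Raise if any entry is missing, negative or inconsistent."""
        missing = [n for n in ALL_NAMES if n not in self.values]
        if missing:
            raise ParameterError("missing parameters: " + ", ".join(missing))
        unknown = [n for n in self.values if n not in ALL_NAMES]
        if unknown:
            raise ParameterError("unknown parameters: " + ", ".join(unknown))
        for n, v in self.values.items():
            if v < 0:
                raise ValueError(f"{n} must be non-negative, got {v}")
        for _, km in MM_PAIRS.values():
            if self[km] <= 0:
                raise ValueError(f"{km} must be positive")
        on, on4 = self["k.ampar-pick.on"], self["k.ampar-pick.on*"]
        if abs(on4 - 4.0 * on) > 1e-9 * max(on4, 1e-30):
            raise ValueError(
                "k.ampar-pick.on* must equal 4 x k.ampar-pick.on "
                f"(got {on4} vs 4 x {on})"
            )
        total = self["init.ampar.membrane"] + self["init.ampar.endosome"]
        if abs(total - 250.0) > 1e-9:
            raise ValueError(f"initial receptor count must total 250, got {total}")
        _ = self.volume  # positivity

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            n: {"value": self.values[n],
                "provenance": self.provenance.get(n, Provenance.DEFAULT).value}
            for n in ALL_NAMES if n in self.values
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        p = cls()
        unknown = [n for n in data if n not in ALL_NAMES]
        if unknown:
            raise ParameterError("unknown parameters: " + ", ".join(sorted(unknown)))
        for name, entry in data.items():
            if isinstance(entry, dict):
                p.set(name, float(entry["value"]),
                      Provenance(entry.get("provenance", "default")))
            else:
                p.set(name, float(entry))
        p.validate()
        return p

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ParameterSet":
        """The shipped default parameter set (see docs/methods.md)."""
        p = cls()
        for name, value in DEFAULTS.items():
            p.set(name, value, Provenance.DEFAULT)
        p.validate()
        return p


def diffusion_rate(diffusion_coefficient: float, area: float) -> float:
    """First-order hop rate (s^-1) out of a membrane region.

    The lateral-diffusion rate constants are primary parameters of the model;
    this helper documents their physical origin as the ratio of the receptor
    diffusion coefficient (um^2/s) to the area (um^2) of the source region,
    for users who wish to recompute them from measured coefficients.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    return diffusion_coefficient / area


# Shipped defaults.  Geometry gives V = 1 um^3 so particle numbers equal
# concentrations; rate magnitudes are literature-anchored (receptor diffusion
# coefficient ~0.1 um^2/s over sub-micron areas, strong GRIP anchoring with a
# ~500-fold off-rate increase for the S880-phosphorylated bond, second-scale
# phospho-turnover).  k.endo, k.exo and kcat.ptpmeg are starting points for
# the calibration loop, which pins them to the basal operating point.
DEFAULTS: dict[str, float] = {
    "k.ampar-grip.on": 1.5e-3,
    "k.ampar-grip.off": 5.0e-3,
    "k.ampar-grip.offpS": 1.0,
    "k.ampar-pick.on": 3.0e-4,
    "k.ampar-pick.on*": 1.2e-3,
    "k.ampar-pick.off": 5.0e-2,
    "k.grip-pick.on": 5.0e-5,
    "k.grip-pick.off": 5.0e-2,
    "k.ansf.on": 1.0e-3,
    "k.ansf.off": 2.0e-2,
    "k.diff.psd-x": 5.0e-2,
    "k.diff.x-psd": 2.0e-1,
    "k.diff.x-ez": 2.0e-1,
    "k.diff.ez-x": 8.0e-3,
    "k.endo": 1.0e-1,
    "k.exo": 1.4e-2,
    "pkc.act": 0.0,
    "pkc.deact": 0.0,
    "k.pick-pkc.on": 5.0e-4,
    "k.pick-pkc.off": 5.0e-2,
    "kcat.pkc": 1.0,
    "km.pkc": 50.0,
    "kcat.pp2a": 2.0,
    "km.pp2a": 50.0,
    "kcat.sfk": 2.0,
    "km.sfk": 500.0,
    "kcat.ptpmeg": 0.32,
    "km.ptpmeg": 10.0,
    "init.ampar.membrane": 125.0,
    "init.ampar.endosome": 125.0,
    "init.pkc": 20.0,
    "init.pp2a": 20.0,
    "init.sfk": 10.0,
    "init.ptpmeg": 10.0,
    "init.grip": 300.0,
    "init.pick1": 200.0,
    "init.nsf": 200.0,
    "geometry.depth": 0.12,
    "geometry.area": 8.3333333333333,
}
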