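"""Legal AMPAR state space.

Every receptor species in the model is a combination of

* a phosphorylation state of the GluA2 C-terminus — unphosphorylated,
  S880-phosphorylated or Y876-phosphorylated.  The two sites are mutually
  exclusive, which is encoded structurally: a receptor carries exactly one
  :class:`PhosphoState`, so a doubly phosphorylated species cannot be written.
* a binding state — free, bound to the scaffold GRIP, to PICK1, to a
  PICK1 molecule carrying active PKC, to tripartite GRIP-PICK1 complexes, or
  to NSF.
* a location — the postsynaptic density (PSD), the extra-synaptic membrane
  (X), the endocytic zone (EZ), or the endosome.

Not every combination is legal: GRIP anchors receptors only at the PSD and
the endosome, and NSF binds receptors only at the endosome.  The predicate
:func:`legal_state` encodes these rules and :func:`enumerate_species` produces
the full, deterministically ordered species list (receptor states followed by
the dynamic enzyme species).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator


class PhosphoState(enum.Enum):
    """GluA2 C-terminal phosphorylation state (S880 and Y876 are exclusive)."""

    UNPHOS = ""
    P_S880 = "pS"
    P_Y876 = "pY"


class BindingState(enum.Enum):
    """Protein partner(s) bound at the GluA2 PDZ ligand (and piggy-backed PKC)."""

    FREE = ""
    GRIP = "GRIP"
    PICK1 = "PICK1"
    PICK1_PKCACT = "PICK1-PKC*"
    GRIP_PICK1 = "GRIP-PICK1"
    GRIP_PICK1_PKCACT = "GRIP-PICK1-PKC*"
    NSF = "NSF"


class Location(enum.Enum):
    """Sub-compartment holding the receptor."""

    PSD = "PSD"
    EXTRASYN = "X"
    EZ = "EZ"
    ENDO = "endo"


#: binding states that contain GRIP (receptor anchored, immobile)
GRIP_BOUND = frozenset(
    {BindingState.GRIP, BindingState.GRIP_PICK1, BindingState.GRIP_PICK1_PKCACT}
)
#: binding states that sequester one active PKC molecule on the receptor
PKC_CARRYING = frozenset({BindingState.PICK1_PKCACT, BindingState.GRIP_PICK1_PKCACT})
#: membrane sub-compartments (the sub-membrane compartment)
MEMBRANE = frozenset({Location.PSD, Location.EXTRASYN, Location.EZ})


@dataclass(frozen=True, order=True)
class ReceptorState:
    """One legal AMPAR complex: phospho-state x binding partner x location."""

    phospho: PhosphoState
    binding: BindingState
    location: Location

    @property
    def name(self) -> str:
        base = "AMPAR" + self.phospho.value
        if self.binding is not BindingState.FREE:
            base += "-" + self.binding.value
        return f"{base}@{self.location.value}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


# Dynamic non-receptor species.  GRIP, PICK1 and NSF are *not* listed here:
# they are modelled as fixed-concentration cytosolic pools (a partner consumed
# by binding is immediately replaced from the bulk cytosol) and therefore
# never enter the state vector.
PKC = "PKC"
PKC_ACTIVE = "PKC*"
PICK1_PKC = "PICK1-PKC*"
PP2A = "PP2A"
SFK = "SFK"
PTPMEG = "PTPMEG"

ENZYME_SPECIES: tuple[str, ...] = (PKC, PKC_ACTIVE, PICK1_PKC, PP2A, SFK, PTPMEG)

#: constant-concentration pools (boundary species)
POOL_SPECIES: tuple[str, ...] = ("GRIP", "PICK1", "NSF")


def legal_state(s: ReceptorState) -> bool:
    """True iff the receptor state satisfies every structural legality rule.

    Rules: GRIP-containing complexes exist only where GRIP populations exist
    (PSD and endosome); NSF-bound receptors exist only at the endosome.
    """
    if s.binding in GRIP_BOUND and s.location not in (Location.PSD, Location.ENDO):
        return False
    if s.binding is BindingState.NSF and s.location is not Location.ENDO:
        return False
    return True


def iter_receptor_states() -> Iterator[ReceptorState]:
    """All legal receptor states in a fixed, deterministic order.

    Ordered by location, then binding state, then phospho-state (enum
    definition order), so the builder output is identical across runs.
    """
    for loc in Location:
        for binding in BindingState:
            for ph in PhosphoState:
                s = ReceptorState(ph, binding, loc)
                if legal_state(s):
                    yield s


class SpeciesTable:
    """Index of every dynamic species in the model.

    Receptor states come first (deterministic order), followed by the enzyme
    species.  Provides name <-> index lookup and a receptor mask used by the
    conservation checks.
    """

    def __init__(self) -> None:
        self.receptor_states: list[ReceptorState] = list(iter_receptor_states())
        self.names: list[str] = [s.name for s in self.receptor_states] + list(
            ENZYME_SPECIES
        )
        self._index = {n: i for i, n in enumerate(self.names)}
        self.n_receptor = len(self.receptor_states)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    def is_receptor(self, name: str) -> bool:
        return self._index[name] < self.n_receptor

    def state(self, name: str) -> ReceptorState:
        i = self._index[name]
        if i >= self.n_receptor:
            raise KeyError(f"{name} is not a receptor species")
        return self.receptor_states[i]

    def receptor_indices(self, *, phospho=None, binding=None, location=None,
                         locations=None) -> list[int]:
        """Indices of receptor species matching the given filters."""
        out = []
        for i, s in enumerate(self.receptor_states):
            if phospho is not None and s.phospho is not phospho:
                continue
            if binding is not None and s.binding is not binding:
                continue
            if location is not None and s.location is not location:
                continue
            if locations is not None and s.location not in locations:
                continue
            out.append(i)
        return out


def enumerate_species() -> list[str]:
    """Names of every legal receptor state plus the dynamic enzyme species."""
    return list(SpeciesTable().names)
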