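"""Expansion of the 57 reaction templates into an elementary reaction network.

The model's reaction table is written over generic species ("AMPAR" meaning
any phospho-form that can participate).  This module expands each template
into elementary reactions over the legal state space:

* GRIP interactions (templates 1, 2, 7-12) occur at the PSD and the
  endosome only, NSF binding (13, 14) at the endosome only, while PICK1
  association/dissociation (3-6) is unrestricted; GRIP association
  (template 1) is abolished for S880-phosphorylated receptors, which
  therefore reach GRIP-bound pS states only by phosphorylation of a
  pre-formed GRIP complex;
* GRIP dissociation (templates 2, 11, 12) uses the enhanced off-rate
  ``k.ampar-grip.offpS`` when the receptor is S880-phosphorylated;
* lateral diffusion (templates 15-26) moves free, PICK1-bound and
  PICK1-PKC*-bound receptors of every phospho-form between PSD,
  extra-synaptic area and endocytic zone;
* endocytosis (27, 28) acts only on PICK1-bound receptors at the EZ;
  exocytosis (29) reinserts NSF-bound endosomal receptors into the
  extra-synaptic membrane, shedding NSF;
* phosphorylation/dephosphorylation (34-57) follows Michaelis-Menten
  kinetics and occurs in every sub-compartment where the substrate exists
  (NSF-bound receptors are never substrates); receptors carrying PICK1-PKC*
  are S880-phosphorylated at the PKC turnover rate (first order, 38/39).

GRIP, PICK1 and NSF are fixed-concentration cytosolic pools; a partner
consumed by binding is immediately replaced from the bulk, so these species
contribute constant concentration factors and never appear in the state
vector.  The PICK1-PKC* complex, by contrast, sequesters a finite PKC
molecule and is dynamic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .parameters import ParameterSet
from .states import (
    BindingState,
    Location,
    PhosphoState,
    PICK1_PKC,
    PKC,
    PKC_ACTIVE,
    PP2A,
    PTPMEG,
    SFK,
    GRIP_BOUND,
    SpeciesTable,
    ReceptorState,
)

PH_ALL = tuple(PhosphoState)
PH_NO_PS = (PhosphoState.UNPHOS, PhosphoState.P_Y876)
BINDING_LOCS = (Location.PSD, Location.ENDO)
MOBILE_BINDINGS = (BindingState.FREE, BindingState.PICK1, BindingState.PICK1_PKCACT)

#: pool name -> parameter holding its fixed concentration
POOL_CONC = {"GRIP": "init.grip", "PICK1": "init.pick1", "NSF": "init.nsf"}


class RateLawKind(enum.Enum):
    MASS_ACTION = "mass_action"
    MICHAELIS_MENTEN = "michaelis_menten"
    FIRST_ORDER = "first_order"


@dataclass(frozen=True)
class RateLaw:
    """Kinetic law of one elementary reaction, referencing parameter names."""

    kind: RateLawKind
    k: str | None = None          # mass-action / first-order rate constant
    kcat: str | None = None       # MM turnover
    km: str | None = None         # MM Michaelis constant
    enzyme: str | None = None     # dynamic enzyme species (MM modifier)

    def parameter_names(self) -> tuple[str, ...]:
        if self.kind is RateLawKind.MICHAELIS_MENTEN:
            return (self.kcat, self.km)
        return (self.k,)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction (unit stoichiometry throughout).

    ``reactants``/``products`` are dynamic species; ``pool_reactants``/
    ``pool_products`` are the fixed-concentration pools consumed or released
    (pool reactants multiply the rate by their constant concentration).
    """

    id: str
    template: int
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_law: RateLaw
    pool_reactants: tuple[str, ...] = ()
    pool_products: tuple[str, ...] = ()

    def format(self) -> str:
        lhs = " + ".join(self.reactants + self.pool_reactants) or "(none)"
        rhs = " + ".join(self.products + self.pool_products) or "(none)"
        law = self.rate_law
        if law.kind is RateLawKind.MICHAELIS_MENTEN:
            tag = f"MM[{law.enzyme}]({law.kcat}, {law.km})"
        elif law.kind is RateLawKind.FIRST_ORDER:
            tag = f"first-order({law.k})"
        else:
            tag = f"mass-action({law.k})"
        return f"[{self.template:2d}] {lhs} -> {rhs} @ {tag}"


@dataclass
class ValidationReport:
    """Structural checks over an expanded network (failures reported, not raised)."""

    n_species: int
    n_reactions: int
    receptor_conserved: bool
    pkc_conserved: bool
    illegal_species: list[str] = field(default_factory=list)
    failing_reactions: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (self.receptor_conserved and self.pkc_conserved
                and not self.illegal_species)


@dataclass
class ReactionNetwork:
    """The expanded elementary network over the legal species table."""

    species: SpeciesTable
    reactions: list[Reaction]

    def reactions_by_template(self, template: int) -> list[Reaction]:
        return [r for r in self.reactions if r.template == template]

    def parameter_names(self) -> set[str]:
        names: set[str] = set()
        for r in self.reactions:
            names.update(r.rate_law.parameter_names())
            names.update(POOL_CONC[p] for p in r.pool_reactants)
        return names

    def dump(self) -> str:
        """Human-readable elementary-reaction listing (for diffing)."""
        return "\n".join(r.format() for r in self.reactions)


def _rname(s: ReceptorState) -> str:
    return s.name


def build_network(p: ParameterSet, *, y876f: bool = False,
                  ptpmeg_membrane_only: bool = False) -> ReactionNetwork:
    """Expand all reaction templates over the legal state space.

    ``y876f`` removes the Y876-phosphorylation templates (46-51), modelling
    the phospho-null GluA2-Y876F mutant.  ``ptpmeg_membrane_only`` restricts
    Y876 dephosphorylation (52-57) to the sub-membrane compartment.

    Every rate-parameter name used by a template is resolved against ``p`` at
    build time, so a missing entry raises an error naming it.
    """
    table = SpeciesTable()
    rxns: list[Reaction] = []

    def need(*names: str) -> None:
        for n in names:
            p[n]  # raises ParameterError naming the parameter if absent

    def R(ph: PhosphoState, b: BindingState, loc: Location) -> str:
        s = ReceptorState(ph, b, loc)
        name = s.name
        if name not in table:
            raise ValueError(f"illegal expansion request: {name}")
        return name

    def add(template: int, rid: str, reactants, products, law,
            pool_r=(), pool_p=()) -> None:
        rxns.append(Reaction(rid, template, tuple(reactants), tuple(products),
                             law, tuple(pool_r), tuple(pool_p)))

    def mass(k: str) -> RateLaw:
        need(k)
        return RateLaw(RateLawKind.MASS_ACTION, k=k)

    def mm(enzyme: str, kcat: str, km: str) -> RateLaw:
        need(kcat, km)
        return RateLaw(RateLawKind.MICHAELIS_MENTEN, kcat=kcat, km=km,
                       enzyme=enzyme)

    def first(k: str) -> RateLaw:
        need(k)
        return RateLaw(RateLawKind.FIRST_ORDER, k=k)

    loctag = {Location.PSD: "psd", Location.EXTRASYN: "x",
              Location.EZ: "ez", Location.ENDO: "endo"}
    phtag = {PhosphoState.UNPHOS: "u", PhosphoState.P_S880: "pS",
             PhosphoState.P_Y876: "pY"}

    # ---- binding interactions at the PSD and the endosome (1-14) -------
    for loc in BINDING_LOCS:
        lt = loctag[loc]
        # 1: GRIP association, abolished for S880-phosphorylated receptors
        for ph in PH_NO_PS:
            add(1, f"r01.{phtag[ph]}.{lt}",
                [R(ph, BindingState.FREE, loc)],
                [R(ph, BindingState.GRIP, loc)],
                mass("k.ampar-grip.on"), pool_r=("GRIP",))
        # 2: GRIP dissociation, enhanced off-rate for the pS-GRIP bond
        for ph in PH_ALL:
            off = ("k.ampar-grip.offpS" if ph is PhosphoState.P_S880
                   else "k.ampar-grip.off")
            add(2, f"r02.{phtag[ph]}.{lt}",
                [R(ph, BindingState.GRIP, loc)],
                [R(ph, BindingState.FREE, loc)],
                mass(off), pool_p=("GRIP",))
        for ph in PH_ALL:
            pt = phtag[ph]
            # 7/8: PICK1 joins/leaves the GRIP of an anchored receptor
            add(7, f"r07.{pt}.{lt}", [R(ph, BindingState.GRIP, loc)],
                [R(ph, BindingState.GRIP_PICK1, loc)],
                mass("k.grip-pick.on"), pool_r=("PICK1",))
            add(8, f"r08.{pt}.{lt}", [R(ph, BindingState.GRIP_PICK1, loc)],
                [R(ph, BindingState.GRIP, loc)],
                mass("k.grip-pick.off"), pool_p=("PICK1",))
            # 9/10: PICK1-PKC* joins/leaves the GRIP anchor
            add(9, f"r09.{pt}.{lt}",
                [R(ph, BindingState.GRIP, loc), PICK1_PKC],
                [R(ph, BindingState.GRIP_PICK1_PKCACT, loc)],
                mass("k.grip-pick.on"))
            add(10, f"r10.{pt}.{lt}",
                [R(ph, BindingState.GRIP_PICK1_PKCACT, loc)],
                [R(ph, BindingState.GRIP, loc), PICK1_PKC],
                mass("k.grip-pick.off"))
            # 11/12: full tripartite dissociation (GRIP bond breaks;
            # phospho-dependent off-rate mirrors template 2)
            off = ("k.ampar-grip.offpS" if ph is PhosphoState.P_S880
                   else "k.ampar-grip.off")
            add(11, f"r11.{pt}.{lt}", [R(ph, BindingState.GRIP_PICK1, loc)],
                [R(ph, BindingState.FREE, loc)],
                mass(off), pool_p=("GRIP", "PICK1"))
            add(12, f"r12.{pt}.{lt}",
                [R(ph, BindingState.GRIP_PICK1_PKCACT, loc)],
                [R(ph, BindingState.FREE, loc), PICK1_PKC],
                mass(off), pool_p=("GRIP",))
    # 3-6: PICK1 (and PICK1-PKC*) association/dissociation.  PICK1 carries
    # no location restriction (only GRIP and NSF interactions are
    # location-restricted), so these occur in every sub-compartment.
    for loc in Location:
        lt = loctag[loc]
        for ph in PH_ALL:
            pt = phtag[ph]
            add(3, f"r03.{pt}.{lt}", [R(ph, BindingState.FREE, loc)],
                [R(ph, BindingState.PICK1, loc)],
                mass("k.ampar-pick.on"), pool_r=("PICK1",))
            add(4, f"r04.{pt}.{lt}", [R(ph, BindingState.PICK1, loc)],
                [R(ph, BindingState.FREE, loc)],
                mass("k.ampar-pick.off"), pool_p=("PICK1",))
            add(5, f"r05.{pt}.{lt}",
                [R(ph, BindingState.FREE, loc), PICK1_PKC],
                [R(ph, BindingState.PICK1_PKCACT, loc)],
                mass("k.ampar-pick.on*"))
            add(6, f"r06.{pt}.{lt}",
                [R(ph, BindingState.PICK1_PKCACT, loc)],
                [R(ph, BindingState.FREE, loc), PICK1_PKC],
                mass("k.ampar-pick.off"))
    # 13/14: NSF binding, endosome only, any phospho-state
    for ph in PH_ALL:
        pt = phtag[ph]
        add(13, f"r13.{pt}", [R(ph, BindingState.FREE, Location.ENDO)],
            [R(ph, BindingState.NSF, Location.ENDO)],
            mass("k.ansf.on"), pool_r=("NSF",))
        add(14, f"r14.{pt}", [R(ph, BindingState.NSF, Location.ENDO)],
            [R(ph, BindingState.FREE, Location.ENDO)],
            mass("k.ansf.off"), pool_p=("NSF",))

    # ---- lateral diffusion (15-26) -------------------------------------
    hops = (
        (15, Location.PSD, Location.EXTRASYN, "k.diff.psd-x"),
        (18, Location.EXTRASYN, Location.PSD, "k.diff.x-psd"),
        (21, Location.EXTRASYN, Location.EZ, "k.diff.x-ez"),
        (24, Location.EZ, Location.EXTRASYN, "k.diff.ez-x"),
    )
    for base, src, dst, kname in hops:
        for j, b in enumerate(MOBILE_BINDINGS):
            for ph in PH_ALL:
                add(base + j, f"r{base + j:02d}.{phtag[ph]}",
                    [R(ph, b, src)], [R(ph, b, dst)], mass(kname))

    # ---- endocytosis and exocytosis (27-29) -----------------------------
    for ph in PH_ALL:
        pt = phtag[ph]
        add(27, f"r27.{pt}", [R(ph, BindingState.PICK1, Location.EZ)],
            [R(ph, BindingState.PICK1, Location.ENDO)], mass("k.endo"))
        add(28, f"r28.{pt}", [R(ph, BindingState.PICK1_PKCACT, Location.EZ)],
            [R(ph, BindingState.PICK1_PKCACT, Location.ENDO)], mass("k.endo"))
        add(29, f"r29.{pt}", [R(ph, BindingState.NSF, Location.ENDO)],
            [R(ph, BindingState.FREE, Location.EXTRASYN)],
            mass("k.exo"), pool_p=("NSF",))

    # ---- PKC activation switch and PICK1-PKC* complex (30-33) -----------
    add(30, "r30", [PKC], [PKC_ACTIVE], mass("pkc.act"))
    add(31, "r31", [PKC_ACTIVE], [PKC], mass("pkc.deact"))
    add(32, "r32", [PKC_ACTIVE], [PICK1_PKC],
        mass("k.pick-pkc.on"), pool_r=("PICK1",))
    add(33, "r33", [PICK1_PKC], [PKC_ACTIVE],
        mass("k.pick-pkc.off"), pool_p=("PICK1",))

    # ---- phosphorylation / dephosphorylation (34-57) --------------------
    # substrate binding-state order fixed so template numbering is stable
    pkc_templates = (
        (34, BindingState.FREE, False), (35, BindingState.GRIP, False),
        (36, BindingState.PICK1, False), (37, BindingState.GRIP_PICK1, False),
        (38, BindingState.PICK1_PKCACT, True),
        (39, BindingState.GRIP_PICK1_PKCACT, True),
    )
    mm_bindings = (BindingState.FREE, BindingState.GRIP, BindingState.PICK1,
                   BindingState.PICK1_PKCACT, BindingState.GRIP_PICK1,
                   BindingState.GRIP_PICK1_PKCACT)

    def substrate_locations(b: BindingState):
        return BINDING_LOCS if b in GRIP_BOUND else tuple(Location)

    for t, b, first_order in pkc_templates:
        for loc in substrate_locations(b):
            law = (first("kcat.pkc") if first_order
                   else mm(PKC_ACTIVE, "kcat.pkc", "km.pkc"))
            add(t, f"r{t}.{loctag[loc]}",
                [R(PhosphoState.UNPHOS, b, loc)],
                [R(PhosphoState.P_S880, b, loc)], law)
    for j, b in enumerate(mm_bindings):
        t = 40 + j
        for loc in substrate_locations(b):
            add(t, f"r{t}.{loctag[loc]}",
                [R(PhosphoState.P_S880, b, loc)],
                [R(PhosphoState.UNPHOS, b, loc)],
                mm(PP2A, "kcat.pp2a", "km.pp2a"))
    if not y876f:
        for j, b in enumerate(mm_bindings):
            t = 46 + j
            for loc in substrate_locations(b):
                add(t, f"r{t}.{loctag[loc]}",
                    [R(PhosphoState.UNPHOS, b, loc)],
                    [R(PhosphoState.P_Y876, b, loc)],
                    mm(SFK, "kcat.sfk", "km.sfk"))
    for j, b in enumerate(mm_bindings):
        t = 52 + j
        locs = substrate_locations(b)
        if ptpmeg_membrane_only:
            locs = tuple(l for l in locs if l is not Location.ENDO)
        for loc in locs:
            add(t, f"r{t}.{loctag[loc]}",
                [R(PhosphoState.P_Y876, b, loc)],
                [R(PhosphoState.UNPHOS, b, loc)],
                mm(PTPMEG, "kcat.ptpmeg", "km.ptpmeg"))

    return ReactionNetwork(table, rxns)


def _pkc_content(table: SpeciesTable, name: str) -> int:
    """Number of PKC molecules carried by one unit of the species."""
    if name in (PKC, PKC_ACTIVE, PICK1_PKC):
        return 1
    if table.is_receptor(name):
        b = table.state(name).binding
        return 1 if b in (BindingState.PICK1_PKCACT,
                          BindingState.GRIP_PICK1_PKCACT) else 0
    return 0


def validate_network(net: ReactionNetwork) -> ValidationReport:
    """Structural validation: species legality and conservation stoichiometry.

    Checks that every reaction conserves the receptor count (consumes and
    produces exactly one receptor-containing species, or none) and the total
    PKC content, and that every species referenced is a legal model species.
    """
    table = net.species
    illegal: list[str] = []
    failing: list[str] = []
    rec_ok = pkc_ok = True
    for r in net.reactions:
        for name in r.reactants + r.products:
            if name not in table:
                illegal.append(name)
        known_r = [n for n in r.reactants if n in table]
        known_p = [n for n in r.products if n in table]
        nrec_r = sum(table.is_receptor(n) for n in known_r)
        nrec_p = sum(table.is_receptor(n) for n in known_p)
        if nrec_r != nrec_p or nrec_r > 1:
            rec_ok = False
            failing.append(r.id)
        dpkc = (sum(_pkc_content(table, n) for n in known_p)
                - sum(_pkc_content(table, n) for n in known_r))
        if dpkc != 0:
            pkc_ok = False
            if r.id not in failing:
                failing.append(r.id)
    return ValidationReport(
        n_species=len(table), n_reactions=len(net.reactions),
        receptor_conserved=rec_ok, pkc_conserved=pkc_ok,
        illegal_species=sorted(set(illegal)), failing_reactions=failing,
    )
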