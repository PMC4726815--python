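"""SBML Level 3 export and re-import of the expanded network.

The exporter writes one SBML species per model species (fixed GRIP/PICK1/NSF
pools become boundary species), one reaction per elementary reaction, and an
explicit MathML kinetic law per reaction, so the document is self-contained:
a reader needs nothing but the file to reproduce the dynamics.  Receptor and
enzyme species live in the sub-membrane or sub-endosome compartment
according to their location.

The importer parses the document back into an independent runnable model:
kinetic laws are compiled from their MathML (a small arithmetic subset —
times, divide, plus, minus — is sufficient for mass-action and
Michaelis-Menten laws), which makes the re-imported simulator a genuinely
separate evaluation path from the native vectorised one and lets round-trip
trajectory comparisons serve as a cross-check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from lxml import etree
from scipy.integrate import solve_ivp

from .dynamics import CompiledNetwork, initial_state
from .network import POOL_CONC, RateLawKind, ReactionNetwork
from .parameters import ParameterSet
from .states import Location

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SBMLError(ValueError):
    """Malformed or unsupported SBML content."""


def _sid(name: str) -> str:
    """Sanitise a species/parameter name into an SBML SId."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not re.match(r"[A-Za-z_]", s):
        s = "x" + s
    return s


def _species_sid(name: str) -> str:
    return "s_" + _sid(name)


def _param_sid(name: str) -> str:
    return "p_" + _sid(name)


def _compartment_of(net: ReactionNetwork, name: str) -> str:
    if name in net.species and net.species.is_receptor(name):
        loc = net.species.state(name).location
        return "subendosome" if loc is Location.ENDO else "submembrane"
    return "submembrane"


def _math(expr) -> etree._Element:
    """Build a MathML element tree from a nested tuple/str/float expression."""
    M = "{%s}" % MATHML_NS
    if isinstance(expr, tuple):
        op, *args = expr
        apply_ = etree.Element(M + "apply")
        apply_.append(etree.Element(M + op))
        for a in args:
            apply_.append(_math(a))
        return apply_
    if isinstance(expr, str):
        ci = etree.Element(M + "ci")
        ci.text = " " + expr + " "
        return ci
    cn = etree.Element(M + "cn")
    cn.text = " " + repr(float(expr)) + " "
    return cn


def export_sbml(net: ReactionNetwork, p: ParameterSet,
                y0: np.ndarray | None = None) -> bytes:
    """Serialise the network + parameters as an SBML L3V2 document.

    ``y0`` supplies initial amounts (defaults to the canonical initial
    populations).  Returns the document as bytes; write with
    ``Path(...).write_bytes``.
    """
    if y0 is None:
        y0 = initial_state(p, net.species)
    V = p.volume
    S = "{%s}" % SBML_NS
    root = etree.Element(S + "sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, S + "model")
    model.set("id", "ampar_recycling")

    lc = etree.SubElement(model, S + "listOfCompartments")
    for cid in ("submembrane", "subendosome"):
        c = etree.SubElement(lc, S + "compartment")
        c.set("id", cid)
        c.set("size", repr(V))
        c.set("constant", "true")
        c.set("spatialDimensions", "3")

    ls = etree.SubElement(model, S + "listOfSpecies")
    for i, name in enumerate(net.species.names):
        sp = etree.SubElement(ls, S + "species")
        sp.set("id", _species_sid(name))
        sp.set("name", name)
        sp.set("compartment", _compartment_of(net, name))
        sp.set("initialAmount", repr(float(y0[i])))
        sp.set("hasOnlySubstanceUnits", "true")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")
    for pool, conc_param in POOL_CONC.items():
        sp = etree.SubElement(ls, S + "species")
        sp.set("id", _species_sid(pool))
        sp.set("name", pool)
        sp.set("compartment", "submembrane")
        # fixed pools are stored as concentrations; amount = conc x V
        sp.set("initialAmount", repr(p[conc_param] * V))
        sp.set("hasOnlySubstanceUnits", "true")
        sp.set("boundaryCondition", "true")
        sp.set("constant", "true")

    lp = etree.SubElement(model, S + "listOfParameters")
    used = sorted(net.parameter_names())
    for name in used:
        par = etree.SubElement(lp, S + "parameter")
        par.set("id", _param_sid(name))
        par.set("name", name)
        par.set("value", repr(p[name]))
        par.set("constant", "true")

    lr = etree.SubElement(model, S + "listOfReactions")
    for r in net.reactions:
        rx = etree.SubElement(lr, S + "reaction")
        rx.set("id", "r_" + _sid(r.id))
        rx.set("name", r.id)
        rx.set("reversible", "false")
        lre = etree.SubElement(rx, S + "listOfReactants")
        for name in r.reactants + r.pool_reactants:
            ref = etree.SubElement(lre, S + "speciesReference")
            ref.set("species", _species_sid(name))
            ref.set("stoichiometry", "1")
            ref.set("constant", "true")
        lpr = etree.SubElement(rx, S + "listOfProducts")
        for name in r.products + r.pool_products:
            ref = etree.SubElement(lpr, S + "speciesReference")
            ref.set("species", _species_sid(name))
            ref.set("stoichiometry", "1")
            ref.set("constant", "true")
        law = r.rate_law
        if law.kind is RateLawKind.MICHAELIS_MENTEN:
            lm = etree.SubElement(rx, S + "listOfModifiers")
            ref = etree.SubElement(lm, S + "modifierSpeciesReference")
            ref.set("species", _species_sid(law.enzyme))
            sub = _species_sid(r.reactants[0])
            comp = _compartment_of(net, r.reactants[0])
            expr = ("divide",
                    ("times", _param_sid(law.kcat),
                     _species_sid(law.enzyme), sub),
                    ("plus", ("times", _param_sid(law.km), comp), sub))
        else:
            factors = [_param_sid(law.k)]
            factors += [_species_sid(n) for n in r.reactants]
            if law.kind is RateLawKind.MASS_ACTION:
                # fixed pools contribute their concentration (amount / V)
                for pool in r.pool_reactants:
                    factors.append(("divide", _species_sid(pool),
                                    "submembrane"))
                if len(r.reactants) == 2:
                    expr = ("divide", ("times", *factors),
                            _compartment_of(net, r.reactants[0]))
                else:
                    expr = ("times", *factors) if len(factors) > 1 else factors[0]
            else:
                expr = ("times", *factors)
        kl = etree.SubElement(rx, S + "kineticLaw")
        math = etree.SubElement(kl, "{%s}math" % MATHML_NS,
                                nsmap={None: MATHML_NS})
        math.append(_math(expr))

    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

_OPS = {
    "times": lambda args: lambda env: float(np.prod([a(env) for a in args])),
    "plus": lambda args: lambda env: sum(a(env) for a in args),
    "divide": lambda args: lambda env: args[0](env) / args[1](env),
    "minus": lambda args: (lambda env: -args[0](env)) if len(args) == 1
             else (lambda env: args[0](env) - args[1](env)),
}


def _compile_math(node) -> "callable":
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLError("math element must hold one expression")
        return _compile_math(children[0])
    if tag == "ci":
        name = node.text.strip()
        return lambda env: env[name]
    if tag == "cn":
        value = float(node.text.strip())
        return lambda env: value
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        if op not in _OPS:
            raise SBMLError(f"unsupported MathML operator: {op}")
        args = [_compile_math(c) for c in children[1:]]
        return _OPS[op](args)
    raise SBMLError(f"unsupported MathML element: {tag}")


@dataclass
class ImportedReaction:
    id: str
    reactants: list[str]
    products: list[str]
    rate: "callable"


class ImportedModel:
    """An SBML document compiled into an independently runnable ODE model."""

    def __init__(self, doc: bytes | str):
        if isinstance(doc, str):
            doc = doc.encode()
        root = etree.fromstring(doc)
        S = "{%s}" % SBML_NS
        model = root.find(S + "model")
        if model is None:
            raise SBMLError("no <model> element")
        self.env: dict[str, float] = {}
        self.species: list[str] = []       # dynamic species ids, in order
        self.names: dict[str, str] = {}
        self.constant: dict[str, bool] = {}
        for c in model.findall(f"{S}listOfCompartments/{S}compartment"):
            self.env[c.get("id")] = float(c.get("size"))
        for sp in model.findall(f"{S}listOfSpecies/{S}species"):
            sid = sp.get("id")
            self.env[sid] = float(sp.get("initialAmount"))
            self.names[sid] = sp.get("name") or sid
            const = (sp.get("constant") == "true"
                     or sp.get("boundaryCondition") == "true")
            self.constant[sid] = const
            if not const:
                self.species.append(sid)
        for par in model.findall(f"{S}listOfParameters/{S}parameter"):
            self.env[par.get("id")] = float(par.get("value"))
        self.reactions: list[ImportedReaction] = []
        for rx in model.findall(f"{S}listOfReactions/{S}reaction"):
            reactants = [ref.get("species") for ref in
                         rx.findall(f"{S}listOfReactants/{S}speciesReference")]
            products = [ref.get("species") for ref in
                        rx.findall(f"{S}listOfProducts/{S}speciesReference")]
            math = rx.find(f"{S}kineticLaw/{{{MATHML_NS}}}math")
            if math is None:
                raise SBMLError(f"reaction {rx.get('id')} has no kinetic law")
            self.reactions.append(ImportedReaction(
                rx.get("id"), reactants, products, _compile_math(math)))
        self._index = {sid: i for i, sid in enumerate(self.species)}

    @property
    def y0(self) -> np.ndarray:
        return np.array([self.env[s] for s in self.species])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        env = dict(self.env)
        for sid, i in self._index.items():
            env[sid] = max(float(y[i]), 0.0)
        dy = np.zeros_like(y)
        for r in self.reactions:
            f = r.rate(env)
            for s in r.reactants:
                if not self.constant[s]:
                    dy[self._index[s]] -= f
            for s in r.products:
                if not self.constant[s]:
                    dy[self._index[s]] += f
        return dy

    def simulate(self, t_end: float, grid_dt: float = 1.0,
                 rtol: float = 1e-8, atol: float = 1e-10) -> tuple:
        t_eval = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
        sol = solve_ivp(self.rhs, (0.0, t_end), self.y0, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SBMLError(f"integration of imported model failed: "
                            f"{sol.message}")
        return sol.t, sol.y.T

    def amounts_by_name(self, y: np.ndarray) -> dict[str, float]:
        return {self.names[s]: float(y[i]) for s, i in self._index.items()}


def validate_document(doc: bytes) -> None:
    """Light structural validation: parseable, one model, species/reaction
    references resolve, every reaction has a compilable kinetic law."""
    ImportedModel(doc)  # raises SBMLError on any structural problem
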