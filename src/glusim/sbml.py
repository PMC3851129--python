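"""SBML Level 3 export of a reaction network.

The document is built directly as XML (species, compartments, reactions,
kinetic laws as content MathML generated through sympy).  Modification
cycles are exported as explicit kinase/phosphatase reaction pairs; the
gene-expression layer is outside SBML core and is not exported.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import sympy
from sympy.printing.mathml import MathMLContentPrinter


class _PlainSymbolPrinter(MathMLContentPrinter):
    """Content-MathML printer emitting symbol names verbatim (the default
    printer renders trailing ``_X`` as presentation-namespace subscripts,
    which breaks ci/species-id matching)."""

    def _print_Symbol(self, sym):  # noqa: N802 (sympy API)
        ci = self.dom.createElement("ci")
        ci.appendChild(self.dom.createTextNode(sym.name))
        return ci


def mathml(expr) -> str:
    return _PlainSymbolPrinter().doprint(expr)

from .model_core import ConfigurationError, RateLaw, Reaction, ReactionNetwork

__all__ = ["export_sbml", "rate_law_expression"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sym(sid: str) -> sympy.Symbol:
    # species ids may start with digits (13DPG); SBML ids must not
    return sympy.Symbol(_sbml_id(sid))


def _sbml_id(sid: str) -> str:
    clean = sid.replace("-", "_")
    if clean and clean[0].isdigit():
        clean = "_" + clean
    return clean


def rate_law_expression(rxn: Reaction) -> sympy.Expr:
    """Symbolic rate expression of one reaction (same forms as mm_rate)."""
    law = rxn.rate_law
    e = _sym(rxn.catalyst) if rxn.catalyst else sympy.Integer(1)
    reg = sympy.Integer(1)
    for sid, ki, _mode in law.inhibitors:
        reg *= 1 / (1 + _sym(sid) / ki)
    for sid, k in law.modifiers:
        reg *= _sym(sid) / (k + _sym(sid))
    if law.form == "mass_action":
        expr = law.kcat * e
        for sid in law.substrates:
            expr *= _sym(sid)
        return expr * reg
    if law.form == "irreversible_mm":
        expr = law.kcat * e
        for sid in law.substrates:
            s = _sym(sid)
            expr *= s / (law.Km[sid] + s)
        return expr * reg
    if law.form == "reversible_mm":
        fwd = sympy.Integer(1)
        den_s = sympy.Integer(1)
        km_s = sympy.Integer(1)
        for sid in law.substrates:
            s = _sym(sid)
            fwd *= s
            den_s *= 1 + s / law.Km[sid]
            km_s *= sympy.Float(law.Km[sid])
        rev = sympy.Integer(1) / law.Keq
        den_p = sympy.Integer(1)
        for sid in law.products:
            s = _sym(sid)
            rev *= s
            den_p *= 1 + s / law.Km[sid]
        return law.kcat * e * (fwd - rev) / (km_s * (den_s + den_p - 1)) * reg
    raise ConfigurationError(
        f"reaction {rxn.id!r}: rate form {law.form!r} not exportable"
    )


def export_sbml(network: ReactionNetwork, path) -> None:
    """Write the network as an SBML L3V2 document.

    Species and reaction counts in the document equal the network's (plus
    two reactions per modification cycle for the converter legs).
    """
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "glusim_model"})

    compartments = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid in ("intracellular", "extracellular"):
        ET.SubElement(
            compartments,
            f"{{{SBML_NS}}}compartment",
            {"id": cid, "constant": "true", "size": "1", "spatialDimensions": "3"},
        )

    species_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(
            species_list,
            f"{{{SBML_NS}}}species",
            {
                "id": _sbml_id(sp.id),
                "name": sp.id,
                "compartment": sp.compartment,
                "initialConcentration": repr(sp.concentration),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "true" if sp.role == "boundary" else "false",
                "constant": "false",
            },
        )

    reactions_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")

    def add_reaction(rid, stoich, math_expr) -> None:
        rx = ET.SubElement(
            reactions_el,
            f"{{{SBML_NS}}}reaction",
            {"id": _sbml_id(rid), "name": rid, "reversible": "true"},
        )
        reactants = [(s, -c) for s, c in stoich.items() if c < 0]
        products = [(s, c) for s, c in stoich.items() if c > 0]
        if reactants:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s, c in reactants:
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    {
                        "species": _sbml_id(s),
                        "stoichiometry": repr(float(c)),
                        "constant": "true",
                    },
                )
        if products:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s, c in products:
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    {
                        "species": _sbml_id(s),
                        "stoichiometry": repr(float(c)),
                        "constant": "true",
                    },
                )
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math_xml = mathml(math_expr)
        math_el = ET.fromstring(
            f'<math xmlns="{MATHML_NS}">{math_xml}</math>'
        )
        kl.append(math_el)

    for rxn in network.reactions:
        add_reaction(rxn.id, rxn.stoichiometry, rate_law_expression(rxn))

    for cyc in network.cycles:
        conv, tgt, mod = _sym(cyc.converter), _sym(cyc.target), _sym(cyc.modified_form)
        kin = cyc.k_kin * conv * tgt / (cyc.Km_kin + tgt)
        if cyc.kinase_inhibitor is not None:
            kin *= 1 / (1 + _sym(cyc.kinase_inhibitor) / cyc.Ki_inh)
        add_reaction(
            f"{cyc.id}_kinase", {cyc.target: -1, cyc.modified_form: 1}, kin
        )
        phos = cyc.k_phos * conv * mod / (cyc.Km_phos + mod)
        add_reaction(
            f"{cyc.id}_phosphatase", {cyc.modified_form: -1, cyc.target: 1}, phos
        )

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(Path(path), xml_declaration=True, encoding="UTF-8")
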