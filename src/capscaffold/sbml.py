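"""SBML Level 3 Version 1 export of the assembly network.

Writes core-package SBML with mass-action kinetic laws, initial amounts and
boundary-condition flags on the buffered ribosome pools, and reads such
documents back for round-trip checking.  The writer emits only the subset of
SBML this model needs (one compartment, parameters, species, reactions with
``<kineticLaw>`` math as products of rate constant and reactant amounts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from lxml import etree

from .network import ReactionNetwork

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_ID_BAD = re.compile(r"[^A-Za-z0-9_]")


def species_sid(label: str) -> str:
    """Map a canonical label to a valid SBML id (injective on this grammar)."""
    return "s_" + _ID_BAD.sub(
        "_", label.replace("(", "_").replace(")", "").replace(".", "__")
    ).strip("_")


def param_pid(ref: str) -> str:
    return "p_" + _ID_BAD.sub("_", ref.replace("[", "_").replace("]", ""))


def export_sbml(network: ReactionNetwork, params, totals, path: str) -> None:
    """Write the parameterized network as an SBML L3V1 document.

    ``params`` maps every rate-parameter reference used by the network to a
    value (a :class:`~capscaffold.kinetics.RateParameterSet` works); ``totals``
    is a :class:`~capscaffold.kinetics.TotalsConfig` giving initial amounts
    and the fixed (boundary) pools.
    """
    x0 = totals.initial_amounts(network)
    fixed = set(totals.fixed_pools)

    root = etree.Element("{%s}sbml" % SBML_NS, nsmap={None: SBML_NS},
                         attrib={"level": "3", "version": "1"})
    model = etree.SubElement(root, "{%s}model" % SBML_NS, attrib={"id": "cap_assembly"})

    comps = etree.SubElement(model, "{%s}listOfCompartments" % SBML_NS)
    etree.SubElement(comps, "{%s}compartment" % SBML_NS, attrib={
        "id": "cell", "constant": "true", "spatialDimensions": "3", "size": "1"})

    sp_list = etree.SubElement(model, "{%s}listOfSpecies" % SBML_NS)
    for i, sp in enumerate(network.species):
        etree.SubElement(sp_list, "{%s}species" % SBML_NS, attrib={
            "id": species_sid(sp.label),
            "name": sp.label,
            "compartment": "cell",
            "initialAmount": repr(float(x0[i])),
            "hasOnlySubstanceUnits": "true",
            "boundaryCondition": "true" if sp.label in fixed else "false",
            "constant": "false",
        })

    refs = sorted({r.rate_param for r in network.reactions})
    par_list = etree.SubElement(model, "{%s}listOfParameters" % SBML_NS)
    for ref in refs:
        try:
            val = params.value(ref)
        except (AttributeError, KeyError):
            val = params[ref]
        etree.SubElement(par_list, "{%s}parameter" % SBML_NS, attrib={
            "id": param_pid(ref), "name": ref,
            "value": repr(float(val)), "constant": "true"})

    rx_list = etree.SubElement(model, "{%s}listOfReactions" % SBML_NS)
    for j, rxn in enumerate(network.reactions):
        rx = etree.SubElement(rx_list, "{%s}reaction" % SBML_NS, attrib={
            "id": f"r{j}", "reversible": "false", "fast": "false"})
        lor = etree.SubElement(rx, "{%s}listOfReactants" % SBML_NS)
        for lab in rxn.reactants:
            etree.SubElement(lor, "{%s}speciesReference" % SBML_NS, attrib={
                "species": species_sid(lab), "stoichiometry": "1", "constant": "true"})
        lop = etree.SubElement(rx, "{%s}listOfProducts" % SBML_NS)
        for lab in rxn.products:
            etree.SubElement(lop, "{%s}speciesReference" % SBML_NS, attrib={
                "species": species_sid(lab), "stoichiometry": "1", "constant": "true"})
        kl = etree.SubElement(rx, "{%s}kineticLaw" % SBML_NS)
        math = etree.SubElement(kl, "{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, "{%s}apply" % MATHML_NS)
        etree.SubElement(apply_, "{%s}times" % MATHML_NS)
        ci = etree.SubElement(apply_, "{%s}ci" % MATHML_NS)
        ci.text = param_pid(rxn.rate_param)
        for lab in rxn.reactants:
            ci = etree.SubElement(apply_, "{%s}ci" % MATHML_NS)
            ci.text = species_sid(lab)

    etree.ElementTree(root).write(path, xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


@dataclass
class SBMLModelSummary:
    n_species: int
    n_reactions: int
    n_parameters: int
    n_boundary: int
    species_names: list[str]
    initial_amounts: dict[str, float]
    parameter_values: dict[str, float]


def read_sbml(path: str) -> SBMLModelSummary:
    """Parse an exported document back into a structural summary."""
    tree = etree.parse(path)
    ns = {"s": SBML_NS}
    species = tree.findall(".//s:listOfSpecies/s:species", ns)
    reactions = tree.findall(".//s:listOfReactions/s:reaction", ns)
    parameters = tree.findall(".//s:listOfParameters/s:parameter", ns)
    return SBMLModelSummary(
        n_species=len(species),
        n_reactions=len(reactions),
        n_parameters=len(parameters),
        n_boundary=sum(1 for s in species if s.get("boundaryCondition") == "true"),
        species_names=[s.get("name") for s in species],
        initial_amounts={s.get("name"): float(s.get("initialAmount")) for s in species},
        parameter_values={p.get("name"): float(p.get("value")) for p in parameters},
    )
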