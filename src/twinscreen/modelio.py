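"""Read/write network models as an SBML Level 3 subset or a YAML mirror.

The SBML writer emits standard Level 3 core structure (compartments,
species, reactions with kinetic-law MathML and local parameters) and stores
the package-specific vocabulary — reaction kind, gene mapping, pathway tags,
input/readout roles — in a custom annotation namespace, which the reader
uses to reconstruct the model exactly.  The YAML mirror carries identical
content in a hand-editable form; both round-trip losslessly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import yaml

from .errors import ValidationError
from .model_core import KIND_PARAMETERS, NetworkModel, Reaction, Species

__all__ = ["write_model", "read_model",
           "write_model_yaml", "read_model_yaml",
           "write_model_sbml", "read_model_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TS_NS = "urn:twinscreen:model-annotations"


def write_model(model: NetworkModel, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        write_model_yaml(model, path)
    elif path.suffix in (".xml", ".sbml"):
        write_model_sbml(model, path)
    else:
        raise ValidationError(f"unknown model format {path.suffix!r}")


def read_model(path) -> NetworkModel:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        return read_model_yaml(path)
    if path.suffix in (".xml", ".sbml"):
        return read_model_sbml(path)
    raise ValidationError(f"unknown model format {path.suffix!r}")


# ---------------------------------------------------------------------------
# YAML mirror
# ---------------------------------------------------------------------------

def _model_dict(model: NetworkModel) -> dict:
    return {
        "species": [{
            "id": s.id, "name": s.name, "compartment": s.compartment,
            "initial_concentration": float(s.initial_concentration),
            "is_gene_representative": bool(s.is_gene_representative),
            "gene": s.gene,
            "degradation_rate": float(s.degradation_rate),
        } for s in model.species],
        "reactions": [{
            "id": r.id, "kind": r.kind,
            "reactants": [[sid, float(st)] for sid, st in r.reactants],
            "products": [[sid, float(st)] for sid, st in r.products],
            "modifiers": list(r.modifiers),
            "parameters": {k: float(v) for k, v in r.parameters.items()},
        } for r in model.reactions],
        "pathway_tags": dict(model.pathway_tags),
        "input_species": list(model.input_species),
        "readout_positive": model.readout_positive,
        "readout_negative": model.readout_negative,
    }


def _model_from_dict(data: dict) -> NetworkModel:
    species = tuple(Species(
        id=s["id"], name=s.get("name", ""),
        compartment=s.get("compartment", "cytoplasm"),
        initial_concentration=float(s.get("initial_concentration", 0.0)),
        is_gene_representative=bool(s.get("is_gene_representative", False)),
        gene=s.get("gene"),
        degradation_rate=float(s.get("degradation_rate", 0.0)),
    ) for s in data["species"])
    reactions = tuple(Reaction(
        id=r["id"], kind=r["kind"],
        reactants=tuple((sid, float(st)) for sid, st in r.get("reactants", [])),
        products=tuple((sid, float(st)) for sid, st in r.get("products", [])),
        modifiers=tuple(r.get("modifiers", [])),
        parameters={k: float(v) for k, v in r.get("parameters", {}).items()},
    ) for r in data["reactions"])
    return NetworkModel(
        species=species, reactions=reactions,
        pathway_tags=dict(data.get("pathway_tags", {})),
        input_species=tuple(data.get("input_species", [])),
        readout_positive=data["readout_positive"],
        readout_negative=data["readout_negative"],
    )


def write_model_yaml(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_model_dict(model), fh, sort_keys=False)


def read_model_yaml(path) -> NetworkModel:
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# SBML Level 3 subset
# ---------------------------------------------------------------------------

def _math_for(reaction: Reaction) -> ET.Element:
    """Kinetic-law MathML for the reaction's rate-law vocabulary."""
    def ci(tok):
        el = ET.Element(f"{{{MATHML_NS}}}ci")
        el.text = f" {tok} "
        return el

    def apply(op, *args):
        el = ET.Element(f"{{{MATHML_NS}}}apply")
        el.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
        el.extend(args)
        return el

    k = KIND_PARAMETERS[reaction.kind][0]
    sub = reaction.reactants[0][0] if reaction.reactants else None
    mod = reaction.modifiers[0] if reaction.modifiers else None
    if reaction.kind == "synthesis":
        body = ci(k)
    elif reaction.kind in ("degradation", "complex_dissociation"):
        body = apply("times", ci(k), ci(sub))
    elif reaction.kind == "mass_action_activation":
        body = apply("times", ci(k), ci(mod), ci(sub))
    elif reaction.kind == "michaelis_menten":
        body = apply("divide",
                     apply("times", ci(k), ci(mod), ci(sub)),
                     apply("plus", ci("Km"), ci(sub)))
    elif reaction.kind == "complex_formation":
        body = apply("times", ci(k), ci(reaction.reactants[0][0]),
                     ci(reaction.reactants[1][0]))
    else:  # pragma: no cover
        raise ValidationError(f"unknown kind {reaction.kind}")
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(body)
    return math


def write_model_sbml(model: NetworkModel, path) -> None:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("ts", TS_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": "twinscreen_model"})

    ann = ET.SubElement(mdl, f"{{{SBML_NS}}}annotation")
    info = ET.SubElement(ann, f"{{{TS_NS}}}modelInfo")
    info.set("readoutPositive", model.readout_positive)
    info.set("readoutNegative", model.readout_negative)
    info.set("inputSpecies", " ".join(model.input_species))

    compartments = sorted({s.compartment for s in model.species})
    locomp = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for comp in compartments:
        ET.SubElement(locomp, f"{{{SBML_NS}}}compartment",
                      {"id": comp, "constant": "true", "size": "1",
                       "spatialDimensions": "3"})

    losp = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        el = ET.SubElement(losp, f"{{{SBML_NS}}}species", {
            "id": s.id, "name": s.name, "compartment": s.compartment,
            "initialConcentration": repr(float(s.initial_concentration)),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": str(s.id in model.input_species).lower(),
            "constant": "false",
        })
        sann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        sinfo = ET.SubElement(sann, f"{{{TS_NS}}}speciesInfo")
        sinfo.set("isGeneRepresentative", str(s.is_gene_representative).lower())
        if s.gene is not None:
            sinfo.set("gene", s.gene)
        sinfo.set("degradationRate", repr(float(s.degradation_rate)))
        sinfo.set("pathway", model.pathway_tags.get(s.id, "Core"))

    lorx = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        el = ET.SubElement(lorx, f"{{{SBML_NS}}}reaction",
                           {"id": r.id, "reversible": "false"})
        rann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        rinfo = ET.SubElement(rann, f"{{{TS_NS}}}reactionInfo")
        rinfo.set("kind", r.kind)
        if r.reactants:
            lo = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sid, st in r.reactants:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": sid, "stoichiometry": repr(float(st)),
                               "constant": "true"})
        if r.products:
            lo = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sid, st in r.products:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": sid, "stoichiometry": repr(float(st)),
                               "constant": "true"})
        if r.modifiers:
            lo = ET.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
            for sid in r.modifiers:
                ET.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": sid})
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math_for(r))
        lop = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for name, value in r.parameters.items():
            ET.SubElement(lop, f"{{{SBML_NS}}}localParameter",
                          {"id": name, "value": repr(float(value))})

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def read_model_sbml(path) -> NetworkModel:
    ns = {"sbml": SBML_NS, "ts": TS_NS}
    root = ET.parse(path).getroot()
    mdl = root.find("sbml:model", ns)
    if mdl is None:
        raise ValidationError("no <model> element found")
    info = mdl.find("sbml:annotation/ts:modelInfo", ns)
    if info is None:
        raise ValidationError("model annotation missing (not written by this package)")

    species = []
    tags = {}
    for el in mdl.findall("sbml:listOfSpecies/sbml:species", ns):
        sinfo = el.find("sbml:annotation/ts:speciesInfo", ns)
        gene = sinfo.get("gene") if sinfo is not None else None
        species.append(Species(
            id=el.get("id"), name=el.get("name", ""),
            compartment=el.get("compartment", "cytoplasm"),
            initial_concentration=float(el.get("initialConcentration", "0")),
            is_gene_representative=(sinfo is not None and
                                    sinfo.get("isGeneRepresentative") == "true"),
            gene=gene,
            degradation_rate=float(sinfo.get("degradationRate", "0"))
            if sinfo is not None else 0.0,
        ))
        tags[el.get("id")] = (sinfo.get("pathway", "Core")
                              if sinfo is not None else "Core")

    reactions = []
    for el in mdl.findall("sbml:listOfReactions/sbml:reaction", ns):
        rinfo = el.find("sbml:annotation/ts:reactionInfo", ns)
        if rinfo is None or rinfo.get("kind") is None:
            raise ValidationError(f"reaction {el.get('id')}: kind annotation missing")
        reactants = tuple(
            (sr.get("species"), float(sr.get("stoichiometry", "1")))
            for sr in el.findall("sbml:listOfReactants/sbml:speciesReference", ns))
        products = tuple(
            (sr.get("species"), float(sr.get("stoichiometry", "1")))
            for sr in el.findall("sbml:listOfProducts/sbml:speciesReference", ns))
        modifiers = tuple(
            sr.get("species") for sr in
            el.findall("sbml:listOfModifiers/sbml:modifierSpeciesReference", ns))
        params = {
            lp.get("id"): float(lp.get("value"))
            for lp in el.findall(
                "sbml:kineticLaw/sbml:listOfLocalParameters/sbml:localParameter",
                ns)}
        reactions.append(Reaction(id=el.get("id"), kind=rinfo.get("kind"),
                                  reactants=reactants, products=products,
                                  modifiers=modifiers, parameters=params))

    return NetworkModel(
        species=tuple(species), reactions=tuple(reactions), pathway_tags=tags,
        input_species=tuple(info.get("inputSpecies", "").split()),
        readout_positive=info.get("readoutPositive"),
        readout_negative=info.get("readoutNegative"),
    )
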