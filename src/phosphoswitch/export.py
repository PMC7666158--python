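"""Model export (BNGL / SBML) and tab-separated network dumps.

The exports exist for cross-validation: an exported file can be
re-parsed independently and its species/reaction counts compared with
the in-memory network.  The BNGL writer emits the fully expanded network
(seed species plus one reaction line per mass-action reaction); the SBML
writer produces an SBML Level 3 document via lxml.
"""

from __future__ import annotations

import re
from pathlib import Path

from lxml import etree

from .network import ReactionNetwork
from .params import ModelParameters


def _bngl_species_name(s) -> str:
    # BNGL-compatible: dots and bonds instead of '!': keep it parseable
    return s.name().replace("!", ".")


def export_bngl(network: ReactionNetwork, params: ModelParameters) -> str:
    """Serialize the expanded network as BNGL text.

    Parameter values are written with ``repr`` so decimal strings
    round-trip bit-exact.
    """
    lines = ["begin model", "begin parameters"]
    for name, value in params.as_dict().items():
        lines.append(f"  {name} {value!r}")
    lines.append("end parameters")
    lines.append("begin species")
    init = network.initial_state(params)
    for s, c in zip(network.species, init):
        lines.append(f"  {_bngl_species_name(s)} {c!r}")
    lines.append("end species")
    lines.append("begin reactions")
    for i, r in enumerate(network.reactions, start=1):
        lhs = " + ".join(_bngl_species_name(s) for s in r.reactants)
        rhs = " + ".join(_bngl_species_name(s) for s in r.products)
        lines.append(f"  {i} {lhs} -> {rhs} {r.rate_name}")
    lines.append("end reactions")
    lines.append("end model")
    return "\n".join(lines) + "\n"


def parse_bngl_counts(text: str) -> dict[str, int]:
    """Re-parse exported BNGL text: species / reaction / parameter counts."""
    counts = {"parameters": 0, "species": 0, "reactions": 0}
    block = None
    for raw in text.splitlines():
        line = raw.strip()
        m = re.match(r"begin (parameters|species|reactions)$", line)
        if m:
            block = m.group(1)
            continue
        if line.startswith("end "):
            block = None
            continue
        if block and line:
            counts[block] += 1
    return counts


_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def export_sbml(network: ReactionNetwork, params: ModelParameters) -> str:
    """Serialize the expanded network as an SBML Level 3 document."""
    nsmap = {None: _SBML_NS}
    sbml = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(sbml, "model", id="atf2_phosphoswitch")
    comps = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(comps, "compartment", id="cell", constant="true", size="1")
    sp_list = etree.SubElement(model, "listOfSpecies")
    ids = {}
    init = network.initial_state(params)
    for i, (s, c) in enumerate(zip(network.species, init)):
        sid = f"s{i}"
        ids[s] = sid
        etree.SubElement(
            sp_list, "species", id=sid, name=s.name(), compartment="cell",
            initialConcentration=repr(float(c)), constant="false",
            hasOnlySubstanceUnits="false", boundaryCondition="false",
        )
    par_list = etree.SubElement(model, "listOfParameters")
    for name, value in params.as_dict().items():
        etree.SubElement(par_list, "parameter", id=name, value=repr(float(value)),
                         constant="true")
    rx_list = etree.SubElement(model, "listOfReactions")
    for j, r in enumerate(network.reactions):
        rx = etree.SubElement(rx_list, "reaction", id=f"r{j}", reversible="false",
                              name=r.rate_name)
        reactants = etree.SubElement(rx, "listOfReactants")
        for s in r.reactants:
            etree.SubElement(reactants, "speciesReference", species=ids[s],
                             stoichiometry="1", constant="true")
        products = etree.SubElement(rx, "listOfProducts")
        for s in r.products:
            etree.SubElement(products, "speciesReference", species=ids[s],
                             stoichiometry="1", constant="true")
    return etree.tostring(sbml, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def parse_sbml_counts(text: str) -> dict[str, int]:
    """Independent SBML re-parse (xml.etree) returning element counts."""
    import xml.etree.ElementTree as ET

    root = ET.fromstring(text)
    ns = {"s": _SBML_NS}
    return {
        "species": len(root.findall(".//s:listOfSpecies/s:species", ns)),
        "reactions": len(root.findall(".//s:listOfReactions/s:reaction", ns)),
        "parameters": len(root.findall(".//s:listOfParameters/s:parameter", ns)),
    }


def export_model(network: ReactionNetwork, params: ModelParameters,
                 fmt: str = "BNGL") -> str:
    """Export the network in the requested format (``BNGL`` or ``SBML``)."""
    fmt = fmt.upper()
    if fmt == "BNGL":
        return export_bngl(network, params)
    if fmt == "SBML":
        return export_sbml(network, params)
    raise ValueError(f"unsupported export format {fmt!r}")


def network_tables(network: ReactionNetwork) -> tuple[str, str]:
    """Tab-separated species and reaction tables (the network dump)."""
    species_lines = ["index\tspecies"]
    species_lines += [f"{i}\t{s.name()}" for i, s in enumerate(network.species)]
    rxn_lines = ["index\trate\treactants\tproducts"]
    for i, r in enumerate(network.reactions):
        lhs = " + ".join(s.name() for s in r.reactants)
        rhs = " + ".join(s.name() for s in r.products)
        rxn_lines.append(f"{i}\t{r.rate_name}\t{lhs}\t{rhs}")
    return "\n".join(species_lines) + "\n", "\n".join(rxn_lines) + "\n"


def write_network(network: ReactionNetwork, params: ModelParameters,
                  directory: str | Path, fmt: str | None = None) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp, rx = network_tables(network)
    paths = [directory / "species.tsv", directory / "reactions.tsv"]
    paths[0].write_text(sp)
    paths[1].write_text(rx)
    if fmt:
        out = directory / f"model.{fmt.lower()}"
        out.write_text(export_model(network, params, fmt))
        paths.append(out)
    return paths
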