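"""Static signaling-network data model.

A :class:`PathwayNetwork` is a typed species/reaction graph for one cell:
species are the state variables of the ODE system (declaration order defines
state-vector order), reactions carry a rate-law kind plus the kinetic
parameters that kind requires.  This module owns the YAML schema
(parse/serialize), structural validation (reachability, dangling references,
missing parameters, conserved-moiety detection), and a minimal SBML Level 3
interchange subset.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import sympy
import yaml

__all__ = [
    "Species",
    "KineticParams",
    "Reaction",
    "PathwayNetwork",
    "NetworkError",
    "ParseError",
    "parse_network",
    "serialize_network",
    "validate_network",
    "export_interchange",
    "import_interchange",
    "stoichiometric_matrix",
    "conserved_moieties",
]

SPECIES_ROLES = frozenset(
    {
        "ligand",
        "receptor",
        "receptor_active",
        "g_protein_complex",
        "subunit",
        "enzyme",
        "enzyme_active",
        "adapter",
        "kinase",
        "transcription_factor",
        "tf_active",
        "metabolite",
        "secreted_marker",
    }
)

REACTION_KINDS = frozenset(
    {
        "smm_induced",
        "smm_summed",
        "smm_inhibited",
        "mass_action_irrev",
        "mass_action_rev",
        "synthesis",
        "degradation",
        "secretion",
    }
)

#: reaction kinds that interconvert species mass (used for moiety detection);
#: synthesis/degradation/secretion create, destroy or export mass and are excluded.
CONVERSION_KINDS = frozenset(
    {"smm_induced", "smm_summed", "smm_inhibited", "mass_action_irrev", "mass_action_rev"}
)

MODIFIER_MODES = frozenset({"activator", "inhibitor"})


class NetworkError(ValueError):
    """Structural violation in a network definition."""


class ParseError(NetworkError):
    """Document does not conform to the network schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Species:
    """One state variable: a molecular species in a compartment.

    ``expression_scale`` multiplies the initial amount and any synthesis flux
    producing this species; ``activity_scale`` multiplies fluxes this species
    catalyses (or, for inhibitors, its effective inhibitory concentration).
    Both default to 1 and are the hooks genomic lesions act through.
    ``clamped`` freezes the species at its initial value during integration
    (used for constant boundary inputs in staged feed-forward runs).
    """

    id: str
    name: str = ""
    role: str = "metabolite"
    compartment: str = "cell"
    initial_amount: float = 0.0
    expression_scale: float = 1.0
    activity_scale: float = 1.0
    gene: str | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if not self.id or not isinstance(self.id, str):
            raise NetworkError("species id must be a non-empty string")
        if self.role not in SPECIES_ROLES:
            raise NetworkError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.initial_amount < 0:
            raise NetworkError(f"species {self.id!r}: initial_amount must be >= 0")
        if self.expression_scale < 0 or self.activity_scale < 0:
            raise NetworkError(f"species {self.id!r}: scales must be >= 0")


@dataclass
class KineticParams:
    """Kinetic parameter bundle; which fields are required depends on the
    reaction kind.  ``vmax``/``ka``/``ki`` may be lists for summed-SMM
    reactions (one entry per activator) and multi-inhibitor terms.

    Units: vmax a.u./h, km/ka/ki a.u., kcat 1/h, kf/kr per mass-action order.
    """

    vmax: float | list[float] | None = None
    km: float | None = None
    kcat: float | None = None
    ka: float | list[float] | None = None
    ki: float | list[float] | None = None
    kf: float | None = None
    kr: float | None = None

    def __post_init__(self) -> None:
        for name in ("vmax", "km", "kcat", "ka", "ki", "kf", "kr"):
            val = getattr(self, name)
            if val is None:
                continue
            vals = val if isinstance(val, list) else [val]
            if any(not isinstance(v, (int, float)) or v <= 0 for v in vals):
                raise NetworkError(f"kinetic parameter {name} must be positive, got {val!r}")

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("vmax", "km", "kcat", "ka", "ki", "kf", "kr")
            if getattr(self, k) is not None
        }


@dataclass
class Reaction:
    id: str
    kind: str
    substrates: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[tuple[str, str]] = field(default_factory=list)
    params: KineticParams = field(default_factory=KineticParams)
    provenance: list[str] = field(default_factory=list)
    #: multiplier applied to product-side stoichiometry at flux accounting time;
    #: used by multicell composition for volume-ratio-corrected transfer.
    transfer_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise NetworkError(f"reaction {self.id!r}: unsupported kind {self.kind!r}")
        for sid, st in self.substrates + self.products:
            if not (isinstance(st, int) and st > 0):
                raise NetworkError(
                    f"reaction {self.id!r}: stoichiometry for {sid!r} must be a positive integer"
                )
        for sid, mode in self.modifiers:
            if mode not in MODIFIER_MODES:
                raise NetworkError(f"reaction {self.id!r}: unknown modifier mode {mode!r}")

    def activators(self) -> list[str]:
        return [sid for sid, mode in self.modifiers if mode == "activator"]

    def inhibitors(self) -> list[str]:
        return [sid for sid, mode in self.modifiers if mode == "inhibitor"]


@dataclass
class PathwayNetwork:
    """One cell's signaling network: species (in state-vector order), reactions,
    agonist input ports and biomarker output markers."""

    cell_id: str
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    input_ports: list[tuple[str, str]] = field(default_factory=list)  # (ligand id, agonist)
    output_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sp in self.species:
            if sp.id in seen:
                raise NetworkError(f"duplicate species id {sp.id!r}")
            seen.add(sp.id)
        rseen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in rseen:
                raise NetworkError(f"duplicate reaction id {rxn.id!r}")
            rseen.add(rxn.id)
        self._check_refs()

    # -- lookups ------------------------------------------------------------

    def species_map(self) -> dict[str, Species]:
        return {sp.id: sp for sp in self.species}

    def species_index(self) -> dict[str, int]:
        return {sp.id: i for i, sp in enumerate(self.species)}

    def get_reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def port_for_agonist(self, agonist: str) -> str:
        hits = [sid for sid, name in self.input_ports if name == agonist]
        if len(hits) != 1:
            raise NetworkError(
                f"cell {self.cell_id!r}: agonist {agonist!r} resolves to {len(hits)} input ports"
            )
        return hits[0]

    def copy(self) -> "PathwayNetwork":
        return PathwayNetwork(
            cell_id=self.cell_id,
            species=[replace(sp) for sp in self.species],
            reactions=[
                replace(
                    r,
                    substrates=list(r.substrates),
                    products=list(r.products),
                    modifiers=list(r.modifiers),
                    params=replace(r.params),
                    provenance=list(r.provenance),
                )
                for r in self.reactions
            ],
            input_ports=list(self.input_ports),
            output_markers=list(self.output_markers),
        )

    def _check_refs(self) -> None:
        ids = {sp.id for sp in self.species}
        for rxn in self.reactions:
            for sid, _ in rxn.substrates + rxn.products + rxn.modifiers:
                if sid not in ids:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references undeclared species {sid!r}"
                    )
        for sid, _ in self.input_ports:
            if sid not in ids:
                raise NetworkError(f"input port references undeclared species {sid!r}")
        for sid in self.output_markers:
            if sid not in ids:
                raise NetworkError(f"output marker references undeclared species {sid!r}")


# ---------------------------------------------------------------------------
# YAML schema
# ---------------------------------------------------------------------------

_SPECIES_KEYS = {
    "id",
    "name",
    "role",
    "compartment",
    "initial_amount",
    "expression_scale",
    "activity_scale",
    "gene",
    "clamped",
}
_REACTION_KEYS = {"id", "kind", "substrates", "products", "modifiers", "params", "provenance"}
_TOP_KEYS = {"cell_id", "species", "reactions", "inputs", "outputs"}
_PARAM_KEYS = {"vmax", "km", "kcat", "ka", "ki", "kf", "kr"}


def _reject_unknown(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParseError(f"{where}: unknown key(s) {sorted(unknown)}")


def _parse_side(raw, where: str) -> list[tuple[str, int]]:
    """Substrate/product lists: either ["A", "B"] or [{"A": 2}] entries."""
    out: list[tuple[str, int]] = []
    if raw is None:
        return out
    if not isinstance(raw, list):
        raise ParseError(f"{where}: expected a list")
    for entry in raw:
        if isinstance(entry, str):
            out.append((entry, 1))
        elif isinstance(entry, dict) and len(entry) == 1:
            (sid, st), = entry.items()
            if not isinstance(st, int):
                raise ParseError(f"{where}: stoichiometry for {sid!r} must be an integer")
            out.append((sid, st))
        else:
            raise ParseError(f"{where}: bad entry {entry!r}")
    return out


def parse_network(text: str) -> PathwayNetwork:
    """Parse a YAML network document into a validated :class:`PathwayNetwork`.

    Species order in the document defines the ODE state-vector order.
    Unknown keys and rate-law kinds are rejected with located errors.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - defers to pyyaml messages
        raise ParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("top level must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "top level")
    if "cell_id" not in doc or "species" not in doc:
        raise ParseError("top level requires keys 'cell_id' and 'species'")

    species: list[Species] = []
    for i, raw in enumerate(doc["species"] or []):
        if not isinstance(raw, dict) or "id" not in raw:
            raise ParseError(f"species[{i}]: expected a mapping with an 'id'")
        _reject_unknown(raw, _SPECIES_KEYS, f"species[{i}] ({raw.get('id')})")
        try:
            species.append(
                Species(
                    id=raw["id"],
                    name=raw.get("name", ""),
                    role=raw.get("role", "metabolite"),
                    compartment=raw.get("compartment", "cell"),
                    initial_amount=float(raw.get("initial_amount", 0.0)),
                    expression_scale=float(raw.get("expression_scale", 1.0)),
                    activity_scale=float(raw.get("activity_scale", 1.0)),
                    gene=raw.get("gene"),
                    clamped=bool(raw.get("clamped", False)),
                )
            )
        except NetworkError as exc:
            raise ParseError(f"species[{i}]: {exc}") from exc

    reactions: list[Reaction] = []
    for i, raw in enumerate(doc.get("reactions") or []):
        if not isinstance(raw, dict) or "id" not in raw or "kind" not in raw:
            raise ParseError(f"reactions[{i}]: expected a mapping with 'id' and 'kind'")
        where = f"reactions[{i}] ({raw.get('id')})"
        _reject_unknown(raw, _REACTION_KEYS, where)
        if raw["kind"] not in REACTION_KINDS:
            raise ParseError(f"{where}: unsupported rate-law kind {raw['kind']!r}")
        praw = raw.get("params") or {}
        if not isinstance(praw, dict):
            raise ParseError(f"{where}: params must be a mapping")
        _reject_unknown(praw, _PARAM_KEYS, f"{where} params")
        modifiers: list[tuple[str, str]] = []
        for entry in raw.get("modifiers") or []:
            if isinstance(entry, dict) and len(entry) == 1:
                (sid, mode), = entry.items()
                modifiers.append((sid, mode))
            else:
                raise ParseError(f"{where}: modifier entries must be {{species: mode}}")
        try:
            reactions.append(
                Reaction(
                    id=raw["id"],
                    kind=raw["kind"],
                    substrates=_parse_side(raw.get("substrates"), f"{where} substrates"),
                    products=_parse_side(raw.get("products"), f"{where} products"),
                    modifiers=modifiers,
                    params=KineticParams(**praw),
                    provenance=list(raw.get("provenance") or []),
                )
            )
        except NetworkError as exc:
            raise ParseError(f"{where}: {exc}") from exc

    inputs = [(d["ligand"], d["agonist"]) for d in (doc.get("inputs") or [])]
    outputs = list(doc.get("outputs") or [])
    try:
        return PathwayNetwork(
            cell_id=doc["cell_id"],
            species=species,
            reactions=reactions,
            input_ports=inputs,
            output_markers=outputs,
        )
    except NetworkError as exc:
        raise ParseError(str(exc)) from exc


def serialize_network(net: PathwayNetwork) -> str:
    """Canonical YAML serialization; ``parse_network`` round-trips it exactly."""

    def side(entries):
        return [sid if st == 1 else {sid: st} for sid, st in entries]

    doc: dict = {"cell_id": net.cell_id, "species": []}
    for sp in net.species:
        raw: dict = {"id": sp.id}
        if sp.name:
            raw["name"] = sp.name
        raw["role"] = sp.role
        raw["compartment"] = sp.compartment
        raw["initial_amount"] = sp.initial_amount
        if sp.expression_scale != 1.0:
            raw["expression_scale"] = sp.expression_scale
        if sp.activity_scale != 1.0:
            raw["activity_scale"] = sp.activity_scale
        if sp.gene:
            raw["gene"] = sp.gene
        if sp.clamped:
            raw["clamped"] = True
        doc["species"].append(raw)
    doc["reactions"] = []
    for rxn in net.reactions:
        raw = {"id": rxn.id, "kind": rxn.kind}
        if rxn.substrates:
            raw["substrates"] = side(rxn.substrates)
        if rxn.products:
            raw["products"] = side(rxn.products)
        if rxn.modifiers:
            raw["modifiers"] = [{sid: mode} for sid, mode in rxn.modifiers]
        raw["params"] = rxn.params.as_dict()
        if rxn.provenance:
            raw["provenance"] = rxn.provenance
        doc["reactions"].append(raw)
    if net.input_ports:
        doc["inputs"] = [{"ligand": sid, "agonist": name} for sid, name in net.input_ports]
    if net.output_markers:
        doc["outputs"] = list(net.output_markers)
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_REQUIRED_PARAMS = {
    "mass_action_irrev": ("kf",),
    "mass_action_rev": ("kf", "kr"),
    "synthesis": ("kf",),
    "degradation": ("kf",),
    "secretion": ("kf",),
}


def _required_param_violations(rxn: Reaction) -> list[str]:
    p = rxn.params
    out: list[str] = []
    nact = len(rxn.activators())
    ninh = len(rxn.inhibitors())

    def need(name: str) -> None:
        if getattr(p, name) is None:
            out.append(f"reaction {rxn.id!r} ({rxn.kind}): missing parameter {name!r}")

    def need_list(name: str, n: int) -> None:
        val = getattr(p, name)
        if val is None:
            out.append(f"reaction {rxn.id!r} ({rxn.kind}): missing parameter {name!r}")
        elif isinstance(val, list) and len(val) != n:
            out.append(
                f"reaction {rxn.id!r}: parameter {name!r} has {len(val)} entries, expected {n}"
            )

    if rxn.kind in _REQUIRED_PARAMS:
        for name in _REQUIRED_PARAMS[rxn.kind]:
            need(name)
    if rxn.kind == "synthesis" and rxn.substrates:
        out.append(f"reaction {rxn.id!r}: synthesis takes no substrates")
    if rxn.kind in ("degradation", "secretion") and len(rxn.substrates) != 1:
        out.append(f"reaction {rxn.id!r}: {rxn.kind} requires exactly one substrate")
    if rxn.kind == "secretion" and len(rxn.products) != 1:
        out.append(f"reaction {rxn.id!r}: secretion requires exactly one (medium) product")
    if rxn.kind in ("smm_induced", "smm_summed", "smm_inhibited"):
        if len(rxn.substrates) != 1:
            out.append(f"reaction {rxn.id!r}: {rxn.kind} requires exactly one substrate")
        need("km")
        if rxn.kind == "smm_induced":
            if p.vmax is None and p.kcat is None:
                out.append(
                    f"reaction {rxn.id!r}: smm_induced requires vmax (or kcat with an enzyme modifier)"
                )
            if p.kcat is not None and nact == 0:
                out.append(f"reaction {rxn.id!r}: kcat form requires an activator (enzyme) modifier")
            if p.vmax is not None and nact > 0:
                need_list("ka", nact if p.kcat is None else max(nact - 1, 1))
        elif rxn.kind == "smm_summed":
            if nact < 2:
                out.append(f"reaction {rxn.id!r}: smm_summed requires >= 2 activator modifiers")
            need_list("vmax", nact)
            need_list("ka", nact)
        elif rxn.kind == "smm_inhibited":
            need("vmax")
        if ninh:
            need_list("ki", ninh)
    elif ninh:
        need_list("ki", ninh)
    return out


def stoichiometric_matrix(
    net: PathwayNetwork, kinds: Iterable[str] | None = None
) -> tuple[list[str], list[str], list[list[int]]]:
    """Integer stoichiometric matrix N (species x reactions), optionally
    restricted to a set of reaction kinds.  Returns (species ids, reaction ids, N)."""
    kinds = set(kinds) if kinds is not None else REACTION_KINDS
    rxns = [r for r in net.reactions if r.kind in kinds]
    idx = net.species_index()
    N = [[0] * len(rxns) for _ in net.species]
    for j, rxn in enumerate(rxns):
        for sid, st in rxn.substrates:
            N[idx[sid]][j] -= st
        for sid, st in rxn.products:
            N[idx[sid]][j] += st
    return [sp.id for sp in net.species], [r.id for r in rxns], N


def conserved_moieties(net: PathwayNetwork) -> list[dict[str, Fraction]]:
    """Candidate conserved moieties: rational left-null-space vectors of the
    stoichiometric matrix restricted to conversion reactions (mass-action and
    saturating kinds; synthesis/degradation/secretion excluded, since those
    deliberately create/destroy/export mass).

    Each returned vector maps species id -> weight; the weighted total is
    invariant under every conversion reaction.  Vectors are normalized to
    integer weights with gcd 1 and restricted to species that take part in at
    least one conversion reaction (never-reacting species are trivially
    constant and not reported).
    """
    sids, rids, N = stoichiometric_matrix(net, CONVERSION_KINDS)
    if not rids:
        return []
    active = [i for i, row in enumerate(N) if any(row)]
    if not active:
        return []
    M = sympy.Matrix([[Fraction(N[i][j]) for j in range(len(rids))] for i in active])
    null = M.T.nullspace()  # left null space of N == null space of N^T
    out: list[dict[str, Fraction]] = []
    for vec in null:
        fracs = [Fraction(sympy.nsimplify(v)) for v in vec]
        denom = 1
        for f in fracs:
            denom = denom * f.denominator // _gcd(denom, f.denominator)
        ints = [f * denom for f in fracs]
        g = 0
        for f in ints:
            g = _gcd(g, abs(int(f)))
        if g > 1:
            ints = [f / g for f in ints]
        if all(f <= 0 for f in ints):
            ints = [-f for f in ints]
        out.append({sids[active[i]]: ints[i] for i in range(len(active)) if ints[i] != 0})
    return out


def _gcd(a: int, b: int) -> int:
    import math

    return math.gcd(int(a), int(b))


def validate_network(net: PathwayNetwork) -> list[str]:
    """Structural diagnostics; an empty report means every invariant holds and
    ODE assembly cannot fail on a missing symbol.

    Checks: output markers reachable from at least one input port, orphan
    species, kind-specific kinetic parameters present, stoichiometry sanity.
    Conserved-moiety candidates are informational and not violations.
    """
    report: list[str] = []
    ids = {sp.id for sp in net.species}

    # reachability over the directed bipartite species->reaction->species graph;
    # modifiers count as edges into the reaction (they gate it).
    g = nx.DiGraph()
    for sp in net.species:
        g.add_node(("s", sp.id))
    for rxn in net.reactions:
        g.add_node(("r", rxn.id))
        for sid, _ in rxn.substrates:
            g.add_edge(("s", sid), ("r", rxn.id))
        for sid, _ in rxn.modifiers:
            g.add_edge(("s", sid), ("r", rxn.id))
        for sid, _ in rxn.products:
            g.add_edge(("r", rxn.id), ("s", sid))
    reachable: set = set()
    for sid, _ in net.input_ports:
        reachable |= nx.descendants(g, ("s", sid)) | {("s", sid)}
    for marker in net.output_markers:
        if net.input_ports and ("s", marker) not in reachable:
            report.append(f"output marker {marker!r} unreachable from any input port")

    used = set()
    for rxn in net.reactions:
        for sid, _ in rxn.substrates + rxn.products + rxn.modifiers:
            used.add(sid)
    ports = {sid for sid, _ in net.input_ports}
    for sp in net.species:
        if sp.id not in used and sp.id not in ports and sp.id not in net.output_markers:
            report.append(f"orphan species {sp.id!r} participates in no reaction")

    for rxn in net.reactions:
        report.extend(_required_param_violations(rxn))
    return report


# ---------------------------------------------------------------------------
# SBML Level 3 interchange (minimal subset, stdlib ElementTree)
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_ANNOT_NS = "https://mcsim.invalid/ns/network"


def _mathml_rate_expr(rxn: Reaction) -> ET.Element:
    """Explicit kinetic-law MathML for external tools.

    Written as an infix string compiled to a MathML <ci>-wrapped expression is
    overkill here; we emit a flat <apply><times> over named factors, which is
    valid MathML and adequate for interchange.  The authoritative rate law for
    re-import travels in the package annotation.
    """
    math = ET.Element(f"{{{_MATHML_NS}}}math")
    apply = ET.SubElement(math, f"{{{_MATHML_NS}}}apply")
    ET.SubElement(apply, f"{{{_MATHML_NS}}}times")
    for sid, st in rxn.substrates:
        for _ in range(st):
            ci = ET.SubElement(apply, f"{{{_MATHML_NS}}}ci")
            ci.text = f" {sid} "
    if not rxn.substrates:
        cn = ET.SubElement(apply, f"{{{_MATHML_NS}}}cn")
        cn.text = " 1 "
    ci = ET.SubElement(apply, f"{{{_MATHML_NS}}}ci")
    ci.text = f" k_{rxn.id} "
    return math


def export_interchange(net: PathwayNetwork) -> str:
    """Serialize to an SBML Level 3 Version 2 document.

    One SBML species per Species (compartments ``cell_<id>`` / ``medium``),
    one SBML reaction per Reaction with modifiers and a kinetic law.  The
    full rate-law kind/parameter bundle rides in a namespaced annotation so
    that :func:`import_interchange` reconstructs a network whose simulation is
    identical to the original's.
    """
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("math", _MATHML_NS)
    ET.register_namespace("mcsim", _ANNOT_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": f"cell_{net.cell_id}"})

    comps = sorted(
        {("medium" if sp.compartment == "medium" else f"cell_{net.cell_id}") for sp in net.species}
    ) or [f"cell_{net.cell_id}"]
    loc = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    for cid in comps:
        ET.SubElement(
            loc, f"{{{_SBML_NS}}}compartment", {"id": cid, "constant": "true", "size": "1"}
        )

    los = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for sp in net.species:
        comp = "medium" if sp.compartment == "medium" else f"cell_{net.cell_id}"
        el = ET.SubElement(
            los,
            f"{{{_SBML_NS}}}species",
            {
                "id": sp.id,
                "name": sp.name or sp.id,
                "compartment": comp,
                "initialConcentration": repr(sp.initial_amount),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "true" if sp.clamped else "false",
                "constant": "false",
            },
        )
        annot = ET.SubElement(el, f"{{{_SBML_NS}}}annotation")
        ET.SubElement(
            annot,
            f"{{{_ANNOT_NS}}}speciesInfo",
            {
                "role": sp.role,
                "compartment": sp.compartment,
                "expressionScale": repr(sp.expression_scale),
                "activityScale": repr(sp.activity_scale),
                **({"gene": sp.gene} if sp.gene else {}),
            },
        )

    if net.reactions:
        lor = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
        for rxn in net.reactions:
            rel = ET.SubElement(
                lor, f"{{{_SBML_NS}}}reaction", {"id": rxn.id, "reversible": str(rxn.kind == "mass_action_rev").lower()}
            )
            annot = ET.SubElement(rel, f"{{{_SBML_NS}}}annotation")
            params = rxn.params.as_dict()
            a = ET.SubElement(
                annot,
                f"{{{_ANNOT_NS}}}rateLaw",
                {"kind": rxn.kind, "transferScale": repr(rxn.transfer_scale)},
            )
            for name, val in params.items():
                vals = val if isinstance(val, list) else [val]
                ET.SubElement(
                    a, f"{{{_ANNOT_NS}}}param", {"name": name, "value": " ".join(repr(v) for v in vals), "list": str(isinstance(val, list)).lower()}
                )
            if rxn.provenance:
                ET.SubElement(a, f"{{{_ANNOT_NS}}}provenance").text = " ".join(rxn.provenance)
            if rxn.substrates:
                lre = ET.SubElement(rel, f"{{{_SBML_NS}}}listOfReactants")
                for sid, st in rxn.substrates:
                    ET.SubElement(
                        lre,
                        f"{{{_SBML_NS}}}speciesReference",
                        {"species": sid, "stoichiometry": str(st), "constant": "true"},
                    )
            if rxn.products:
                lpr = ET.SubElement(rel, f"{{{_SBML_NS}}}listOfProducts")
                for sid, st in rxn.products:
                    ET.SubElement(
                        lpr,
                        f"{{{_SBML_NS}}}speciesReference",
                        {"species": sid, "stoichiometry": str(st), "constant": "true"},
                    )
            if rxn.modifiers:
                lmo = ET.SubElement(rel, f"{{{_SBML_NS}}}listOfModifiers")
                for sid, mode in rxn.modifiers:
                    mel = ET.SubElement(
                        lmo, f"{{{_SBML_NS}}}modifierSpeciesReference", {"species": sid}
                    )
                    man = ET.SubElement(mel, f"{{{_SBML_NS}}}annotation")
                    ET.SubElement(man, f"{{{_ANNOT_NS}}}modifierMode", {"mode": mode})
            kl = ET.SubElement(rel, f"{{{_SBML_NS}}}kineticLaw")
            kl.append(_mathml_rate_expr(rxn))

    # ports/markers
    mannot = ET.SubElement(model, f"{{{_SBML_NS}}}annotation")
    io_el = ET.SubElement(mannot, f"{{{_ANNOT_NS}}}io")
    for sid, name in net.input_ports:
        ET.SubElement(io_el, f"{{{_ANNOT_NS}}}input", {"ligand": sid, "agonist": name})
    for sid in net.output_markers:
        ET.SubElement(io_el, f"{{{_ANNOT_NS}}}output", {"species": sid})

    buf = io.BytesIO()
    ET.indent(root)
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue().decode("utf-8")


def import_interchange(text: str) -> PathwayNetwork:
    """Inverse of :func:`export_interchange` for documents this package wrote
    (the supported SBML subset requires the package annotations)."""
    root = ET.fromstring(text)
    model = root.find(f"{{{_SBML_NS}}}model")
    if model is None:
        raise ParseError("SBML document has no <model>")
    cell_id = (model.get("id") or "cell").removeprefix("cell_")

    species: list[Species] = []
    for el in model.iter(f"{{{_SBML_NS}}}species"):
        info = el.find(f"./{{{_SBML_NS}}}annotation/{{{_ANNOT_NS}}}speciesInfo")
        attrs = info.attrib if info is not None else {}
        species.append(
            Species(
                id=el.get("id"),
                name=el.get("name") or "",
                role=attrs.get("role", "metabolite"),
                compartment=attrs.get("compartment", "cell"),
                initial_amount=float(el.get("initialConcentration", "0")),
                expression_scale=float(attrs.get("expressionScale", "1")),
                activity_scale=float(attrs.get("activityScale", "1")),
                gene=attrs.get("gene"),
                clamped=el.get("boundaryCondition") == "true",
            )
        )

    reactions: list[Reaction] = []
    for rel in model.iter(f"{{{_SBML_NS}}}reaction"):
        law = rel.find(f"./{{{_SBML_NS}}}annotation/{{{_ANNOT_NS}}}rateLaw")
        if law is None:
            raise ParseError(f"reaction {rel.get('id')!r}: missing rate-law annotation")
        params: dict = {}
        for pel in law.findall(f"{{{_ANNOT_NS}}}param"):
            vals = [float(v) for v in pel.get("value").split()]
            params[pel.get("name")] = vals if pel.get("list") == "true" else vals[0]
        prov_el = law.find(f"{{{_ANNOT_NS}}}provenance")
        subs = [
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in rel.findall(f"./{{{_SBML_NS}}}listOfReactants/{{{_SBML_NS}}}speciesReference")
        ]
        prods = [
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in rel.findall(f"./{{{_SBML_NS}}}listOfProducts/{{{_SBML_NS}}}speciesReference")
        ]
        mods: list[tuple[str, str]] = []
        for mel in rel.findall(f"./{{{_SBML_NS}}}listOfModifiers/{{{_SBML_NS}}}modifierSpeciesReference"):
            mm = mel.find(f"./{{{_SBML_NS}}}annotation/{{{_ANNOT_NS}}}modifierMode")
            mods.append((mel.get("species"), mm.get("mode") if mm is not None else "activator"))
        reactions.append(
            Reaction(
                id=rel.get("id"),
                kind=law.get("kind"),
                substrates=subs,
                products=prods,
                modifiers=mods,
                params=KineticParams(**params),
                provenance=prov_el.text.split() if prov_el is not None and prov_el.text else [],
                transfer_scale=float(law.get("transferScale", "1")),
            )
        )

    inputs: list[tuple[str, str]] = []
    outputs: list[str] = []
    io_el = model.find(f"./{{{_SBML_NS}}}annotation/{{{_ANNOT_NS}}}io")
    if io_el is not None:
        for el in io_el.findall(f"{{{_ANNOT_NS}}}input"):
            inputs.append((el.get("ligand"), el.get("agonist")))
        for el in io_el.findall(f"{{{_ANNOT_NS}}}output"):
            outputs.append(el.get("species"))

    return PathwayNetwork(
        cell_id=cell_id,
        species=species,
        reactions=reactions,
        input_ports=inputs,
        output_markers=outputs,
    )
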