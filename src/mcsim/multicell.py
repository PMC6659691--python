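"""Multi-cell composition: autocrine/paracrine coupling through a shared
medium, and staged feed-forward runs.

Single-cell networks are composed into one simulatable system by namespacing
each cell's species as ``<cell_id>.<species_id>`` and appending the medium
species.  Secretion reactions move mass cell->medium (volume-ratio
corrected); uptake either adds the medium species as an activator modifier of
the target cell's receptor-activation reaction (``as_modifier``, ligand
sensed but not consumed -- the default) or transports mass medium->cell
(``as_transport``).  Feed-forward runs stage the computation: source cells
are simulated to the endpoint and their medium concentrations become clamped
constant inputs of the target cell, with the target's control defined by
unperturbed sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .network_model import (
    KineticParams,
    NetworkError,
    PathwayNetwork,
    Reaction,
    Species,
)
from .ode_engine import (
    MarkerResponse,
    SimulationResult,
    SimulationSettings,
    percent_change_readout,
    simulate,
)

__all__ = [
    "Secretion",
    "Uptake",
    "CouplingMap",
    "MultiCellModel",
    "compose_coculture",
    "run_feedforward",
    "parse_coupling",
    "serialize_coupling",
]


@dataclass(frozen=True)
class Secretion:
    cell_id: str
    species: str  # intracellular marker
    medium_species: str
    ks: float = 1.0  # 1/h

    def __post_init__(self):
        if self.ks < 0:
            raise ValueError("secretion rate ks must be >= 0")


@dataclass(frozen=True)
class Uptake:
    medium_species: str
    cell_id: str
    ligand: str  # input ligand species of the target cell
    mode: str = "as_modifier"
    ka: float | None = None  # half-activation for as_modifier (default: reuse reaction's)
    vmax: float | None = None  # activator weight for as_modifier (default: reuse reaction's)
    ku: float = 1.0  # transport rate for as_transport, 1/h

    def __post_init__(self):
        if self.mode not in ("as_modifier", "as_transport"):
            raise ValueError(f"unknown uptake mode {self.mode!r}")
        if self.ku < 0:
            raise ValueError("uptake rate ku must be >= 0")


@dataclass(frozen=True)
class CouplingMap:
    secretions: tuple[Secretion, ...] = ()
    uptakes: tuple[Uptake, ...] = ()
    medium_degradation: tuple[tuple[str, float], ...] = ()  # (medium species, kd 1/h)
    volume_ratio: float = 1.0  # cell:medium

    def __post_init__(self):
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be positive")
        for _, kd in self.medium_degradation:
            if kd < 0:
                raise ValueError("medium degradation rate must be >= 0")


@dataclass
class MultiCellModel:
    cells: list[PathwayNetwork]
    medium: list[Species]
    coupling: CouplingMap
    network: PathwayNetwork  # flattened, simulatable system
    output_markers: list[str] = field(default_factory=list)

    def qualified(self, cell_id: str, species_id: str) -> str:
        return f"{cell_id}.{species_id}"


def _medium_species_ids(coupling: CouplingMap) -> list[str]:
    seen: list[str] = []
    for sec in coupling.secretions:
        if sec.medium_species not in seen:
            seen.append(sec.medium_species)
    for upt in coupling.uptakes:
        if upt.medium_species not in seen:
            seen.append(upt.medium_species)
    for sid, _ in coupling.medium_degradation:
        if sid not in seen:
            seen.append(sid)
    return seen


def compose_coculture(
    cells: Sequence[PathwayNetwork],
    coupling: CouplingMap,
    medium: Sequence[Species] | None = None,
    model_id: str = "coculture",
) -> MultiCellModel:
    """Compose cell networks plus a shared medium into one system.

    The composed state vector concatenates each cell's state (in the given
    cell order) followed by the medium species.  Autocrine loops (a cell
    secreting and sensing the same medium species) are permitted.
    """
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise NetworkError("cell ids must be unique in a co-culture")
    by_id = {c.cell_id: c for c in cells}

    if medium is None:
        medium = [
            Species(id=sid, role="secreted_marker", compartment="medium", initial_amount=0.0)
            for sid in _medium_species_ids(coupling)
        ]
    medium = [replace(sp, compartment="medium") for sp in medium]
    medium_ids = {sp.id for sp in medium}

    species: list[Species] = []
    reactions: list[Reaction] = []
    inputs: list[tuple[str, str]] = []
    markers: list[str] = []
    for cell in cells:
        q = lambda sid, c=cell.cell_id: f"{c}.{sid}"
        for sp in cell.species:
            species.append(replace(sp, id=q(sp.id), compartment=f"cell:{cell.cell_id}"))
        for rxn in cell.reactions:
            reactions.append(
                replace(
                    rxn,
                    id=q(rxn.id),
                    substrates=[(q(s), st) for s, st in rxn.substrates],
                    products=[(q(s), st) for s, st in rxn.products],
                    modifiers=[(q(s), m) for s, m in rxn.modifiers],
                    params=replace(rxn.params),
                    provenance=list(rxn.provenance),
                )
            )
        # agonist names stay unqualified: the same agonist may enter several cells
        inputs.extend((q(sid), name) for sid, name in cell.input_ports)
        markers.extend(q(sid) for sid in cell.output_markers)
    species.extend(medium)
    markers.extend(sp.id for sp in medium)

    rho = coupling.volume_ratio
    for i, sec in enumerate(coupling.secretions):
        if sec.cell_id not in by_id:
            raise NetworkError(f"secretion references unknown cell {sec.cell_id!r}")
        if sec.species not in {sp.id for sp in by_id[sec.cell_id].species}:
            raise NetworkError(
                f"secretion references missing species {sec.species!r} in cell {sec.cell_id!r}"
            )
        if sec.medium_species not in medium_ids:
            raise NetworkError(f"secretion references unknown medium species {sec.medium_species!r}")
        if sec.ks == 0:  # a zero-rate secretion moves nothing
            continue
        reactions.append(
            Reaction(
                id=f"sec_{i}_{sec.cell_id}_{sec.species}",
                kind="secretion",
                substrates=[(f"{sec.cell_id}.{sec.species}", 1)],
                products=[(sec.medium_species, 1)],
                params=KineticParams(kf=sec.ks),
                transfer_scale=rho,
            )
        )

    for i, upt in enumerate(coupling.uptakes):
        if upt.cell_id not in by_id:
            raise NetworkError(f"uptake references unknown cell {upt.cell_id!r}")
        if upt.medium_species not in medium_ids:
            raise NetworkError(f"uptake references unknown medium species {upt.medium_species!r}")
        target = by_id[upt.cell_id]
        if upt.ligand not in {sp.id for sp in target.species}:
            raise NetworkError(
                f"uptake references missing ligand {upt.ligand!r} in cell {upt.cell_id!r}"
            )
        qlig = f"{upt.cell_id}.{upt.ligand}"
        if upt.mode == "as_transport":
            reactions.append(
                Reaction(
                    id=f"upt_{i}_{upt.cell_id}_{upt.ligand}",
                    kind="mass_action_irrev",
                    substrates=[(upt.medium_species, 1)],
                    products=[(qlig, 1)],
                    params=KineticParams(kf=upt.ku),
                    transfer_scale=1.0 / rho,
                )
            )
            continue
        # as_modifier: graft the medium species onto the receptor-activation
        # reaction in which the ligand acts as an activator modifier.
        hit = None
        for j, rxn in enumerate(reactions):
            if not rxn.id.startswith(f"{upt.cell_id}."):
                continue
            if rxn.kind in ("smm_induced", "smm_summed") and qlig in rxn.activators():
                hit = j
                break
        if hit is None:
            raise NetworkError(
                f"uptake: no receptor-activation reaction uses ligand {upt.ligand!r} "
                f"as an activator in cell {upt.cell_id!r}"
            )
        rxn = reactions[hit]
        p = rxn.params
        if rxn.kind == "smm_induced":
            if p.vmax is None:
                raise NetworkError(
                    f"uptake target reaction {rxn.id!r} must use the vmax form"
                )
            nact = len(rxn.activators())
            vmaxes = p.vmax if isinstance(p.vmax, list) else [p.vmax] * nact
            kas = p.ka if isinstance(p.ka, list) else [p.ka] * nact
            new_params = replace(
                p,
                vmax=list(vmaxes) + [upt.vmax if upt.vmax is not None else vmaxes[0]],
                ka=list(kas) + [upt.ka if upt.ka is not None else kas[0]],
                kcat=None,
            )
            reactions[hit] = replace(
                rxn,
                kind="smm_summed",
                modifiers=rxn.modifiers + [(upt.medium_species, "activator")],
                params=new_params,
            )
        else:  # already smm_summed
            reactions[hit] = replace(
                rxn,
                modifiers=rxn.modifiers + [(upt.medium_species, "activator")],
                params=replace(
                    p,
                    vmax=list(p.vmax) + [upt.vmax if upt.vmax is not None else p.vmax[0]],
                    ka=list(p.ka) + [upt.ka if upt.ka is not None else p.ka[0]],
                ),
            )

    for i, (sid, kd) in enumerate(coupling.medium_degradation):
        if kd <= 0:
            continue
        reactions.append(
            Reaction(
                id=f"meddeg_{i}_{sid}",
                kind="degradation",
                substrates=[(sid, 1)],
                params=KineticParams(kf=kd),
            )
        )

    net = PathwayNetwork(
        cell_id=model_id,
        species=species,
        reactions=reactions,
        input_ports=inputs,
        output_markers=markers,
    )
    return MultiCellModel(
        cells=list(cells), medium=list(medium), coupling=coupling, network=net, output_markers=markers
    )


def run_feedforward(
    sources: Sequence[PathwayNetwork],
    target: PathwayNetwork,
    coupling: CouplingMap,
    mapping: Sequence[tuple[str, str]],
    settings: SimulationSettings | None = None,
    *,
    perturb_sources: Callable[[PathwayNetwork], PathwayNetwork] | None = None,
    theta: float = 5.0,
) -> list[MarkerResponse]:
    """Staged feed-forward run (source cells -> medium -> target cell).

    ``mapping`` pairs (medium species, target input ligand).  Stage 1
    simulates the source cells (coupled to the medium through their
    secretions) to the endpoint; stage 2 clamps the target's mapped ligands at
    the stage-1 medium concentrations and reads the target's output markers as
    percent change versus the control (the same staging with unperturbed
    sources).  ``perturb_sources`` maps each source network to its perturbed
    version (e.g. genomic-profile application).
    """
    settings = settings or SimulationSettings()
    target_ids = {sp.id for sp in target.species}
    for med_sid, ligand in mapping:
        if ligand not in target_ids:
            raise NetworkError(f"feed-forward mapping: unknown target ligand {ligand!r}")

    def stage1(cells: Sequence[PathwayNetwork]) -> dict[str, float]:
        model = compose_coculture(cells, coupling, model_id="ff_sources")
        med_ids = {sp.id for sp in model.medium}
        for med_sid, _ in mapping:
            if med_sid not in med_ids:
                raise NetworkError(
                    f"feed-forward mapping: medium species {med_sid!r} is not produced by any source"
                )
        res = simulate(model.network, settings)
        return {med_sid: float(res.endpoint[med_sid]) for med_sid, _ in mapping}

    def stage2(inputs: dict[str, float]) -> SimulationResult:
        net = target.copy()
        lig_by_id = {lig: med for med, lig in mapping}
        for sp in net.species:
            if sp.id in lig_by_id:
                sp.initial_amount = inputs[lig_by_id[sp.id]]
                sp.clamped = True
        return simulate(net, settings)

    control_inputs = stage1(sources)
    if perturb_sources is None:
        perturbed_inputs = control_inputs
    else:
        perturbed_inputs = stage1([perturb_sources(c) for c in sources])

    control_res = stage2(control_inputs)
    perturbed_res = stage2(perturbed_inputs)
    return percent_change_readout(
        control_res, perturbed_res, target.output_markers, theta=theta
    )


# ---------------------------------------------------------------------------
# coupling YAML
# ---------------------------------------------------------------------------


def serialize_coupling(coupling: CouplingMap) -> str:
    """Canonical YAML for a coupling map (a ``coupling:`` document section)."""
    import yaml

    doc = {
        "coupling": {
            "secretions": [
                {
                    "cell": s.cell_id,
                    "species": s.species,
                    "medium_species": s.medium_species,
                    "ks": s.ks,
                }
                for s in coupling.secretions
            ],
            "uptakes": [
                {
                    "medium_species": u.medium_species,
                    "cell": u.cell_id,
                    "ligand": u.ligand,
                    "mode": u.mode,
                    **({"ka": u.ka} if u.ka is not None else {}),
                    **({"vmax": u.vmax} if u.vmax is not None else {}),
                    **({"ku": u.ku} if u.mode == "as_transport" else {}),
                }
                for u in coupling.uptakes
            ],
            "medium_degradation": [
                {"medium_species": sid, "kd": kd} for sid, kd in coupling.medium_degradation
            ],
            "volume_ratio": coupling.volume_ratio,
        }
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def parse_coupling(text: str) -> CouplingMap:
    """Parse the YAML ``coupling:`` section written by :func:`serialize_coupling`."""
    import yaml

    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "coupling" not in doc:
        raise NetworkError("coupling document must have a top-level 'coupling' key")
    raw = doc["coupling"] or {}
    secretions = tuple(
        Secretion(d["cell"], d["species"], d["medium_species"], float(d.get("ks", 1.0)))
        for d in raw.get("secretions") or []
    )
    uptakes = tuple(
        Uptake(
            d["medium_species"],
            d["cell"],
            d["ligand"],
            d.get("mode", "as_modifier"),
            ka=d.get("ka"),
            vmax=d.get("vmax"),
            ku=float(d.get("ku", 1.0)),
        )
        for d in raw.get("uptakes") or []
    )
    meddeg = tuple(
        (d["medium_species"], float(d["kd"])) for d in raw.get("medium_degradation") or []
    )
    return CouplingMap(
        secretions=secretions,
        uptakes=uptakes,
        medium_degradation=meddeg,
        volume_ratio=float(raw.get("volume_ratio", 1.0)),
    )
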