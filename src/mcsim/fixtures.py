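"""Self-contained, seeded example models.

The proprietary full-genome network library behind the original platform is
not distributable, so this module generates small curated stand-ins that
exercise every part of the simulator:

* ``gpcr_camp``         -- prostaglandin GPCR signaling: PGE2 activates
  adenylyl cyclase through PTGER4/G-alpha-s (activation arm) and inhibits it
  through GPR44/G-alpha-i (inhibition arm); readout cAMP.
* ``ifng_stat1``        -- interferon-gamma receptor signaling through
  JAK1/JAK2 to STAT1 dimerization and NF-kB translocation, with a
  summed-SMM PIK3CA node driven by GAB2 and IRS2.
* ``inflammation_trio`` -- keratinocyte-, dendritic-cell- and helper-T-like
  cells secreting ten inflammatory markers into a shared medium, stimulated
  with LPS (TLR4 arm) or Pam3CSK4 (TLR2/1 arm), plus a synthetic "observed"
  response table for the trend-match pipeline.
* ``mm_dc_pair``        -- a myeloma-like secretory cell with two divergent
  genomic profiles (a weak and a strong immunosuppressive signature) feeding
  a dendritic-like cell whose maturation markers are inhibited by IL-10 and
  TGF-beta-1.

All kinetic parameters are curated, documented here, and frozen; directional
behavior (not magnitudes) is the tested contract.  Every fixture is
byte-identical for a fixed :class:`FixtureSpec`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .multicell import CouplingMap, Secretion, Uptake, compose_coculture, serialize_coupling
from .network_model import (
    KineticParams,
    PathwayNetwork,
    Reaction,
    Species,
    serialize_network,
)
from .ode_engine import SimulationSettings, percent_change_readout, simulate
from .perturbation import (
    AgonistDose,
    EffectLibrary,
    GenomicProfile,
    MutationRecord,
    apply_agonist,
    profile_to_csv,
)

__all__ = [
    "DC_MARKERS",
    "FIXTURE_NAMES",
    "KDEG",
    "MM_MARKERS",
    "TRIO_MARKERS",
    "FixtureSpec",
    "build_gpcr_fixture",
    "build_ifng_fixture",
    "build_inflammation_trio",
    "build_mm_dc_pair",
    "disable_inhibition_arm",
    "jitter_network",
    "lps_trio_reference_panel",
    "write_fixture",
]

FIXTURE_NAMES = ("gpcr_camp", "ifng_stat1", "inflammation_trio", "mm_dc_pair")

#: first-order decay for secreted markers: half-life 8 h
KDEG = math.log(2) / 8.0

TRIO_MARKERS = ("CCL3", "CCL4", "CCL5", "CSF2", "IL12B", "IL1A", "IL6", "IL8", "TNF", "VEGFA")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic fixture request: same (name, seed, jitter) -> identical
    documents.  ``jitter`` multiplies every kinetic parameter by a seeded
    log-uniform factor in the given range; it is off (None) by default so the
    canonical parameters are used."""

    name: str
    seed: int = 17
    jitter: tuple[float, float] | None = None

    def __post_init__(self):
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}")
        if self.jitter is not None and not (0 < self.jitter[0] <= self.jitter[1]):
            raise ValueError("jitter range must satisfy 0 < lo <= hi")


DEFAULT_JITTER = (1.0 / 3.0, 3.0)


def jitter_network(net: PathwayNetwork, rng: np.random.Generator, lo: float = DEFAULT_JITTER[0], hi: float = DEFAULT_JITTER[1]) -> PathwayNetwork:
    """Multiply every kinetic parameter by an independent log-uniform factor
    in [lo, hi]; used for property tests and synthetic observed data."""
    out = net.copy()
    for rxn in out.reactions:
        p = rxn.params
        for name in ("vmax", "km", "kcat", "ka", "ki", "kf", "kr"):
            val = getattr(p, name)
            if val is None:
                continue
            if isinstance(val, list):
                setattr(p, name, [v * float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for v in val])
            else:
                setattr(p, name, val * float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return out


def _maybe_jitter(net: PathwayNetwork, spec: FixtureSpec) -> PathwayNetwork:
    if spec.jitter is None:
        return net
    rng = np.random.default_rng(spec.seed)
    return jitter_network(net, rng, *spec.jitter)


# ---------------------------------------------------------------------------
# GPCR / cAMP pathway
# ---------------------------------------------------------------------------


def build_gpcr_fixture(spec: FixtureSpec | None = None) -> PathwayNetwork:
    """Prostaglandin GPCR network with an activation arm (PTGER4 ->
    G-alpha-s -> adenylyl cyclase) and an inhibition arm (GPR44 ->
    G-alpha-i).  The G-protein pools cycle through purely mass-action
    reactions, so receptor, G-protein and cyclase moieties are conserved.
    """
    spec = spec or FixtureSpec("gpcr_camp")
    sp = [
        Species("PGE2", "prostaglandin E2", "ligand", initial_amount=0.0),
        Species("PTGER4", "EP4 receptor", "receptor", initial_amount=10.0, gene="PTGER4"),
        Species("PTGER4_act", "EP4, ligand-bound", "receptor_active", gene="PTGER4"),
        Species("GPR44", "DP2 receptor", "receptor", initial_amount=10.0, gene="PTGDR2"),
        Species("GPR44_act", "DP2, ligand-bound", "receptor_active", gene="PTGDR2"),
        Species("GDP_GNAS_GNBC", "inactive Gs heterotrimer", "g_protein_complex", initial_amount=20.0),
        Species("GDP_GNAI_GNBC", "inactive Gi heterotrimer", "g_protein_complex", initial_amount=20.0),
        Species("GTP_GNAS", "active G-alpha-s", "subunit", gene="GNAS"),
        Species("GTP_GNAI", "active G-alpha-i", "subunit", gene="GNAI1"),
        Species("GNBC", "free G-beta-gamma", "subunit"),
        Species("ADCY1", "adenylyl cyclase 1", "enzyme", initial_amount=10.0, gene="ADCY1"),
        Species("ADCY1_act", "adenylyl cyclase 1, active", "enzyme_active", gene="ADCY1"),
        Species("ATP", "ATP", "metabolite", initial_amount=100.0),
        Species("cAMP", "cyclic AMP", "secreted_marker"),
    ]
    P = KineticParams
    rx = [
        Reaction("bind_ptger4", "smm_induced", [("PTGER4", 1)], [("PTGER4_act", 1)],
                 [("PGE2", "activator")], P(vmax=5.0, ka=1.0, km=5.0)),
        Reaction("deact_ptger4", "mass_action_irrev", [("PTGER4_act", 1)], [("PTGER4", 1)], [], P(kf=0.5)),
        Reaction("bind_gpr44", "smm_induced", [("GPR44", 1)], [("GPR44_act", 1)],
                 [("PGE2", "activator")], P(vmax=5.0, ka=1.0, km=5.0)),
        Reaction("deact_gpr44", "mass_action_irrev", [("GPR44_act", 1)], [("GPR44", 1)], [], P(kf=0.5)),
        Reaction("gnas_activate", "mass_action_irrev", [("GDP_GNAS_GNBC", 1)],
                 [("GTP_GNAS", 1), ("GNBC", 1)], [("PTGER4_act", "activator")], P(kf=0.05)),
        Reaction("gnas_recycle", "mass_action_irrev", [("GTP_GNAS", 1), ("GNBC", 1)],
                 [("GDP_GNAS_GNBC", 1)], [], P(kf=0.5)),
        Reaction("gnai_activate", "mass_action_irrev", [("GDP_GNAI_GNBC", 1)],
                 [("GTP_GNAI", 1), ("GNBC", 1)], [("GPR44_act", "activator")], P(kf=0.05)),
        Reaction("gnai_recycle", "mass_action_irrev", [("GTP_GNAI", 1), ("GNBC", 1)],
                 [("GDP_GNAI_GNBC", 1)], [], P(kf=0.5)),
        Reaction("adcy_basal", "mass_action_irrev", [("ADCY1", 1)], [("ADCY1_act", 1)], [], P(kf=0.02)),
        Reaction("adcy_activate", "smm_induced", [("ADCY1", 1)], [("ADCY1_act", 1)],
                 [("GTP_GNAS", "activator"), ("GTP_GNAI", "inhibitor")],
                 P(vmax=10.0, ka=2.0, km=5.0, ki=2.0)),
        Reaction("adcy_deact", "mass_action_irrev", [("ADCY1_act", 1)], [("ADCY1", 1)], [], P(kf=1.0)),
        Reaction("camp_prod", "smm_induced", [("ATP", 1)], [("cAMP", 1)],
                 [("ADCY1_act", "activator")], P(kcat=2.0, km=20.0)),
        Reaction("atp_supply", "synthesis", [], [("ATP", 1)], [], P(kf=5.0)),
        Reaction("atp_turnover", "degradation", [("ATP", 1)], [], [], P(kf=0.05)),
        Reaction("camp_decay", "degradation", [("cAMP", 1)], [], [], P(kf=KDEG)),
    ]
    net = PathwayNetwork(
        cell_id="gpcr_cell",
        species=sp,
        reactions=rx,
        input_ports=[("PGE2", "PGE2")],
        output_markers=["cAMP"],
    )
    return _maybe_jitter(net, spec)


def disable_inhibition_arm(net: PathwayNetwork) -> PathwayNetwork:
    """Copy of the GPCR fixture with the inhibitory DP2 receptor emptied, so
    PGE2 acts through the activation arm alone."""
    out = net.copy()
    for sp in out.species:
        if sp.id == "GPR44":
            sp.initial_amount = 0.0
    return out


# ---------------------------------------------------------------------------
# IFN-gamma / STAT1 pathway
# ---------------------------------------------------------------------------


def build_ifng_fixture(spec: FixtureSpec | None = None) -> PathwayNetwork:
    spec = spec or FixtureSpec("ifng_stat1")
    sp = [
        Species("IFNG", "interferon gamma", "ligand"),
        Species("IFNGR1", "IFNG receptor alpha chain", "receptor", initial_amount=10.0, gene="IFNGR1"),
        Species("JAK1", "Janus kinase 1", "kinase", initial_amount=10.0, gene="JAK1"),
        Species("IFNGR1_JAK1", "receptor alpha / JAK1", "receptor", gene="IFNGR1"),
        Species("IFNGR2", "IFNG receptor beta chain", "receptor", initial_amount=10.0, gene="IFNGR2"),
        Species("JAK2", "Janus kinase 2", "kinase", initial_amount=10.0, gene="JAK2"),
        Species("IFNGR2_JAK2", "receptor beta / JAK2", "receptor", gene="IFNGR2"),
        Species("IFNGR_JAK", "assembled receptor-JAK complex", "receptor"),
        Species("IFNGR_JAK_act", "ligand-activated receptor complex", "receptor_active"),
        Species("FYN", "FYN kinase", "kinase", initial_amount=10.0, gene="FYN"),
        Species("FYN_act", "FYN, active", "kinase", gene="FYN"),
        Species("GAB2", "GAB2 adapter", "adapter", initial_amount=10.0, gene="GAB2"),
        Species("GAB2_act", "GAB2, active", "adapter", gene="GAB2"),
        Species("IRS2", "IRS2 adapter", "adapter", initial_amount=10.0, gene="IRS2"),
        Species("IRS2_act", "IRS2, active", "adapter", gene="IRS2"),
        Species("PIK3CA", "PI3K catalytic subunit", "enzyme", initial_amount=10.0, gene="PIK3CA"),
        Species("PIK3CA_act", "PI3K, active", "enzyme_active", gene="PIK3CA"),
        Species("CHUK", "IKK-alpha", "kinase", initial_amount=10.0, gene="CHUK"),
        Species("IKBKB", "IKK-beta", "kinase", initial_amount=10.0, gene="IKBKB"),
        Species("CHUK_IKBKB", "IKK complex", "kinase"),
        Species("NFKB_cyt", "cytosolic NF-kB", "transcription_factor", initial_amount=10.0, gene="NFKB1"),
        Species("NFKB_nuc", "nuclear NF-kB", "tf_active", gene="NFKB1"),
        Species("STAT1", "STAT1", "transcription_factor", initial_amount=10.0, gene="STAT1"),
        Species("STAT1_act", "phospho-STAT1", "tf_active", gene="STAT1"),
        Species("STAT1_dimer", "STAT1 homodimer", "tf_active", gene="STAT1"),
    ]
    P = KineticParams
    rx = [
        Reaction("bind_r1j1", "mass_action_irrev", [("IFNGR1", 1), ("JAK1", 1)],
                 [("IFNGR1_JAK1", 1)], [], P(kf=0.05)),
        Reaction("bind_r2j2", "mass_action_irrev", [("IFNGR2", 1), ("JAK2", 1)],
                 [("IFNGR2_JAK2", 1)], [], P(kf=0.05)),
        Reaction("assemble_receptor", "mass_action_irrev",
                 [("IFNGR1_JAK1", 1), ("IFNGR2_JAK2", 1)], [("IFNGR_JAK", 1)], [], P(kf=0.05)),
        Reaction("receptor_activate", "smm_induced", [("IFNGR_JAK", 1)], [("IFNGR_JAK_act", 1)],
                 [("IFNG", "activator")], P(vmax=5.0, ka=2.0, km=3.0)),
        Reaction("receptor_deact", "mass_action_irrev", [("IFNGR_JAK_act", 1)],
                 [("IFNGR_JAK", 1)], [], P(kf=0.2)),
        Reaction("fyn_activate", "smm_induced", [("FYN", 1)], [("FYN_act", 1)],
                 [("IFNGR_JAK_act", "activator")], P(vmax=5.0, ka=1.0, km=3.0)),
        Reaction("fyn_deact", "mass_action_irrev", [("FYN_act", 1)], [("FYN", 1)], [], P(kf=0.2)),
        Reaction("gab2_activate", "smm_induced", [("GAB2", 1)], [("GAB2_act", 1)],
                 [("FYN_act", "activator")], P(vmax=4.0, ka=1.0, km=3.0)),
        Reaction("gab2_deact", "mass_action_irrev", [("GAB2_act", 1)], [("GAB2", 1)], [], P(kf=0.2)),
        Reaction("irs2_activate", "smm_induced", [("IRS2", 1)], [("IRS2_act", 1)],
                 [("FYN_act", "activator")], P(vmax=3.0, ka=2.0, km=3.0)),
        Reaction("irs2_deact", "mass_action_irrev", [("IRS2_act", 1)], [("IRS2", 1)], [], P(kf=0.2)),
        # summed-SMM node: flux is the sum of one saturating term per activator
        Reaction("pik3ca_activate", "smm_summed", [("PIK3CA", 1)], [("PIK3CA_act", 1)],
                 [("GAB2_act", "activator"), ("IRS2_act", "activator")],
                 P(vmax=[4.0, 2.0], ka=[1.0, 2.0], km=3.0)),
        Reaction("pik3ca_deact", "mass_action_irrev", [("PIK3CA_act", 1)], [("PIK3CA", 1)], [], P(kf=0.2)),
        Reaction("ikk_assemble", "mass_action_irrev", [("CHUK", 1), ("IKBKB", 1)],
                 [("CHUK_IKBKB", 1)], [("PIK3CA_act", "activator")], P(kf=0.01)),
        Reaction("ikk_dissoc", "mass_action_irrev", [("CHUK_IKBKB", 1)],
                 [("CHUK", 1), ("IKBKB", 1)], [], P(kf=0.2)),
        Reaction("nfkb_translocate", "smm_induced", [("NFKB_cyt", 1)], [("NFKB_nuc", 1)],
                 [("CHUK_IKBKB", "activator")], P(vmax=4.0, ka=1.0, km=3.0)),
        Reaction("nfkb_export", "mass_action_irrev", [("NFKB_nuc", 1)], [("NFKB_cyt", 1)], [], P(kf=0.1)),
        Reaction("stat1_activate", "smm_induced", [("STAT1", 1)], [("STAT1_act", 1)],
                 [("IFNGR_JAK_act", "activator")], P(vmax=2.0, ka=4.0, km=3.0)),
        Reaction("stat1_deact", "mass_action_irrev", [("STAT1_act", 1)], [("STAT1", 1)], [], P(kf=0.5)),
        Reaction("stat1_dimerize", "mass_action_irrev", [("STAT1_act", 2)],
                 [("STAT1_dimer", 1)], [], P(kf=0.02)),
    ]
    net = PathwayNetwork(
        cell_id="ifng_cell",
        species=sp,
        reactions=rx,
        input_ports=[("IFNG", "IFNG")],
        output_markers=["STAT1_dimer", "NFKB_nuc"],
    )
    return _maybe_jitter(net, spec)


# ---------------------------------------------------------------------------
# three-cell inflammation model
# ---------------------------------------------------------------------------

# per-cell production weight (vmax, a.u./h) for each of the ten markers;
# the three profiles differ so the cells have distinct output signatures.
_TRIO_WEIGHTS = {
    "KER": dict(CCL3=1.0, CCL4=0.8, CCL5=0.6, CSF2=1.2, IL12B=0.3,
                IL1A=1.5, IL6=2.5, IL8=3.0, TNF=1.0, VEGFA=0.8),
    "DC": dict(CCL3=2.0, CCL4=2.2, CCL5=1.5, CSF2=1.0, IL12B=2.5,
               IL1A=1.2, IL6=3.0, IL8=3.5, TNF=2.8, VEGFA=0.5),
    "HTL": dict(CCL3=0.6, CCL4=0.7, CCL5=1.8, CSF2=1.5, IL12B=0.4,
                IL1A=0.5, IL6=1.2, IL8=1.0, TNF=1.5, VEGFA=0.4),
}

# (receptor, ligand species, agonist name) complement per cell
_TRIO_RECEPTORS = {
    "KER": [("TLR4", "LPS_lig", "LPS"), ("TLR21", "PAM_lig", "Pam3CSK4")],
    "DC": [("TLR4", "LPS_lig", "LPS"), ("TLR21", "PAM_lig", "Pam3CSK4")],
    "HTL": [("IL1R", "IL1A_in", "IL1A")],
}


def _immune_cell(cell_id: str, receptors, weights) -> PathwayNetwork:
    P = KineticParams
    sp = [Species(lig, f"{ag} ligand", "ligand") for _, lig, ag in receptors]
    for rec, _, _ in receptors:
        sp.append(Species(rec, f"{rec} receptor", "receptor", initial_amount=10.0, gene=rec))
        sp.append(Species(f"{rec}_act", f"{rec}, ligand-bound", "receptor_active", gene=rec))
    sp.append(Species("NFKB_cyt", "cytosolic NF-kB", "transcription_factor", initial_amount=10.0))
    sp.append(Species("NFKB_nuc", "nuclear NF-kB", "tf_active"))
    sp.append(Species("PRE", "translational precursor pool", "metabolite", initial_amount=100.0))
    for m in TRIO_MARKERS:
        sp.append(Species(m, m, "secreted_marker", gene=m))

    rx = []
    for rec, lig, _ in receptors:
        rx.append(Reaction(f"act_{rec}", "smm_induced", [(rec, 1)], [(f"{rec}_act", 1)],
                           [(lig, "activator")], P(vmax=5.0, ka=2.0, km=3.0)))
        rx.append(Reaction(f"deact_{rec}", "mass_action_irrev",
                           [(f"{rec}_act", 1)], [(rec, 1)], [], P(kf=0.2)))
    acts = [f"{rec}_act" for rec, _, _ in receptors]
    if len(acts) >= 2:
        rx.append(Reaction("nfkb_translocate", "smm_summed", [("NFKB_cyt", 1)], [("NFKB_nuc", 1)],
                           [(a, "activator") for a in acts],
                           P(vmax=[3.0] * len(acts), ka=[1.0] * len(acts), km=3.0)))
    else:
        rx.append(Reaction("nfkb_translocate", "smm_induced", [("NFKB_cyt", 1)], [("NFKB_nuc", 1)],
                           [(acts[0], "activator")], P(vmax=3.0, ka=1.0, km=3.0)))
    rx.append(Reaction("nfkb_export", "mass_action_irrev",
                       [("NFKB_nuc", 1)], [("NFKB_cyt", 1)], [], P(kf=0.1)))
    rx.append(Reaction("pre_supply", "synthesis", [], [("PRE", 1)], [], P(kf=10.0)))
    rx.append(Reaction("pre_turnover", "degradation", [("PRE", 1)], [], [], P(kf=0.1)))
    for m in TRIO_MARKERS:
        rx.append(Reaction(f"prod_{m}", "smm_induced", [("PRE", 1)], [(m, 1)],
                           [("NFKB_nuc", "activator")], P(vmax=weights[m], ka=1.0, km=50.0)))
        rx.append(Reaction(f"basal_{m}", "synthesis", [], [(m, 1)], [], P(kf=0.5)))
        rx.append(Reaction(f"decay_{m}", "degradation", [(m, 1)], [], [], P(kf=KDEG)))

    return PathwayNetwork(
        cell_id=cell_id,
        species=sp,
        reactions=rx,
        input_ports=[(lig, ag) for _, lig, ag in receptors],
        output_markers=list(TRIO_MARKERS),
    )


def build_inflammation_trio(
    spec: FixtureSpec | None = None,
) -> tuple[list[PathwayNetwork], CouplingMap, pd.DataFrame]:
    """Three coupled immune-like cells plus a synthetic observed-response table.

    Returns (cells [KER, DC, HTL], coupling, observed table).  The observed
    table is generated by re-simulating the LPS response with seeded
    log-uniform parameter jitter and multiplicative log-normal noise
    (sigma=0.2) on the endpoints, mimicking inter-replicate immunoassay
    spread, so the trend-match pipeline has a reproducible non-trivial target.
    """
    spec = spec or FixtureSpec("inflammation_trio")
    cells = [
        _maybe_jitter(_immune_cell(cid, _TRIO_RECEPTORS[cid], _TRIO_WEIGHTS[cid]), spec)
        for cid in ("KER", "DC", "HTL")
    ]
    secretions = tuple(
        Secretion(cid, m, f"med_{m}", ks=0.5) for cid in ("KER", "DC", "HTL") for m in TRIO_MARKERS
    )
    uptakes = (
        Uptake("med_IL1A", "HTL", "IL1A_in", "as_modifier", ka=2.0, vmax=5.0),
        Uptake("med_IL6", "HTL", "IL1A_in", "as_modifier", ka=4.0, vmax=2.0),
    )
    coupling = CouplingMap(
        secretions=secretions,
        uptakes=uptakes,
        medium_degradation=tuple((f"med_{m}", KDEG) for m in TRIO_MARKERS),
        volume_ratio=1.0,
    )
    observed = _trio_observed_table(cells, coupling, spec)
    return cells, coupling, observed


def _trio_observed_table(cells, coupling, spec: FixtureSpec) -> pd.DataFrame:
    """Synthetic observed LPS response: jittered-parameter simulation with
    multiplicative log-normal endpoint noise (sigma = 0.2)."""
    rng = np.random.default_rng(spec.seed + 1)
    jittered = [jitter_network(c, rng, 1 / 1.5, 1.5) for c in cells]
    model = compose_coculture(jittered, coupling)
    settings = SimulationSettings()
    control = simulate(model.network, settings)
    dosed = apply_agonist(model.network, AgonistDose("LPS", 10.0))
    stim = simulate(dosed, settings)
    med = [f"med_{m}" for m in TRIO_MARKERS]
    noise = np.exp(rng.normal(0.0, 0.2, size=len(med)))
    rows = []
    for sid, m, nz in zip(med, TRIO_MARKERS, noise):
        c = float(control.endpoint[sid])
        p = float(stim.endpoint[sid]) * nz
        rows.append({"marker": m, "percent_change": 100.0 * (p - c) / c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# myeloma + dendritic-cell pair
# ---------------------------------------------------------------------------

_MM_WEIGHTS = dict(IL6=2.0, IL10=1.8, TGFB1=1.2, VEGFA=1.5, CD47=0.8, FASL=0.6, PDL1=1.6)
_DC_WEIGHTS = dict(CD80=2.0, CD86=1.8, IL2=1.2, IFNG=1.5, IL12B=1.0)

MM_MARKERS = tuple(_MM_WEIGHTS)
DC_MARKERS = tuple(_DC_WEIGHTS)


def _mm_cell(cell_id: str = "MM") -> PathwayNetwork:
    """Myeloma-like secretory cell: constitutive RAS -> STAT3 signaling
    drives production of immunosuppressive cytokines and surface markers."""
    P = KineticParams
    sp = [
        Species("RAS", "RAS GTPase", "enzyme", initial_amount=10.0, gene="NRAS"),
        Species("RAS_act", "RAS, GTP-bound", "enzyme_active", gene="NRAS"),
        Species("STAT3", "STAT3", "transcription_factor", initial_amount=10.0, gene="STAT3"),
        Species("STAT3_act", "phospho-STAT3", "tf_active", gene="STAT3"),
        Species("PRE", "translational precursor pool", "metabolite", initial_amount=100.0),
    ]
    for m in MM_MARKERS:
        gene = "CD274" if m == "PDL1" else m
        sp.append(Species(m, m, "secreted_marker", gene=gene))
    rx = [
        Reaction("ras_basal", "mass_action_irrev", [("RAS", 1)], [("RAS_act", 1)], [], P(kf=0.05)),
        Reaction("ras_deact", "mass_action_irrev", [("RAS_act", 1)], [("RAS", 1)], [], P(kf=0.5)),
        Reaction("stat3_activate", "smm_induced", [("STAT3", 1)], [("STAT3_act", 1)],
                 [("RAS_act", "activator")], P(vmax=1.0, ka=1.0, km=3.0)),
        Reaction("stat3_deact", "mass_action_irrev", [("STAT3_act", 1)], [("STAT3", 1)], [], P(kf=0.2)),
        Reaction("pre_supply", "synthesis", [], [("PRE", 1)], [], P(kf=10.0)),
        Reaction("pre_turnover", "degradation", [("PRE", 1)], [], [], P(kf=0.1)),
    ]
    for m in MM_MARKERS:
        rx.append(Reaction(f"prod_{m}", "smm_induced", [("PRE", 1)], [(m, 1)],
                           [("STAT3_act", "activator")], P(vmax=_MM_WEIGHTS[m], ka=5.0, km=50.0)))
        rx.append(Reaction(f"basal_{m}", "synthesis", [], [(m, 1)], [], P(kf=0.1)))
        rx.append(Reaction(f"decay_{m}", "degradation", [(m, 1)], [], [], P(kf=KDEG)))
    return PathwayNetwork(cell_id=cell_id, species=sp, reactions=rx,
                          input_ports=[], output_markers=list(MM_MARKERS))


def _dc_cell(cell_id: str = "DC") -> PathwayNetwork:
    """Dendritic-like cell: maturation markers produced constitutively and
    noncompetitively inhibited by the suppressive ligands IL-10 and TGF-b1."""
    P = KineticParams
    sp = [
        Species("IL10_in", "sensed IL-10", "ligand"),
        Species("TGFB1_in", "sensed TGF-beta-1", "ligand"),
        Species("DCACT", "constitutive maturation drive", "transcription_factor", initial_amount=10.0),
        Species("PRE", "translational precursor pool", "metabolite", initial_amount=100.0),
    ]
    for m in DC_MARKERS:
        sp.append(Species(m, m, "secreted_marker", gene=m))
    rx = [
        Reaction("pre_supply", "synthesis", [], [("PRE", 1)], [], P(kf=10.0)),
        Reaction("pre_turnover", "degradation", [("PRE", 1)], [], [], P(kf=0.1)),
    ]
    for m in DC_MARKERS:
        rx.append(Reaction(f"prod_{m}", "smm_induced", [("PRE", 1)], [(m, 1)],
                           [("DCACT", "activator"), ("IL10_in", "inhibitor"), ("TGFB1_in", "inhibitor")],
                           P(vmax=_DC_WEIGHTS[m], ka=5.0, km=50.0, ki=[20.0, 20.0])))
        rx.append(Reaction(f"basal_{m}", "synthesis", [], [(m, 1)], [], P(kf=0.05)))
        rx.append(Reaction(f"decay_{m}", "degradation", [(m, 1)], [], [], P(kf=KDEG)))
    return PathwayNetwork(cell_id=cell_id, species=sp, reactions=rx,
                          input_ports=[("IL10_in", "IL10"), ("TGFB1_in", "TGFB1")],
                          output_markers=list(DC_MARKERS))


def _mm_effect_library() -> EffectLibrary:
    return EffectLibrary({("STAT3", "Y640F"): "deleterious", ("TP53", "P72R"): "neutral"})


def _mm_profiles() -> dict[str, GenomicProfile]:
    """Two divergent genomic signatures.  The weak profile (MM.1S-like)
    carries an activating RAS mutation; the strong profile (U266B1-like)
    additionally carries an activating STAT3 mutation acting directly on
    marker production, so it is marker-wise at least as immunosuppressive."""
    ras = MutationRecord(
        gene="NRAS", variant="Q61K", gene_class="oncogene",
        predictor_calls=(("FATHMM", "deleterious"), ("MutationAssessor", "deleterious"),
                         ("PolyPhen", "deleterious"), ("PROVEAN", "neutral"), ("SIFT", "deleterious")),
    )
    stat3 = MutationRecord(gene="STAT3", variant="Y640F", gene_class="oncogene",
                           library_effect="deleterious")
    tp53_neutral = MutationRecord(gene="TP53", variant="P72R", gene_class="tumor_suppressor",
                                  library_effect="neutral")
    vus = MutationRecord(
        gene="KRAS", variant="A59G", gene_class="oncogene",
        predictor_calls=(("FATHMM", "deleterious"), ("SIFT", "neutral")),  # tie -> unknown
    )
    weak = GenomicProfile("MM1S_like", records=(ras, tp53_neutral, vus))
    strong = GenomicProfile("U266B1_like", records=(ras, stat3, tp53_neutral))
    return {"weak": weak, "strong": strong}


@dataclass
class MmDcPair:
    mm: PathwayNetwork
    dc: PathwayNetwork
    profiles: dict[str, GenomicProfile]
    effect_library: EffectLibrary
    coupling: CouplingMap
    mapping: tuple[tuple[str, str], ...]  # (medium species, DC ligand)


def build_mm_dc_pair(spec: FixtureSpec | None = None) -> MmDcPair:
    spec = spec or FixtureSpec("mm_dc_pair")
    mm = _maybe_jitter(_mm_cell(), spec)
    dc = _maybe_jitter(_dc_cell(), spec)
    secretions = tuple(
        Secretion("MM", m, f"med_{m}", ks=0.5) for m in ("IL6", "IL10", "TGFB1", "VEGFA")
    )
    coupling = CouplingMap(
        secretions=secretions,
        medium_degradation=tuple((f"med_{m}", KDEG) for m in ("IL6", "IL10", "TGFB1", "VEGFA")),
    )
    mapping = (("med_IL10", "IL10_in"), ("med_TGFB1", "TGFB1_in"))
    return MmDcPair(mm=mm, dc=dc, profiles=_mm_profiles(),
                    effect_library=_mm_effect_library(), coupling=coupling, mapping=mapping)


# ---------------------------------------------------------------------------
# bundled reference trend panel
# ---------------------------------------------------------------------------


def lps_trio_reference_panel() -> pd.DataFrame:
    """Bundled ten-marker trend panel for the LPS-stimulated three-cell
    inflammation model: predicted vs observed direction labels, with CCL5 the
    single discordant marker.  This is the worked example for the trend-match
    statistics (9/10 matches)."""
    rows = [
        ("CCL3", "up", "up"),
        ("CCL4", "up", "up"),
        ("CCL5", "up", "down"),
        ("CSF2", "up", "up"),
        ("IL12B", "down", "down"),
        ("IL1A", "up", "up"),
        ("IL6", "up", "up"),
        ("IL8", "up", "up"),
        ("TNF", "up", "up"),
        ("VEGFA", "down", "down"),
    ]
    return pd.DataFrame(rows, columns=["marker", "predicted", "observed"])


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------


def write_fixture(name: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write the named fixture's files (network YAMLs, coupling YAML, profile
    CSVs, observed CSV) under ``outdir``; byte-identical per (name, seed)."""
    spec = FixtureSpec(name, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(fname: str, text: str) -> None:
        path = outdir / fname
        path.write_text(text, encoding="utf-8", newline="\n")
        written.append(path)

    if name == "gpcr_camp":
        emit("gpcr_cell.network.yaml", serialize_network(build_gpcr_fixture(spec)))
    elif name == "ifng_stat1":
        emit("ifng_cell.network.yaml", serialize_network(build_ifng_fixture(spec)))
    elif name == "inflammation_trio":
        cells, coupling, observed = build_inflammation_trio(spec)
        for cell in cells:
            emit(f"{cell.cell_id}.network.yaml", serialize_network(cell))
        emit("coupling.yaml", serialize_coupling(coupling))
        buf = io.StringIO()
        observed.to_csv(buf, index=False)
        emit("observed_lps.csv", buf.getvalue())
        buf = io.StringIO()
        lps_trio_reference_panel().to_csv(buf, index=False)
        emit("reference_trend_panel.csv", buf.getvalue())
    elif name == "mm_dc_pair":
        pair = build_mm_dc_pair(spec)
        emit("MM.network.yaml", serialize_network(pair.mm))
        emit("DC.network.yaml", serialize_network(pair.dc))
        emit("coupling.yaml", serialize_coupling(pair.coupling))
        for label, profile in pair.profiles.items():
            emit(f"profile_{label}_{profile.profile_id}.csv", profile_to_csv(profile))
    else:  # pragma: no cover
        raise ValueError(name)
    return written
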