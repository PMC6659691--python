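"""Agonist dosing and genomic-lesion semantics.

Agonists are mapped to their input ligand species and set that ligand's
initial concentration.  Genomic lesions (point mutations classified by a
learnt effect library with predictor-consensus fallback, and copy-number
variants) become deterministic multipliers on species scales:

* deleterious oncogene mutation  -> gain of function: activity_scale * g
* deleterious tumor-suppressor   -> loss of function: activity_scale * l
* CNV amplification              -> expression_scale * a
* CNV deletion                   -> expression_scale = 0

"Activity level" scales the fluxes the gene's protein catalyses (or its
inhibitory strength); "expression level" scales synthesis flux and initial
amounts.  All operations are pure: the input network is never modified.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .network_model import NetworkError, PathwayNetwork

__all__ = [
    "AgonistDose",
    "MutationRecord",
    "EffectLibrary",
    "GenomicProfile",
    "apply_agonist",
    "consensus_effect",
    "apply_genomic_profile",
    "read_profile_csv",
    "read_effect_library_csv",
]

GENE_CLASSES = frozenset({"oncogene", "tumor_suppressor", "other"})
EFFECTS = frozenset({"deleterious", "neutral", "unknown"})
CNV_STATES = frozenset({"none", "amplification", "deletion"})


@dataclass(frozen=True)
class AgonistDose:
    """An agonist applied at a dose (ug/ml or a.u.); the conversion factor
    maps dose to ligand concentration in a.u. (default 1 a.u. per ug/ml)."""

    agonist: str
    dose: float
    conversion: float = 1.0

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    variant: str = ""
    gene_class: str = "other"
    predictor_calls: tuple[tuple[str, str], ...] = ()
    library_effect: str | None = None
    cnv: str = "none"

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.cnv not in CNV_STATES:
            raise ValueError(f"unknown cnv state {self.cnv!r}")
        for _, call in self.predictor_calls:
            if call not in EFFECTS:
                raise ValueError(f"unknown predictor call {call!r}")
        if not self.predictor_calls and self.library_effect is None and self.cnv == "none":
            raise ValueError(
                f"{self.gene}: record needs predictor calls, a library effect, or a CNV"
            )


class EffectLibrary:
    """gene+variant -> effect call; misses return None (absence, not error)."""

    def __init__(self, entries: Mapping[tuple[str, str], str] | None = None):
        self._entries = dict(entries or {})
        for effect in self._entries.values():
            if effect not in EFFECTS:
                raise ValueError(f"unknown effect {effect!r} in library")

    def lookup(self, gene: str, variant: str) -> str | None:
        return self._entries.get((gene, variant))

    def __len__(self) -> int:
        return len(self._entries)


@dataclass(frozen=True)
class GenomicProfile:
    """A cell line's lesion list plus the scale policy (gain g, loss l,
    amplification a).  Direction is the modeled claim; magnitudes are policy."""

    profile_id: str
    records: tuple[MutationRecord, ...] = ()
    gain_factor: float = 2.0
    loss_factor: float = 0.0
    amplification_factor: float = 2.0

    def __post_init__(self):
        if not self.gain_factor > 1:
            raise ValueError("gain_factor must be > 1")
        if not (0 <= self.loss_factor < 1):
            raise ValueError("loss_factor must be in [0, 1)")
        if not self.amplification_factor > 1:
            raise ValueError("amplification_factor must be > 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def apply_agonist(net: PathwayNetwork, dose: AgonistDose) -> PathwayNetwork:
    """Return a copy of the network with the agonist's ligand(s) initialized
    to dose * conversion.  In a composed multi-cell network the same agonist
    may have one port per cell; all of them are set.  Dose 0 returns a
    network identical to the control."""
    ports = {sid for sid, name in net.input_ports if name == dose.agonist}
    if not ports:
        raise NetworkError(
            f"cell {net.cell_id!r} has no input port for agonist {dose.agonist!r}"
        )
    out = net.copy()
    for sp in out.species:
        if sp.id in ports:
            sp.initial_amount = dose.dose * dose.conversion
    return out


def consensus_effect(rec: MutationRecord, lib: EffectLibrary | None = None) -> str:
    """Effect call for one mutation: a library hit wins outright; otherwise a
    strict majority over the non-unknown predictor calls; tie or no usable
    calls -> unknown."""
    if lib is not None:
        hit = lib.lookup(rec.gene, rec.variant)
        if hit is not None:
            return hit
    calls = [call for _, call in rec.predictor_calls if call != "unknown"]
    if not calls:
        return "unknown"
    n_del = sum(1 for c in calls if c == "deleterious")
    n_neu = len(calls) - n_del
    if n_del > n_neu:
        return "deleterious"
    if n_neu > n_del:
        return "neutral"
    return "unknown"


def apply_genomic_profile(
    net: PathwayNetwork,
    profile: GenomicProfile,
    lib: EffectLibrary | None = None,
) -> tuple[PathwayNetwork, list[dict]]:
    """Return (perturbed copy, applied-lesion report).

    For each record: mutation effect via :func:`consensus_effect`; deleterious
    oncogene -> activity_scale*g on every species of that gene; deleterious
    tumor suppressor -> activity_scale*l; neutral/unknown -> skipped (logged).
    CNVs act independently at the expression level: amplification
    expression_scale*a, deletion expression_scale=0.  A gene without matching
    species is a warning in the report, not an error.
    """
    out = net.copy()
    by_gene: dict[str, list] = {}
    for sp in out.species:
        if sp.gene:
            by_gene.setdefault(sp.gene, []).append(sp)

    report: list[dict] = []
    for rec in profile.records:
        targets = by_gene.get(rec.gene, [])
        entry = {"gene": rec.gene, "variant": rec.variant, "actions": [], "warnings": []}
        if not targets:
            entry["warnings"].append(f"no species annotated with gene {rec.gene!r}")

        if rec.predictor_calls or rec.library_effect is not None:
            effect = consensus_effect(rec, lib)
            entry["effect"] = effect
            if effect == "deleterious" and targets:
                if rec.gene_class == "oncogene":
                    for sp in targets:
                        sp.activity_scale *= profile.gain_factor
                    entry["actions"].append(
                        f"gain of function: activity_scale x{profile.gain_factor}"
                    )
                elif rec.gene_class == "tumor_suppressor":
                    for sp in targets:
                        sp.activity_scale *= profile.loss_factor
                    entry["actions"].append(
                        f"loss of function: activity_scale x{profile.loss_factor}"
                    )
                else:
                    entry["warnings"].append("deleterious mutation in gene of class 'other': no rule")
            elif effect != "deleterious":
                entry["actions"].append(f"skipped: {effect}")

        if rec.cnv == "amplification" and targets:
            for sp in targets:
                sp.expression_scale *= profile.amplification_factor
            entry["actions"].append(
                f"over-expression: expression_scale x{profile.amplification_factor}"
            )
        elif rec.cnv == "deletion" and targets:
            for sp in targets:
                sp.expression_scale = 0.0
            entry["actions"].append("deletion: expression_scale = 0")
        report.append(entry)
    return out, report


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FIXED_COLS = {"gene", "variant", "gene_class", "cnv", "library_effect"}


def read_profile_csv(text_or_path, profile_id: str, **policy) -> GenomicProfile:
    """Genomic profile CSV: columns gene, variant, gene_class, cnv plus one
    column per predictor (cells hold deleterious/neutral/unknown or empty)."""
    df = pd.read_csv(text_or_path, dtype=str).fillna("")
    predictors = [c for c in df.columns if c not in _FIXED_COLS]
    records = []
    for _, row in df.iterrows():
        calls = tuple(
            (p, row[p]) for p in predictors if row.get(p, "") in ("deleterious", "neutral", "unknown")
        )
        records.append(
            MutationRecord(
                gene=row["gene"],
                variant=row.get("variant", ""),
                gene_class=row.get("gene_class") or "other",
                predictor_calls=calls,
                library_effect=(row.get("library_effect") or None) or None,
                cnv=row.get("cnv") or "none",
            )
        )
    return GenomicProfile(profile_id=profile_id, records=tuple(records), **policy)


def profile_to_csv(profile: GenomicProfile) -> str:
    predictors: list[str] = []
    for rec in profile.records:
        for name, _ in rec.predictor_calls:
            if name not in predictors:
                predictors.append(name)
    rows = []
    for rec in profile.records:
        calls = dict(rec.predictor_calls)
        rows.append(
            {
                "gene": rec.gene,
                "variant": rec.variant,
                "gene_class": rec.gene_class,
                "cnv": rec.cnv,
                "library_effect": rec.library_effect or "",
                **{p: calls.get(p, "") for p in predictors},
            }
        )
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    return buf.getvalue()


def read_effect_library_csv(text_or_path) -> EffectLibrary:
    """Two-column(+variant) CSV: gene, variant, effect."""
    df = pd.read_csv(text_or_path, dtype=str).fillna("")
    entries = {}
    for _, row in df.iterrows():
        entries[(row["gene"], row.get("variant", ""))] = row["effect"]
    return EffectLibrary(entries)
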