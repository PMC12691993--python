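"""Curated reaction knowledgebase with exact elemental bookkeeping.

Reactions carry signed rational stoichiometry over metabolites plus net
cofactor deltas (NADH, NADPH, FADH2, ATP). Carbon accounting uses
*transferable* carbons only: folate species count just the one-carbon unit
they carry (THF = 0, methylene-THF = 1, 10-formyl-THF = 1) and CoA thioesters
count their acyl unit, so that carbon conservation is assertable per reaction
without full structural formulas. Protons, water, and phosphate are not
balance-checked. Every reaction must conserve carbon and nitrogen exactly,
in rational arithmetic with no tolerance.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from shunt_ledger.errors import SchemaError, ValidationError

COFACTORS = ("NADH", "NADPH", "FADH2", "ATP")

BLOCKS = frozenset({
    "glycolysis_partial", "serinogenesis", "folate_cycling", "glycine_cleavage",
    "ppp", "pdh", "cac", "fatty_acid_cycling", "transport",
})

ROLES = frozenset({"boundary", "intermediate"})
COMPARTMENTS = frozenset({"cytosol", "mitochondrion", "unassigned"})

#: Metabolites allowed to cross the system boundary. NH3 is boundary so that
#: configurations without glutamate-dehydrogenase recycling stay balanced.
BOUNDARY_IDS = frozenset({"glc", "co2", "h2o", "pi", "nh3"})


def _parse_rational(value, where: str) -> Fraction:
    try:
        return Fraction(str(value))
    except (ValueError, ZeroDivisionError) as exc:
        raise SchemaError(f"{where}: {value!r} is not a rational number") from exc


@dataclass(frozen=True)
class Metabolite:
    """A pool in the network; ``carbons`` counts transferable carbons only."""

    id: str
    name: str
    carbons: int
    nitrogens: int = 0
    role: str = "intermediate"
    compartment: str = "unassigned"

    def __post_init__(self):
        if self.carbons < 0 or self.nitrogens < 0:
            raise ValidationError(f"metabolite {self.id}: negative element count")
        if self.role not in ROLES:
            raise ValidationError(f"metabolite {self.id}: unknown role {self.role!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"metabolite {self.id}: unknown compartment {self.compartment!r}")
        if self.role == "boundary" and self.id not in BOUNDARY_IDS:
            raise ValidationError(
                f"metabolite {self.id}: only {sorted(BOUNDARY_IDS)} may be boundary")


@dataclass(frozen=True)
class Reaction:
    """One enzymatic step: signed stoichiometry plus net cofactor deltas.

    ``step_weight`` is how many enzymatic steps the reaction counts as under
    the step-counting convention (aggregate complexes like the glycine
    cleavage system or PDH count 1; transport counts 0; a second distinct
    reaction catalyzed by an already-counted enzyme counts 0).
    """

    id: str
    enzyme: str
    genes: tuple[str, ...]
    stoich: Mapping[str, Fraction]
    cofactor_delta: Mapping[str, Fraction]
    block: str
    step_weight: int = 1
    compartment: str = "unassigned"

    def __post_init__(self):
        if self.block not in BLOCKS:
            raise ValidationError(f"reaction {self.id}: unknown block {self.block!r}")
        if self.step_weight < 0:
            raise ValidationError(f"reaction {self.id}: negative step_weight")
        for c in self.cofactor_delta:
            if c not in COFACTORS:
                raise ValidationError(f"reaction {self.id}: unknown cofactor {c!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"reaction {self.id}: unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class BalanceReport:
    """Element balance of one reaction; both deltas zero for a valid reaction."""

    reaction_id: str
    carbon_delta: Fraction
    nitrogen_delta: Fraction

    @property
    def balanced(self) -> bool:
        return self.carbon_delta == 0 and self.nitrogen_delta == 0


@dataclass
class ReactionSet:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[rid]
        except KeyError:
            raise ValidationError(f"unknown reaction id {rid!r}") from None

    def subset(self, reaction_ids: Iterable[str]) -> "ReactionSet":
        """Restriction to the given reactions (metabolites kept in full)."""
        return ReactionSet(
            metabolites=dict(self.metabolites),
            reactions={rid: self.reaction(rid) for rid in reaction_ids},
        )

    def blocks(self) -> set[str]:
        return {r.block for r in self.reactions.values()}


def validate_reaction(r: Reaction, metabolites: Mapping[str, Metabolite]) -> BalanceReport:
    """Carbon/nitrogen balance of ``r``; raises on unresolvable metabolites."""
    carbon = Fraction(0)
    nitrogen = Fraction(0)
    for mid, coef in r.stoich.items():
        try:
            m = metabolites[mid]
        except KeyError:
            raise ValidationError(
                f"reaction {r.id}: references unknown metabolite {mid!r}") from None
        carbon += coef * m.carbons
        nitrogen += coef * m.nitrogens
    return BalanceReport(r.id, carbon, nitrogen)


def validate_reaction_set(rs: ReactionSet) -> list[BalanceReport]:
    """Balance reports for all unbalanced reactions (empty when valid)."""
    bad = []
    for r in rs.reactions.values():
        rep = validate_reaction(r, rs.metabolites)
        if not rep.balanced:
            bad.append(rep)
    return bad


# ---------------------------------------------------------------------------
# (De)serialization: JSON (nested) and flat TSV, both shipped with the repo.

def _metabolite_from_record(rec: dict) -> Metabolite:
    try:
        return Metabolite(
            id=rec["id"], name=rec["name"],
            carbons=int(rec["carbons"]), nitrogens=int(rec.get("nitrogens", 0)),
            role=rec.get("role", "intermediate"),
            compartment=rec.get("compartment", "unassigned"),
        )
    except KeyError as exc:
        raise SchemaError(f"metabolite record {rec.get('id', rec)}: missing {exc}") from exc


def _reaction_from_record(rec: dict) -> Reaction:
    try:
        rid = rec["id"]
        stoich = {m: _parse_rational(v, f"reaction {rid} stoich[{m}]")
                  for m, v in rec.get("stoich", {}).items()}
        cof = {c: _parse_rational(v, f"reaction {rid} cofactor_delta[{c}]")
               for c, v in rec.get("cofactor_delta", {}).items()}
        return Reaction(
            id=rid, enzyme=rec.get("enzyme", ""), genes=tuple(rec.get("genes", ())),
            stoich=stoich, cofactor_delta=cof, block=rec["block"],
            step_weight=int(rec.get("step_weight", 1)),
            compartment=rec.get("compartment", "unassigned"),
        )
    except KeyError as exc:
        raise SchemaError(f"reaction record {rec.get('id', rec)}: missing {exc}") from exc


def build_reaction_set(metabolites: Iterable[Metabolite],
                       reactions: Iterable[Reaction]) -> ReactionSet:
    """Assemble and fully validate a ReactionSet.

    Raises :class:`ValidationError` listing every reaction id and its element
    imbalance if any reaction fails carbon or nitrogen conservation.
    """
    rs = ReactionSet()
    for m in metabolites:
        if m.id in rs.metabolites:
            raise ValidationError(f"duplicate metabolite id {m.id!r}")
        rs.metabolites[m.id] = m
    for r in reactions:
        if r.id in rs.reactions:
            raise ValidationError(f"duplicate reaction id {r.id!r}")
        rs.reactions[r.id] = r
    bad = validate_reaction_set(rs)
    if bad:
        detail = "; ".join(
            f"{b.reaction_id}: C delta {b.carbon_delta}, N delta {b.nitrogen_delta}"
            for b in bad)
        raise ValidationError(f"element balance violations: {detail}")
    return rs


def load_reaction_set(path) -> ReactionSet:
    """Load and validate a reaction set from JSON or flat TSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        return _load_tsv(path.read_text())
    return _load_json(path.read_text())


def _load_json(text: str) -> ReactionSet:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "metabolites" not in doc or "reactions" not in doc:
        raise SchemaError("reaction-set JSON must contain 'metabolites' and 'reactions'")
    mets = [_metabolite_from_record(rec) for rec in doc["metabolites"]]
    rxns = [_reaction_from_record(rec) for rec in doc["reactions"]]
    return build_reaction_set(mets, rxns)


_TSV_FIELDS = ["record_type", "id", "name", "carbons", "nitrogens", "role",
               "compartment", "genes", "block", "step_weight", "stoich",
               "cofactor_delta"]


def _encode_pairs(d: Mapping[str, Fraction]) -> str:
    return ";".join(f"{k}:{v}" for k, v in d.items())


def _decode_pairs(s: str, where: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if not s:
        return out
    for item in s.split(";"):
        if ":" not in item:
            raise SchemaError(f"{where}: malformed pair {item!r}")
        k, v = item.split(":", 1)
        out[k] = v
    return out


def dump_reaction_set(rs: ReactionSet, path) -> None:
    """Serialize to JSON or flat TSV (by extension); round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        path.write_text(to_tsv(rs))
    else:
        path.write_text(to_json(rs))


def to_json(rs: ReactionSet) -> str:
    doc = {
        "format": "shunt-ledger-reaction-set",
        "version": 1,
        "metabolites": [
            {"id": m.id, "name": m.name, "carbons": m.carbons,
             "nitrogens": m.nitrogens, "role": m.role, "compartment": m.compartment}
            for m in rs.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "enzyme": r.enzyme, "genes": list(r.genes),
             "block": r.block, "step_weight": r.step_weight,
             "compartment": r.compartment,
             "stoich": {m: str(v) for m, v in r.stoich.items()},
             "cofactor_delta": {c: str(v) for c, v in r.cofactor_delta.items()}}
            for r in rs.reactions.values()
        ],
    }
    return json.dumps(doc, indent=2)


def to_tsv(rs: ReactionSet) -> str:
    buf = io.StringIO()
    w = csv.DictWriter(buf, fieldnames=_TSV_FIELDS, delimiter="\t")
    w.writeheader()
    for m in rs.metabolites.values():
        w.writerow({"record_type": "metabolite", "id": m.id, "name": m.name,
                    "carbons": m.carbons, "nitrogens": m.nitrogens,
                    "role": m.role, "compartment": m.compartment,
                    "genes": "", "block": "", "step_weight": "",
                    "stoich": "", "cofactor_delta": ""})
    for r in rs.reactions.values():
        w.writerow({"record_type": "reaction", "id": r.id, "name": r.enzyme,
                    "carbons": "", "nitrogens": "", "role": "",
                    "compartment": r.compartment,
                    "genes": ",".join(r.genes), "block": r.block,
                    "step_weight": r.step_weight,
                    "stoich": _encode_pairs(r.stoich),
                    "cofactor_delta": _encode_pairs(r.cofactor_delta)})
    return buf.getvalue()


def _load_tsv(text: str) -> ReactionSet:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    mets, rxns = [], []
    for i, row in enumerate(reader, start=2):
        kind = (row.get("record_type") or "").strip()
        if kind == "metabolite":
            mets.append(_metabolite_from_record({
                "id": row["id"], "name": row["name"], "carbons": row["carbons"],
                "nitrogens": row["nitrogens"] or 0, "role": row["role"],
                "compartment": row["compartment"] or "unassigned"}))
        elif kind == "reaction":
            rxns.append(_reaction_from_record({
                "id": row["id"], "enzyme": row["name"],
                "genes": [g for g in (row["genes"] or "").split(",") if g],
                "block": row["block"], "step_weight": row["step_weight"] or 1,
                "compartment": row["compartment"] or "unassigned",
                "stoich": _decode_pairs(row["stoich"] or "", f"line {i} stoich"),
                "cofactor_delta": _decode_pairs(row["cofactor_delta"] or "",
                                                f"line {i} cofactor_delta")}))
        else:
            raise SchemaError(f"line {i}: unknown record_type {kind!r}")
    return build_reaction_set(mets, rxns)


def bundled_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(resources.files("shunt_ledger").joinpath("data", name))


def default_reaction_set() -> ReactionSet:
    """The bundled knowledgebase covering all pathway blocks."""
    return load_reaction_set(bundled_path("shunt_reactions.json"))
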