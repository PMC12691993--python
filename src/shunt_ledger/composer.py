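"""Compose reactions into pathways and compute exact net conversions.

A pathway is an ordered multiset of (reaction, positive integer multiplicity).
Composition is purely linear: metabolite deltas and cofactor ledgers are the
multiplicity-weighted sums of the member reactions, in exact rational
arithmetic. A small exhaustive integer-multiplicity solver doubles as an
independent oracle for the bundled pathway definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from shunt_ledger.errors import SchemaError, SearchSpaceError, ValidationError
from shunt_ledger.reaction_kb import ReactionSet, bundled_path

_ZERO = Fraction(0)


@dataclass(frozen=True)
class Pathway:
    id: str
    steps: tuple[tuple[str, int], ...]
    description: str = ""

    def __post_init__(self):
        for rid, mult in self.steps:
            if mult < 1:
                raise ValidationError(
                    f"pathway {self.id}: multiplicity for {rid} must be >= 1")

    def scaled(self, k: int) -> "Pathway":
        return Pathway(self.id, tuple((r, m * k) for r, m in self.steps),
                       self.description)

    def concat(self, other: "Pathway") -> "Pathway":
        return Pathway(f"{self.id}+{other.id}", self.steps + other.steps)


@dataclass(frozen=True)
class NetConversion:
    """Net metabolite deltas of a composed pathway; exact zeros are omitted."""

    deltas: Mapping[str, Fraction]

    def __getitem__(self, mid: str) -> Fraction:
        return self.deltas.get(mid, _ZERO)


@dataclass(frozen=True)
class CofactorLedger:
    """Net NADH/NADPH/FADH2/ATP produced per pathway execution (exact)."""

    nadh: Fraction = _ZERO
    nadph: Fraction = _ZERO
    fadh2: Fraction = _ZERO
    atp: Fraction = _ZERO

    def __add__(self, other: "CofactorLedger") -> "CofactorLedger":
        return CofactorLedger(self.nadh + other.nadh, self.nadph + other.nadph,
                              self.fadh2 + other.fadh2, self.atp + other.atp)

    def __mul__(self, k) -> "CofactorLedger":
        k = Fraction(k)
        return CofactorLedger(self.nadh * k, self.nadph * k,
                              self.fadh2 * k, self.atp * k)

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, Fraction]:
        return {"NADH": self.nadh, "NADPH": self.nadph,
                "FADH2": self.fadh2, "ATP": self.atp}

    @property
    def two_electron_pairs(self) -> Fraction:
        """NADH + NADPH + FADH2, each a 2-electron carrier."""
        return self.nadh + self.nadph + self.fadh2


@dataclass(frozen=True)
class CompositionResult:
    conversion: NetConversion
    ledger: CofactorLedger
    #: net NADPH per reaction compartment; populated in strict-compartment mode
    nadph_by_compartment: Mapping[str, Fraction] | None = None

    def __iter__(self):
        return iter((self.conversion, self.ledger))


def compose(p: Pathway, rs: ReactionSet,
            strict_compartments: bool = False) -> CompositionResult:
    """Net conversion and cofactor ledger of ``p`` over ``rs``.

    In strict-compartment mode the ledger is additionally broken down into
    net NADPH per reaction compartment, which makes formate export followed
    by cytosolic re-fixation visible as the relocation of one NADPH
    equivalent from the mitochondrion to the cytosol.
    """
    deltas: dict[str, Fraction] = {}
    cof: dict[str, Fraction] = {c: _ZERO for c in ("NADH", "NADPH", "FADH2", "ATP")}
    by_comp: dict[str, Fraction] = {}
    for rid, mult in p.steps:
        r = rs.reaction(rid)
        for mid, coef in r.stoich.items():
            deltas[mid] = deltas.get(mid, _ZERO) + coef * mult
        for c, d in r.cofactor_delta.items():
            cof[c] += d * mult
            if c == "NADPH":
                by_comp[r.compartment] = by_comp.get(r.compartment, _ZERO) + d * mult
    deltas = {m: v for m, v in deltas.items() if v != 0}
    ledger = CofactorLedger(cof["NADH"], cof["NADPH"], cof["FADH2"], cof["ATP"])
    return CompositionResult(
        NetConversion(deltas), ledger,
        nadph_by_compartment=(by_comp if strict_compartments else None))


@dataclass(frozen=True)
class OxidationCheck:
    ok: bool
    uncancelled: Mapping[str, Fraction]
    message: str

    def __bool__(self) -> bool:
        return self.ok


def verify_complete_oxidation(nc: NetConversion, rs: ReactionSet) -> OxidationCheck:
    """True iff the conversion is exactly glucose -> 6 CO2.

    All non-boundary metabolites must cancel, glucose delta must be -1 and
    CO2 delta +6. The diagnostic names every uncancelled intermediate.
    """
    uncancelled = {}
    problems = []
    for mid, v in nc.deltas.items():
        m = rs.metabolites.get(mid)
        if m is None or m.role != "boundary":
            uncancelled[mid] = v
    if uncancelled:
        names = ", ".join(f"{m} ({'+' if v > 0 else ''}{v})"
                          for m, v in sorted(uncancelled.items()))
        problems.append(f"uncancelled intermediates: {names}")
    if nc["glc"] != -1:
        problems.append(f"glucose delta is {nc['glc']}, expected -1")
    if nc["co2"] != 6:
        problems.append(f"CO2 delta is {nc['co2']}, expected +6")
    if problems:
        return OxidationCheck(False, uncancelled, "; ".join(problems))
    return OxidationCheck(True, {}, "complete oxidation of glucose to six CO2")


def count_steps(p: Pathway, rs: ReactionSet) -> int:
    """Enzymatic step count: sum of step_weight over *distinct* reactions.

    Multiplicities are ignored (an enzyme run through by several substrate
    molecules is counted once); transport and bookkeeping reactions carry
    weight 0.
    """
    seen = {rid for rid, _ in p.steps}
    return sum(rs.reaction(rid).step_weight for rid in seen)


# ---------------------------------------------------------------------------
# Exhaustive integer-multiplicity solver (independent oracle).

#: documented limits for the exhaustive search
MAX_REACTIONS = 24
MAX_BOUND = 8
MAX_NODES = 20_000_000


def solve_multiplicities(rs: ReactionSet, target: NetConversion, bound: int,
                         reaction_ids: Sequence[str] | None = None,
                         ) -> list[dict[str, int]]:
    """Every multiplicity assignment within ``bound`` composing to ``target``.

    Enumerates all vectors in {0..bound}^n over ``reaction_ids`` (default:
    every reaction in ``rs``, sorted by id) whose weighted stoichiometric sum
    equals the target exactly, with all other metabolites cancelled. Returns
    the solutions as {reaction: multiplicity} maps (zeros omitted), sorted
    lexicographically on the full vectors.

    The depth-first enumeration prunes a branch as soon as some metabolite
    can no longer be moved by any remaining reaction yet differs from its
    target, which discards no solutions. Limits (<= 24 reactions, bound <= 8,
    bounded node budget) are enforced by explicit refusal, never by silent
    truncation.
    """
    if reaction_ids is None:
        reaction_ids = sorted(rs.reactions)
    rids = list(reaction_ids)
    if len(rids) > MAX_REACTIONS:
        raise SearchSpaceError(
            f"{len(rids)} reactions exceeds the documented limit of {MAX_REACTIONS}")
    if bound < 0 or bound > MAX_BOUND:
        raise SearchSpaceError(f"bound {bound} outside 0..{MAX_BOUND}")

    stoichs = [rs.reaction(rid).stoich for rid in rids]
    # metabolites still touchable by reactions at index >= i
    touchable: list[set[str]] = [set() for _ in range(len(rids) + 1)]
    for i in range(len(rids) - 1, -1, -1):
        touchable[i] = touchable[i + 1] | set(stoichs[i])
    relevant = sorted(touchable[0] | set(target.deltas))

    goal = {m: target[m] for m in relevant}
    state = {m: _ZERO for m in relevant}
    # metabolites that become untouchable exactly after choosing reaction i
    frozen_after: list[list[str]] = []
    for i in range(len(rids)):
        frozen_after.append([m for m in relevant
                             if m in touchable[i] | set()
                             and m not in touchable[i + 1]])
    never_touched = [m for m in relevant if m not in touchable[0]]

    solutions: list[tuple[int, ...]] = []
    nodes = 0

    def dfs(i: int, vec: list[int]):
        nonlocal nodes
        nodes += 1
        if nodes > MAX_NODES:
            raise SearchSpaceError(
                f"search exceeded the node budget of {MAX_NODES}; "
                "reduce the bound or the reaction subset")
        if i == len(rids):
            if all(state[m] == goal[m] for m in relevant):
                solutions.append(tuple(vec))
            return
        st = stoichs[i]
        for mult in range(bound + 1):
            if mult:
                for m, coef in st.items():
                    state[m] += coef
            if all(state[m] == goal[m] for m in frozen_after[i]):
                vec.append(mult)
                dfs(i + 1, vec)
                vec.pop()
        for m, coef in st.items():
            state[m] -= coef * bound

    if any(state[m] != goal[m] for m in never_touched):
        return []
    dfs(0, [])
    solutions.sort()
    return [{rid: mult for rid, mult in zip(rids, vec) if mult}
            for vec in solutions]


# ---------------------------------------------------------------------------
# Pathway files.

def load_pathway(path) -> Pathway:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path.name}: not valid JSON: {exc}") from exc
    try:
        steps = tuple((s["reaction"], int(s["multiplicity"])) for s in doc["steps"])
        return Pathway(id=doc["id"], steps=steps,
                       description=doc.get("description", ""))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path.name}: malformed pathway record ({exc})") from exc


BUNDLED_PATHWAYS = ("shunt_full", "ppp_full", "canonic_full", "axis_full")


def bundled_pathway(name: str) -> Pathway:
    """One of the bundled pathway definitions (shunt/ppp/canonic/axis)."""
    if name not in BUNDLED_PATHWAYS:
        raise ValidationError(
            f"unknown bundled pathway {name!r}; choose from {BUNDLED_PATHWAYS}")
    return load_pathway(bundled_path(f"pathways/{name}.json"))
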