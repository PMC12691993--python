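"""ATP-equivalence accounting for cofactor ledgers.

The default scenario prices the oxidation of each reduced cofactor in ATP
equivalents: NADH respired through an operable complex I yields 5/2 ATP,
FADH2 fed in via the electron-transferring flavoprotein or complex II yields
3/2 ATP, while NADPH has no direct respiratory entry point and is disposed of
through fatty acid cycling at a net *cost* of 3/2 ATP per NADPH (the cycling
converts NADPH 1:1 into respirable FADH2, but the synthesis/activation
overhead exceeds the FADH2 return). Substrate-level ATP enters with weight 1.
All arithmetic is exact; decimal rendering happens only at report layers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from shunt_ledger.composer import CofactorLedger
from shunt_ledger.errors import SchemaError, ValidationError

#: Returned by :func:`nadp_nad_ratio` when NADPH > 0 with zero NADH
#: (an entirely NAD-independent pathway).
INFINITE_RATIO = math.inf


@dataclass(frozen=True)
class ATPScenario:
    """ATP-equivalents per unit of each cofactor (exact rationals)."""

    nadh_atp: Fraction = Fraction(5, 2)
    fadh2_atp: Fraction = Fraction(3, 2)
    nadph_atp: Fraction = Fraction(-3, 2)
    substrate_atp_weight: Fraction = Fraction(1)

    @classmethod
    def from_file(cls, path) -> "ATPScenario":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"scenario file: not valid JSON: {exc}") from exc
        kwargs = {}
        for key in ("nadh_atp", "fadh2_atp", "nadph_atp", "substrate_atp_weight"):
            if key in doc:
                kwargs[key] = Fraction(str(doc[key]))
        return cls(**kwargs)


def atp_balance(ledger: CofactorLedger, s: ATPScenario = ATPScenario()) -> Fraction:
    """Net ATP equivalents of a ledger under scenario ``s`` (linear, exact)."""
    return (ledger.nadh * s.nadh_atp
            + ledger.fadh2 * s.fadh2_atp
            + ledger.nadph * s.nadph_atp
            + ledger.atp * s.substrate_atp_weight)


def nadph_to_fadh2(n: Fraction) -> Fraction:
    """FADH2 delivered by fatty-acid-cycling disposal of ``n`` NADPH (1:1).

    The only net redox effect of concurrent fatty acid synthesis and
    beta-oxidation is the conversion of NADPH into respirable FADH2, so the
    exchange rate is exactly one.
    """
    n = Fraction(n)
    if n < 0:
        raise ValidationError("nadph_to_fadh2 requires a non-negative amount")
    return n


def nad_sparing(shunt: CofactorLedger, reference: CofactorLedger) -> Fraction:
    """Percentage of the reference pathway's NAD demand avoided by the shunt.

    100 * (reference.nadh - shunt.nadh) / reference.nadh; requires a
    reference that actually consumes NAD (nadh > 0).
    """
    if reference.nadh <= 0:
        raise ValidationError(
            f"reference NADH must be positive, got {reference.nadh}")
    return 100 * (reference.nadh - shunt.nadh) / reference.nadh


def nadp_nad_ratio(ledger: CofactorLedger):
    """NADPH:NADH production ratio of a ledger.

    Exact rational when NADH > 0; :data:`INFINITE_RATIO` when the pathway
    produces NADPH without any NADH; 0 when it produces neither.
    """
    if ledger.nadh > 0:
        return ledger.nadph / ledger.nadh
    if ledger.nadph > 0:
        return INFINITE_RATIO
    return Fraction(0)
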