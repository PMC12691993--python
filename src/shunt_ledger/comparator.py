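"""Side-by-side comparison of complete glucose-oxidation pathways.

Builds one report row per pathway: cofactor ledger, ATP balance under a
scenario, enzymatic step count, NAD sparing versus a reference pathway, and
the NADP:NAD production ratio. Pathways that are not complete oxidations are
refused rather than normalized, so the comparison always compares like with
like (everything per glucose).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from shunt_ledger.composer import (CofactorLedger, Pathway, compose,
                                   count_steps, verify_complete_oxidation)
from shunt_ledger.errors import ValidationError
from shunt_ledger.reaction_kb import ReactionSet
from shunt_ledger.yields import (ATPScenario, atp_balance, nad_sparing,
                                 nadp_nad_ratio)


@dataclass(frozen=True)
class ComparisonRow:
    pathway_id: str
    ledger: CofactorLedger
    atp_balance: Fraction
    steps: int
    nad_sparing_vs_reference: Fraction
    nadp_nad_ratio: object  # Fraction or the infinity sentinel


@dataclass(frozen=True)
class PathwayComparison:
    rows: tuple[ComparisonRow, ...]
    reference: str

    def row(self, pathway_id: str) -> ComparisonRow:
        for r in self.rows:
            if r.pathway_id == pathway_id:
                return r
        raise KeyError(pathway_id)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("pathway\tNADH\tNADPH\tFADH2\tATP_substrate\tATP_balance\t"
                  "steps\tNAD_sparing_pct\tNADP_NAD_ratio\n")
        for r in self.rows:
            ratio = "inf" if r.nadp_nad_ratio == float("inf") else str(r.nadp_nad_ratio)
            buf.write(f"{r.pathway_id}\t{r.ledger.nadh}\t{r.ledger.nadph}\t"
                      f"{r.ledger.fadh2}\t{r.ledger.atp}\t{r.atp_balance}\t"
                      f"{r.steps}\t{r.nad_sparing_vs_reference}\t{ratio}\n")
        return buf.getvalue()

    def to_text(self) -> str:
        header = (f"Pathway comparison (per glucose; reference: {self.reference})\n")
        lines = [header]
        fmt = "{:<14} {:>5} {:>6} {:>6} {:>7} {:>8} {:>6} {:>9} {:>9}"
        lines.append(fmt.format("pathway", "NADH", "NADPH", "FADH2", "subATP",
                                "ATP-bal", "steps", "spared%", "NADP:NAD"))
        for r in self.rows:
            ratio = "inf" if r.nadp_nad_ratio == float("inf") else str(r.nadp_nad_ratio)
            lines.append(fmt.format(
                r.pathway_id, str(r.ledger.nadh), str(r.ledger.nadph),
                str(r.ledger.fadh2), str(r.ledger.atp), str(r.atp_balance),
                r.steps, str(r.nad_sparing_vs_reference), ratio))
        return "\n".join(lines) + "\n"


def compare(pathways: Sequence[Pathway], rs: ReactionSet,
            s: ATPScenario = ATPScenario(),
            reference: str | None = None) -> PathwayComparison:
    """Compare complete-oxidation pathways; fails loudly otherwise.

    ``reference`` names the pathway against which NAD sparing is computed
    (default: the first pathway). The reference row has sparing 0 by
    construction.
    """
    if not pathways:
        raise ValidationError("compare requires at least one pathway")
    if reference is None:
        reference = pathways[0].id
    ledgers: dict[str, CofactorLedger] = {}
    for p in pathways:
        conv, ledger = compose(p, rs)
        check = verify_complete_oxidation(conv, rs)
        if not check:
            raise ValidationError(
                f"pathway {p.id} is not a complete oxidation: {check.message}")
        ledgers[p.id] = ledger
    if reference not in ledgers:
        raise ValidationError(f"reference pathway {reference!r} not in input list")
    ref_ledger = ledgers[reference]
    rows = []
    for p in pathways:
        ledger = ledgers[p.id]
        rows.append(ComparisonRow(
            pathway_id=p.id,
            ledger=ledger,
            atp_balance=atp_balance(ledger, s),
            steps=count_steps(p, rs),
            nad_sparing_vs_reference=nad_sparing(ledger, ref_ledger),
            nadp_nad_ratio=nadp_nad_ratio(ledger),
        ))
    return PathwayComparison(tuple(rows), reference)


def plot_atp_balances(comparison: PathwayComparison, path) -> None:
    """Simple bar chart of the ATP balances (one bar per pathway)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = [r.pathway_id for r in comparison.rows]
    vals = [float(r.atp_balance) for r in comparison.rows]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    colors = ["#2b7a3f" if v >= 0 else "#a03a3a" for v in vals]
    ax.bar(ids, vals, color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("ATP per glucose")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
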