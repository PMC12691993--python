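"""Gene-set classification from differential-expression summary tables and
cross-model purpose consensus.

The pipeline's contract is the DE *summary* table (gene symbol, fold change,
adjusted p-value, mean-expression proxy) produced per model by the upstream
DE machinery; estimation from counts is out of scope. Significance is judged
strictly within each model through its :class:`ModelProfile` — adjusted
p-values are never pooled or compared across models, because the models
differ in platform, design, and statistical power. The cross-model step
compares only the resulting categorical verdicts.

Gene-level rule: a gene is ``low_expression`` below the model's expression
floor; otherwise ``induced`` (padj below threshold, fold change > 1),
``suppressed`` (padj below threshold, fold change < 1), else ``unchanged``.

Set-level aggregation (configurable; the default formalizes the informal
reading of induction tables): ``low_expression`` if every detected member is
low; ``induced`` if at least half of the evaluable members are induced and
none suppressed; ``suppressed`` symmetrically; ``mixed`` if both directions
occur; otherwise ``unchanged``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from shunt_ledger.errors import ConfigurationError, SchemaError, ValidationError
from shunt_ledger.reaction_kb import bundled_path

INDUCED = "induced"
SUPPRESSED = "suppressed"
UNCHANGED = "unchanged"
MIXED = "mixed"
LOW_EXPRESSION = "low_expression"

GENE_STATUSES = (INDUCED, SUPPRESSED, UNCHANGED, LOW_EXPRESSION)
SET_STATUSES = (INDUCED, SUPPRESSED, MIXED, UNCHANGED, LOW_EXPRESSION)

UNIVERSAL = "universal"
PARTIAL = "partial"
REJECTED = "rejected"


@dataclass(frozen=True)
class ModelProfile:
    """Model-specific significance regime.

    padj_threshold: BH-adjusted p-value below which a fold change counts.
    low_expr_threshold: expression floor below which no call is made
    (platform-specific units: RPKM-like for RNA-seq models, 0 = disabled).
    """

    model_id: str
    padj_threshold: float
    low_expr_threshold: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not (0 < self.padj_threshold <= 1):
            raise ValidationError(
                f"profile {self.model_id}: padj_threshold must be in (0, 1]")
        if self.low_expr_threshold < 0:
            raise ValidationError(
                f"profile {self.model_id}: low_expr_threshold must be >= 0")


def load_model_profiles(path=None) -> dict[str, ModelProfile]:
    """Bundled defaults: models 1 and 3 at padj < 1e-6, model 2 at p < 0.05."""
    path = Path(path) if path else bundled_path("model_profiles.json")
    doc = json.loads(path.read_text())
    out = {}
    for rec in doc["profiles"]:
        p = ModelProfile(model_id=rec["model_id"],
                         padj_threshold=float(rec["padj_threshold"]),
                         low_expr_threshold=float(rec.get("low_expr_threshold", 0.0)),
                         label=rec.get("label", ""))
        out[p.model_id] = p
    return out


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    purpose: str = ""

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name}: duplicate gene symbols")


def load_genesets(path=None) -> dict[str, GeneSet]:
    path = Path(path) if path else bundled_path("genesets.json")
    doc = json.loads(path.read_text())
    out = {}
    for rec in doc["genesets"]:
        g = GeneSet(name=rec["name"], genes=tuple(rec["genes"]),
                    purpose=rec.get("purpose", ""))
        if g.name in out:
            raise ValidationError(f"duplicate gene set name {g.name!r}")
        out[g.name] = g
    return out


@dataclass
class DETable:
    """Per-gene DE summary for one model: fold change as a ratio (> 0),
    BH-adjusted p-value in [0, 1], and a non-negative expression proxy."""

    model_id: str
    data: pd.DataFrame  # index: gene symbol; columns: fc, padj, expr

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(
                f"DE table {self.model_id}: duplicate gene symbols {dups[:5]}")
        if (df["fc"] <= 0).any():
            raise ValidationError(f"DE table {self.model_id}: fold changes must be > 0")
        if ((df["padj"] < 0) | (df["padj"] > 1)).any():
            raise ValidationError(f"DE table {self.model_id}: padj outside [0, 1]")
        if (df["expr"] < 0).any():
            raise ValidationError(f"DE table {self.model_id}: negative expression")

    def __len__(self) -> int:
        return len(self.data)

    def genes(self) -> set[str]:
        return set(self.data.index)


@dataclass(frozen=True)
class Dialect:
    """Column mapping for reading DE summary TSVs."""

    gene: str = "gene"
    fc: str = "fc"
    padj: str = "padj"
    expr: str = "expr"
    log2_fc: bool = False


def read_de_table(path, dialect: Dialect = Dialect(), model_id: str = "") -> DETable:
    """Read a DE summary TSV into a normalized :class:`DETable`.

    log2 fold changes are converted to ratios; '#'-prefixed header lines are
    skipped. Missing columns, non-numeric values, and duplicate symbols are
    errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in (dialect.gene, dialect.fc, dialect.padj)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    cols = {dialect.gene: "gene", dialect.fc: "fc", dialect.padj: "padj"}
    if dialect.expr in df.columns:
        cols[dialect.expr] = "expr"
    df = df.rename(columns=cols)
    if "expr" not in df.columns:
        df["expr"] = float("inf")  # no expression floor applicable
    for col in ("fc", "padj", "expr"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df[["fc", "padj"]].isna().any().any():
        raise SchemaError(f"{path.name}: non-numeric or missing fc/padj values")
    if dialect.log2_fc:
        df["fc"] = 2.0 ** df["fc"]
    df = df.set_index("gene")[["fc", "padj", "expr"]]
    return DETable(model_id=model_id or path.stem, data=df)


def write_de_table(table: DETable, path, header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df = table.data.reset_index()
        df.columns = ["gene", "fc", "padj", "expr"]
        df.to_csv(fh, sep="\t", index=False)


def classify_gene(fc: float, padj: float, expr: float,
                  profile: ModelProfile) -> str:
    """Status of one gene under one model's significance regime."""
    if expr < profile.low_expr_threshold:
        return LOW_EXPRESSION
    if padj < profile.padj_threshold:
        if fc > 1:
            return INDUCED
        if fc < 1:
            return SUPPRESSED
    return UNCHANGED


@dataclass(frozen=True)
class Verdict:
    geneset: str
    model_id: str
    status: str
    gene_statuses: Mapping[str, str]
    missing_genes: tuple[str, ...] = ()


def classify_gene_set(t: DETable, g: GeneSet, p: ModelProfile) -> Verdict:
    """Aggregate per-gene statuses of ``g`` in table ``t`` into a verdict.

    Genes absent from the table (e.g. unmapped orthologs) are skipped and
    recorded in ``missing_genes``, never imputed; an entirely absent set is
    an error.
    """
    present = [gene for gene in g.genes if gene in t.data.index]
    missing = tuple(gene for gene in g.genes if gene not in t.data.index)
    if not present:
        raise ValidationError(
            f"gene set {g.name}: no member present in DE table {t.model_id}")
    statuses = {}
    for gene in present:
        row = t.data.loc[gene]
        statuses[gene] = classify_gene(row["fc"], row["padj"], row["expr"], p)
    return Verdict(g.name, t.model_id,
                   _aggregate(statuses.values()), statuses, missing)


def _aggregate(statuses: Iterable[str]) -> str:
    statuses = list(statuses)
    evaluable = [s for s in statuses if s != LOW_EXPRESSION]
    if not evaluable:
        return LOW_EXPRESSION
    n_ind = sum(s == INDUCED for s in evaluable)
    n_sup = sum(s == SUPPRESSED for s in evaluable)
    if n_ind and n_sup:
        return MIXED
    if n_ind and 2 * n_ind >= len(evaluable):
        return INDUCED
    if n_sup and 2 * n_sup >= len(evaluable):
        return SUPPRESSED
    return UNCHANGED


# ---------------------------------------------------------------------------
# Cross-model purpose consensus.

@dataclass(frozen=True)
class PurposeRule:
    """What a candidate purpose requires of the gene-set verdicts in a model.

    A model *supports* the purpose when every set in ``all_induced`` is
    induced, at least one set in ``any_induced`` is induced (if any are
    listed), and no referenced set is suppressed. A suppressed referenced set
    *contradicts* the purpose in that model.
    """

    name: str
    all_induced: tuple[str, ...] = ()
    any_induced: tuple[str, ...] = ()
    description: str = ""

    @property
    def referenced(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.all_induced + self.any_induced))


#: The candidate purposes compared across models. Catabolic NADPH production
#: is the shunt hypothesis; the others are the alternative explanations.
DEFAULT_PURPOSE_RULES: tuple[PurposeRule, ...] = (
    PurposeRule(
        "catabolic_nadph",
        all_induced=("shunt_serinogenesis",),
        any_induced=("shunt_mito_folate", "shunt_cyto_folate"),
        description="Complete glucose oxidation with NADP as electron "
                    "acceptor: serinogenesis plus at least one arm of "
                    "folate cycling induced."),
    PurposeRule(
        "oxidative_stress",
        any_induced=("antioxidant_cyto", "antioxidant_mito"),
        description="NADPH for antioxidant repair: broad induction of "
                    "antioxidant enzyme sets."),
    PurposeRule(
        "purine_synthesis",
        all_induced=("purine_synthesis",),
        description="10-formyl-THF demand for de novo purine synthesis."),
    PurposeRule(
        "dna_synthesis",
        all_induced=("pyrimidine_dna",),
        description="DNA building-block demand; suppression of thymidylate "
                    "or its cofactor recycling contradicts it."),
    PurposeRule(
        "methylation",
        all_induced=("methionine_cycle",),
        description="C1 efflux towards S-adenosylmethionine and "
                    "transsulfuration."),
)

SUPPORTED = "supported"
CONTRADICTED = "contradicted"
UNSUPPORTED = "unsupported"


@dataclass(frozen=True)
class ConsensusReport:
    classification: Mapping[str, str]          # purpose -> universal/partial/rejected
    model_status: Mapping[str, Mapping[str, str]]  # purpose -> model -> status
    models: tuple[str, ...]
    flags: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps({
            "models": list(self.models),
            "classification": dict(self.classification),
            "model_status": {p: dict(ms) for p, ms in self.model_status.items()},
            "flags": list(self.flags),
        }, indent=2)


def consensus(verdicts: Sequence[Verdict],
              rules: Sequence[PurposeRule] = DEFAULT_PURPOSE_RULES,
              known_genesets: Iterable[str] | None = None) -> ConsensusReport:
    """Classify each candidate purpose as universal, partial, or rejected.

    universal: every model with data supports the purpose; partial: some do;
    rejected: none does (including contradiction everywhere). Verdicts are
    the only cross-model currency — no p-value pooling occurs here.
    """
    if not verdicts:
        raise ValidationError("consensus requires at least one verdict")
    if known_genesets is None:
        known_genesets = load_genesets().keys()
    known = set(known_genesets) | {v.geneset for v in verdicts}
    for rule in rules:
        for name in rule.referenced:
            if name not in known:
                raise ConfigurationError(
                    f"purpose rule {rule.name!r} references unknown gene set {name!r}")

    by_model: dict[str, dict[str, str]] = {}
    for v in verdicts:
        by_model.setdefault(v.model_id, {})[v.geneset] = v.status
    models = tuple(sorted(by_model))

    model_status: dict[str, dict[str, str]] = {}
    classification: dict[str, str] = {}
    for rule in rules:
        per_model: dict[str, str] = {}
        for model in models:
            sets = by_model[model]
            ref_statuses = {name: sets.get(name) for name in rule.referenced}
            if any(s in (SUPPRESSED, MIXED) for s in ref_statuses.values()):
                per_model[model] = CONTRADICTED
                continue
            ok_all = all(ref_statuses.get(name) == INDUCED
                         for name in rule.all_induced)
            ok_any = (not rule.any_induced or
                      any(ref_statuses.get(name) == INDUCED
                          for name in rule.any_induced))
            per_model[model] = SUPPORTED if (ok_all and ok_any) else UNSUPPORTED
        model_status[rule.name] = per_model
        n_sup = sum(s == SUPPORTED for s in per_model.values())
        if n_sup == len(models) and models:
            classification[rule.name] = UNIVERSAL
        elif n_sup > 0:
            classification[rule.name] = PARTIAL
        else:
            classification[rule.name] = REJECTED

    flags = []
    if len(models) < 2:
        flags.append("single-model input: classification is not cross-model")
    return ConsensusReport(classification, model_status, models, tuple(flags))
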