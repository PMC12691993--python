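"""Synthetic inputs for exercising the pipeline without any downloads.

Two generators:

* DE summary tables with planted, model-specific gene-set structure on top of
  a uniform-p null background. The generator emits summary tables directly
  (fold change, adjusted p, expression proxy) rather than raw counts, because
  DE estimation from counts is the upstream tools' job and the pipeline's
  contract is the summary table. Planted adjusted-p ranges are required to
  sit strictly on the correct side of the model's significance threshold, so
  a plant is recovered by construction unless the classifier is wrong.

* Small element-balanced reaction networks (linear conversion chains with
  CO2/NH3 off-gassing) with a known planted multiplicity vector, used to
  cross-check the composer against the exhaustive solver.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd

from shunt_ledger.composer import NetConversion, Pathway
from shunt_ledger.errors import ValidationError
from shunt_ledger.reaction_kb import Metabolite, Reaction, ReactionSet, build_reaction_set
from shunt_ledger.transcriptomics import (DETable, GeneSet, ModelProfile,
                                          INDUCED, LOW_EXPRESSION, MIXED,
                                          SUPPRESSED, UNCHANGED,
                                          load_genesets, load_model_profiles)


@dataclass(frozen=True)
class PlantedEffect:
    """Target gene status plus the ranges its summary values are drawn from."""

    status: str
    fc_range: tuple[float, float]
    padj_range: tuple[float, float]
    expr_range: tuple[float, float] = (10.0, 1000.0)


def planted_effect(status: str, profile: ModelProfile) -> PlantedEffect:
    """Default effect ranges for a status under a model's regime.

    Induced/suppressed plants draw padj well inside the threshold (<= 1% of
    it) with fold changes >= 2 (or <= 1/2); unchanged plants draw padj in
    [0.5, 1] with fold changes near 1; low-expression plants draw below the
    model's expression floor.
    """
    thr = profile.padj_threshold
    if status == INDUCED:
        return PlantedEffect(INDUCED, (2.0, 8.0), (0.0, thr * 1e-2))
    if status == SUPPRESSED:
        return PlantedEffect(SUPPRESSED, (0.125, 0.5), (0.0, thr * 1e-2))
    if status == UNCHANGED:
        return PlantedEffect(UNCHANGED, (0.8, 1.25), (0.5, 1.0))
    if status == LOW_EXPRESSION:
        if profile.low_expr_threshold <= 0:
            raise ValidationError(
                f"model {profile.model_id} has no expression floor; "
                "cannot plant low_expression")
        return PlantedEffect(LOW_EXPRESSION, (0.5, 2.0), (0.0, 1.0),
                             expr_range=(0.0, profile.low_expr_threshold * 0.5))
    raise ValidationError(f"unknown planted status {status!r}")


@dataclass
class EffectSpec:
    """Planted gene-set effects plus the null background for one table."""

    set_effects: dict[str, PlantedEffect] = field(default_factory=dict)
    gene_overrides: dict[str, PlantedEffect] = field(default_factory=dict)
    n_null_genes: int = 10_000
    background_fc_log2_sigma: float = 0.25
    background_expr_range: tuple[float, float] = (10.0, 1000.0)
    seed: int = 0


def _check_effect(name: str, eff: PlantedEffect, profile: ModelProfile) -> None:
    thr = profile.padj_threshold
    lo, hi = eff.padj_range
    if not (0 <= lo <= hi <= 1):
        raise ValidationError(f"{name}: malformed padj range {eff.padj_range}")
    if eff.fc_range[0] > eff.fc_range[1] or eff.fc_range[0] <= 0:
        raise ValidationError(f"{name}: malformed fc range {eff.fc_range}")
    if eff.status == INDUCED:
        if hi >= thr:
            raise ValidationError(
                f"{name}: planted 'induced' but padj range reaches {hi} >= "
                f"threshold {thr} of model {profile.model_id}")
        if eff.fc_range[0] <= 1:
            raise ValidationError(f"{name}: planted 'induced' needs fc > 1")
    elif eff.status == SUPPRESSED:
        if hi >= thr:
            raise ValidationError(
                f"{name}: planted 'suppressed' but padj range reaches {hi} >= "
                f"threshold {thr} of model {profile.model_id}")
        if eff.fc_range[1] >= 1:
            raise ValidationError(f"{name}: planted 'suppressed' needs fc < 1")
    elif eff.status == UNCHANGED:
        if lo < thr:
            raise ValidationError(
                f"{name}: planted 'unchanged' but padj range starts at {lo} < "
                f"threshold {thr} of model {profile.model_id}")
    elif eff.status == LOW_EXPRESSION:
        if profile.low_expr_threshold <= 0:
            raise ValidationError(
                f"{name}: low_expression plant but model {profile.model_id} "
                "has no expression floor")
        if eff.expr_range[1] >= profile.low_expr_threshold:
            raise ValidationError(
                f"{name}: low_expression plant must draw expr below the "
                f"floor {profile.low_expr_threshold}")
    else:
        raise ValidationError(f"{name}: unknown status {eff.status!r}")


def generate_de_table(profile: ModelProfile, spec: EffectSpec,
                      genesets: Mapping[str, GeneSet] | None = None) -> DETable:
    """Synthesize one model's DE summary table.

    The table contains every gene of every bundled gene set plus
    ``n_null_genes`` background genes. Gene overrides take precedence over
    set-level effects; a gene in several sets takes the effect of the first
    set in name order. Unplanted genes draw from the null background
    (fold change lognormal around 1, padj uniform on [0, 1]).
    """
    if genesets is None:
        genesets = load_genesets()
    for name, eff in spec.set_effects.items():
        if name not in genesets:
            raise ValidationError(f"effect spec references unknown gene set {name!r}")
        _check_effect(f"set {name}", eff, profile)
    for gene, eff in spec.gene_overrides.items():
        _check_effect(f"gene {gene}", eff, profile)

    assignment: dict[str, PlantedEffect | None] = {}
    for gene, eff in spec.gene_overrides.items():
        assignment[gene] = eff
    for name in sorted(genesets):
        eff = spec.set_effects.get(name)
        for gene in genesets[name].genes:
            if gene not in assignment:
                assignment[gene] = eff

    rng = np.random.default_rng([spec.seed, zlib.crc32(profile.model_id.encode())])
    genes, fcs, padjs, exprs = [], [], [], []

    def draw_background():
        fc = float(2.0 ** rng.normal(0.0, spec.background_fc_log2_sigma))
        padj = float(rng.uniform(0.0, 1.0))
        expr = float(rng.uniform(*spec.background_expr_range))
        return fc, padj, expr

    for gene in sorted(assignment):
        eff = assignment[gene]
        if eff is None:
            fc, padj, expr = draw_background()
        else:
            fc = float(rng.uniform(*eff.fc_range))
            padj = float(rng.uniform(*eff.padj_range))
            expr = float(rng.uniform(*eff.expr_range))
        genes.append(gene); fcs.append(fc); padjs.append(padj); exprs.append(expr)

    for i in range(spec.n_null_genes):
        fc, padj, expr = draw_background()
        genes.append(f"NULL{i:05d}"); fcs.append(fc); padjs.append(padj); exprs.append(expr)

    df = pd.DataFrame({"fc": fcs, "padj": padjs, "expr": exprs},
                      index=pd.Index(genes, name="gene"))
    return DETable(model_id=profile.model_id, data=df)


# ---------------------------------------------------------------------------
# The study-mimic study scenario: three complex I inhibition models.

def study_mimic_spec(model_id: str, seed: int = 0,
                     profiles: Mapping[str, ModelProfile] | None = None,
                     ) -> tuple[EffectSpec, dict[str, str]]:
    """Planted effects emulating the narrated induction patterns per model,
    plus the expected set-level verdicts the classifier should recover.

    Model 1 (MPP neurons): shunt sets and antioxidants broadly induced,
    glycine cleavage below the expression floor, methylation and
    thymidylate/DHFR suppressed, purine sets induced. Model 2 (MetR liver):
    shunt and purine sets induced, antioxidants mixed (reductases up, direct
    antioxidants down), pyrimidine-DNA suppressed. Model 3 (NDUFS2
    fibroblasts): serinogenesis and mitochondrial folate cycling induced,
    everything else flat except suppressed DNA-synthesis enzymes.
    """
    if profiles is None:
        profiles = load_model_profiles()
    if model_id not in profiles:
        raise ValidationError(f"unknown model {model_id!r}")
    p = profiles[model_id]

    def eff(status):
        return planted_effect(status, p)

    if model_id == "model1":
        sets = {
            "shunt_serinogenesis": INDUCED, "shunt_mito_folate": INDUCED,
            "shunt_cyto_folate": INDUCED, "glycine_cleavage": LOW_EXPRESSION,
            "nadph_export": INDUCED, "serine_anabolic": UNCHANGED,
            "mito_translation": UNCHANGED, "purine_synthesis": INDUCED,
            "purine_salvage": INDUCED, "pyrimidine_dna": SUPPRESSED,
            "methionine_cycle": SUPPRESSED, "antioxidant_cyto": INDUCED,
            "antioxidant_mito": INDUCED,
        }
        overrides = {"CAD": eff(UNCHANGED), "RRM2": eff(UNCHANGED),
                     "MTR": eff(UNCHANGED), "CBS": eff(UNCHANGED)}
        expected = dict(sets)
    elif model_id == "model2":
        sets = {
            "shunt_serinogenesis": INDUCED, "shunt_mito_folate": INDUCED,
            "shunt_cyto_folate": INDUCED, "glycine_cleavage": INDUCED,
            "nadph_export": UNCHANGED, "serine_anabolic": UNCHANGED,
            "mito_translation": UNCHANGED, "purine_synthesis": INDUCED,
            "purine_salvage": INDUCED, "pyrimidine_dna": SUPPRESSED,
            "methionine_cycle": UNCHANGED, "antioxidant_cyto": UNCHANGED,
            "antioxidant_mito": UNCHANGED,
        }
        overrides = {"TYMS": eff(UNCHANGED), "RRM2": eff(UNCHANGED),
                     "GSR": eff(INDUCED), "TXNRD1": eff(INDUCED),
                     "GPX1": eff(SUPPRESSED), "CAT": eff(SUPPRESSED)}
        expected = dict(sets)
        expected["antioxidant_cyto"] = MIXED
    elif model_id == "model3":
        sets = {
            "shunt_serinogenesis": INDUCED, "shunt_mito_folate": INDUCED,
            "shunt_cyto_folate": UNCHANGED, "glycine_cleavage": UNCHANGED,
            "nadph_export": UNCHANGED, "serine_anabolic": UNCHANGED,
            "mito_translation": UNCHANGED, "purine_synthesis": UNCHANGED,
            "purine_salvage": UNCHANGED, "pyrimidine_dna": SUPPRESSED,
            "methionine_cycle": UNCHANGED, "antioxidant_cyto": UNCHANGED,
            "antioxidant_mito": UNCHANGED,
        }
        overrides = {"DHFR": eff(UNCHANGED), "CAD": eff(UNCHANGED),
                     "GPX1": eff(SUPPRESSED)}
        expected = dict(sets)
    else:
        raise ValidationError(f"no study-mimic scenario for model {model_id!r}")

    spec = EffectSpec(
        set_effects={name: eff(status) for name, status in sets.items()},
        gene_overrides=overrides,
        seed=seed,
    )
    return spec, expected


#: Expected cross-model purpose classification of the study-mimic scenario.
STUDY_MIMIC_CONSENSUS = {
    "catabolic_nadph": "universal",
    "oxidative_stress": "partial",
    "purine_synthesis": "partial",
    "dna_synthesis": "rejected",
    "methylation": "rejected",
}


# ---------------------------------------------------------------------------
# Random balanced reaction networks with a planted multiplicity vector.

def generate_random_network(seed: int, n_reactions: int, n_metabolites: int | None = None,
                            ) -> tuple[ReactionSet, Pathway, NetConversion]:
    """A linear conversion chain, element-balanced by construction.

    Builds metabolites X0 -> X1 -> ... with non-increasing carbon/nitrogen
    content; each step off-gasses the element difference as CO2/NH3 and
    carries random small cofactor deltas. All reactions fire with one common
    planted multiplicity k, giving the returned boundary target
    {X0: -k, Xn: +k, co2/nh3: +...}. The plant is the *unique* solution of
    the target within any bound >= k, because each chain intermediate is
    touched by exactly two reactions.
    """
    if n_metabolites is None:
        n_metabolites = n_reactions + 1
    if n_metabolites < n_reactions + 1:
        raise ValidationError("need at least n_reactions + 1 metabolites")
    rng = np.random.default_rng(seed)

    co2 = Metabolite("co2", "carbon dioxide", 1, 0, role="boundary")
    nh3 = Metabolite("nh3", "ammonia", 0, 1, role="boundary")
    mets = [co2, nh3]
    if n_reactions == 0:
        rs = build_reaction_set(mets, [])
        return rs, Pathway("plant", ()), NetConversion({})

    carbons = [int(rng.integers(n_reactions, n_reactions + 4))]
    nitros = [int(rng.integers(0, 2))]
    for _ in range(n_reactions):
        carbons.append(max(0, carbons[-1] - int(rng.integers(0, 2))))
        nitros.append(max(0, nitros[-1] - int(rng.integers(0, 2))))
    chain = [Metabolite(f"X{i}", f"chain metabolite {i}", carbons[i], nitros[i])
             for i in range(n_reactions + 1)]
    mets.extend(chain)
    for j in range(n_metabolites - (n_reactions + 1)):
        mets.append(Metabolite(f"U{j}", f"unused metabolite {j}",
                               int(rng.integers(0, 5))))

    reactions = []
    for i in range(n_reactions):
        stoich = {chain[i].id: Fraction(-1), chain[i + 1].id: Fraction(1)}
        dc = carbons[i] - carbons[i + 1]
        dn = nitros[i] - nitros[i + 1]
        if dc:
            stoich["co2"] = Fraction(dc)
        if dn:
            stoich["nh3"] = Fraction(dn)
        cof = {}
        for c in ("NADH", "NADPH", "FADH2", "ATP"):
            d = int(rng.integers(-1, 2))
            if d:
                cof[c] = Fraction(d)
        reactions.append(Reaction(
            id=f"R{i}", enzyme=f"synthetic step {i}", genes=(),
            stoich=stoich, cofactor_delta=cof, block="transport",
            step_weight=0))

    rs = build_reaction_set(mets, reactions)
    k = int(rng.integers(1, 4))
    plant = Pathway("plant", tuple((f"R{i}", k) for i in range(n_reactions)),
                    description=f"planted chain, multiplicity {k}")
    from shunt_ledger.composer import compose
    conv, _ = compose(plant, rs)
    return rs, plant, conv
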