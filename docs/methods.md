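# Methods

## The pathway-accounting model

The package models metabolism as a set of reactions with signed rational
stoichiometry over metabolite pools plus net cofactor deltas (NADH, NADPH,
FADH₂, ATP). A pathway is an ordered multiset of (reaction, positive integer
multiplicity); composition is linear, so net conversions and cofactor
ledgers are multiplicity-weighted sums computed in exact `Fraction`
arithmetic. Floating point appears only when reports are rendered.

A composition is a *complete oxidation* when its net conversion is exactly
{glucose: −1, CO₂: +6} with every non-boundary metabolite cancelled.
Boundary species are glucose, CO₂, H₂O, Pi, and NH₃ (NH₃ is boundary so
that configurations without glutamate recycling remain well-posed). A
complete oxidation strips 24 electrons, i.e. 12 two-electron carrier
equivalents — asserted as an invariant for all bundled pathways.

### Accounting conventions

- **Transferable carbons.** Folate species count only the C₁ unit they
  carry (THF = 0, methylene-/methenyl-/10-formyl-THF = 1); CoA thioesters
  count their acyl unit (acetyl-CoA = 2, succinyl-CoA = 4). The carrier
  backbones are opaque. This makes per-reaction carbon and nitrogen
  conservation assertable exactly, without atom mapping.
- **Single ATP currency.** GTP made by succinyl-CoA synthetase is booked as
  ATP.
- **Not balance-checked:** protons, water, inorganic phosphate. The ledgers
  are at cofactor level.
- **Compartments** are recorded but not enforced by default: there is one
  pool per metabolite. An optional strict mode additionally reports net
  NADPH per reaction compartment, under which the mitochondrial formate
  release (MTHFD1L) / cytosolic re-fixation (MTHFD1) loop — ledger-neutral
  in default mode — becomes visible as the relocation of one NADPH
  equivalent per formate from mitochondrion to cytosol (ALDH1L2 → ALDH1L1).
- **MTHFD2 redox mode.** The methylene-THF dehydrogenase step is encoded
  NADP-dependent in the default shunt, reflecting NAD scarcity under
  complex I inhibition; an NAD-mode variant reaction ships in the
  knowledgebase but is excluded from the bundled pathway.
- **Glutamate recycling** for the serinogenesis transamination runs through
  glutamate dehydrogenase in NADH-consuming amination mode, so the
  serinogenesis block nets zero NADH per serine (+1 at PHGDH, −1 at GDH).

### Step counting

`count_steps` sums `step_weight` over the *distinct* reactions of a
pathway; multiplicities are ignored (an enzyme traversed by several
substrate molecules counts once). Weights encode the counting convention:

- aggregate complexes (glycine cleavage system, PDH) count 1;
- transport (SFXN1 serine import, formate export) counts 0;
- the glutamate-dehydrogenase recycling step counts 0 — it closes the
  transaminase loop of the serinogenesis block rather than lying on the
  glucose-to-CO₂ route, whose serinogenesis segment is the three reactions
  PHGDH/PSAT1/PSPH;
- the second transketolase reaction of the PPP (`TKT2`) counts 0 because
  the enzyme is already counted at `TKT1`; mitochondrial folate cycling is
  counted as four *reactions* (SHMT2, methylene-THF dehydrogenase,
  methenyl-THF cyclohydrolase, 10-formyl-THF dehydrogenase) even though the
  middle two share the bifunctional MTHFD2 protein. Reactions, not gene
  products, are the counting unit throughout, applied identically to all
  three routes.

This yields 7 + 3 + 4 + 1 = 15 steps for the shunt, 1 + 7 + 4 = 12 for the
PPP (hexokinase + core + gluconeogenic recycling), and 10 + 1 + 8 = 19 for
the canonic route.

### ATP-equivalence scenario

`ATPScenario` prices cofactor oxidation in ATP equivalents: NADH +5/2
(operable complex I), FADH₂ +3/2 (ETF/complex II entry), NADPH −3/2 (no
direct respiratory entry; disposal through fatty acid cycling converts it
1:1 into FADH₂ but the synthesis/activation overhead makes the round trip a
net cost), substrate-level ATP weight 1. All four parameters are overridable
(e.g. setting NADPH to +5/2 shows the shunt would deliver 30 ATP if NADPH
were directly respirable — a sanity sweep, not a physiological claim).
`atp_balance` is linear in the ledger.

The *axis* pathway (PPP feeding all 12 NADPH into fatty acid cycling) is
composed from the same reaction steps as the PPP route: the cycling
disposal is priced by the scenario, and the 1:1 NADPH → FADH₂ conversion is
exposed as the explicit `nadph_to_fadh2` operation. Derived quantities:
`nad_sparing` = 100·(NADH_ref − NADH)/NADH_ref against a NAD-consuming
reference, and the NADP:NAD production ratio (with an infinity sentinel for
fully NAD-independent ledgers).

### The multiplicity solver

`solve_multiplicities` exhaustively enumerates all multiplicity vectors in
{0..bound}ⁿ whose composition hits a target conversion with all other
metabolites cancelled — an independent oracle proving the hand-specified
multiplicities of the bundled pathways (e.g. ×2 after the triose split, ×4
folate cycling for the 2 serine- plus 2 glycine-derived C₁ units). The
depth-first enumeration prunes a branch once a metabolite that no remaining
reaction can touch differs from its target; this discards no solutions, and
the tests verify equality with literal product-space enumeration on small
networks. Limits (≤ 24 reactions, bound ≤ 8, explicit node budget) are
enforced by refusal, never silent truncation. Solutions are returned in
lexicographic order for determinism.

## The transcriptomic consensus model

Inputs are per-model DE summary tables (gene, fold change as a ratio,
BH-adjusted p, mean-expression proxy). DE estimation from counts,
normalization, and ortholog mapping are upstream concerns and out of scope.

Per gene: `low_expression` below the model's expression floor, else
`induced`/`suppressed` when padj is under the model threshold with fold
change above/below 1, else `unchanged`. Model profiles default to
padj < 10⁻⁶ for the two RNA-seq models (floors 1 RPKM-like and 5
baseMean-like units) and p < 0.05 for the microarray model (no floor, the
source data being pre-filtered). Thresholds are deliberately model-local:
the three experiments differ in platform, replication, and power, so
adjusted p-values are never pooled or compared across models; only
categorical verdicts cross the model boundary.

Per gene set, the aggregation rule — a formalization of how induction
tables are usually read, configurable and stated here prominently:
`low_expression` if every detected member is low; `induced` if at least
half of the evaluable (non-low) members are induced and none suppressed;
`suppressed` symmetrically; `mixed` when both directions occur; else
`unchanged`. Genes absent from a table are skipped and recorded, never
imputed; a fully absent set is an error.

Per candidate purpose, a rule lists gene sets that must all be induced
and/or a group of which at least one must be induced. A model *supports*
the purpose when the rule holds and no referenced set is suppressed or
mixed; a suppressed/mixed referenced set *contradicts* it. Across models:
`universal` (all models with data support), `partial` (some), `rejected`
(none). The bundled rules: catabolic NADPH production requires
serinogenesis plus at least one folate-cycling arm; oxidative stress
requires an antioxidant set; purine synthesis requires the de novo purine
set; DNA synthesis requires the pyrimidine/DNA set (suppression of
thymidylate synthesis or DHFR contradicts it); methylation requires the
methionine cycle.

## The synthetic-data generator

The generator emits DE *summary* tables directly — fold change, adjusted p,
expression proxy — rather than simulating reads or counts, because the
pipeline's contract is the summary table. Each table contains every gene of
every bundled gene set plus 10,000 null background genes (fold change
lognormal around 1 with log₂ σ = 0.25; adjusted p uniform on [0, 1];
expression uniform on [10, 1000]), sizes comparable to the filtered gene
universes of the emulated studies. Planted effects draw padj strictly
inside the model threshold (≤ 1% of it) with fold changes in [2, 8] (or
reciprocals for suppression); planted "unchanged" draws padj from
[0.5, 1]; low-expression plants draw below half the model's floor.
Inconsistent plants (e.g. "induced" with a padj range crossing the
threshold) are validation errors. Per-gene overrides take precedence over
set-level effects, which resolves genes shared between sets (CBS sits in
both the serine-anabolic and methionine-cycle sets) and lets a set be
planted `mixed`. Everything is deterministic given the seed (a named
numpy generator keyed on seed and model id).

The study-mimic scenario plants, per model, the qualitative pattern the
three study models exhibit: model 1 (MPP neurons) with broad shunt and
antioxidant induction, glycine cleavage under the expression floor, and
suppressed methylation/thymidylate enzymes; model 2 (MetR liver) with
shunt, glycine-cleavage, and purine induction, mixed antioxidants
(reductases up, direct antioxidants down), and suppressed DHFR/CAD;
model 3 (NDUFS2 fibroblasts) with serinogenesis and mitochondrial folate
induction only, plus suppressed DNA-synthesis enzymes. Running the
pipeline on these tables classifies catabolic NADPH production as
universal, oxidative stress and purine synthesis as partial, and DNA
synthesis and methylation as rejected.

What the generator does **not** emulate: count-level noise and dispersion
trends, library-size artifacts, correlated genes within sets, ortholog
dropout patterns, or p-value miscalibration. Passing tests therefore show
that the classifier and consensus logic implement their stated rules and
recover effects of the planted magnitude — not that the rules are robust to
real-data pathologies weaker or messier than the plants.

Random reaction networks for solver cross-checks are linear conversion
chains with non-increasing carbon/nitrogen content, off-gassing the element
difference as CO₂/NH₃ — balanced by construction, with a planted uniform
multiplicity that is provably the unique solution of its own boundary
target.

## Numerical and design choices

- Exact rationals everywhere in the accounting core; no tolerances exist to
  tune. Transcriptomic thresholds are strict inequalities (padj <
  threshold, fc > 1); fc = 1 is `unchanged` regardless of significance.
- Solver tie-break: lexicographic vector order. Empty pathways compose to
  zero; the zero vector solves the zero target.
- The comparison report refuses pathways that are not complete oxidations
  instead of normalizing them — like is compared with like, per glucose.
- Problem sizes: the accounting results are closed-form compositions
  (milliseconds); solver cross-checks run on 100 seeded chain networks of
  2–5 reactions at bound 4; null calibration uses 10⁴ null genes per model
  against 99% binomial bands.

## Known limitations

- No kinetics, thermodynamics, enzyme regulation, or flux estimation: the
  ledgers state what the stoichiometry permits, not what cells do.
- Compartment strictness extends only to NADPH attribution; no transporter
  thermodynamics or shuttle costs.
- The multiplicity solver is an oracle for small networks, not an
  elementary-flux-mode enumerator at scale.
- Real-data verdicts for the three study models can only be compared
  qualitatively with the published narrative; the quantitative test surface
  is the synthetic plants.
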