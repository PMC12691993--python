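# shunt-ledger

Exact stoichiometric accounting for the **serine–folate shunt** — an
alternative route of complete glucose oxidation that becomes relevant when
mitochondrial complex I (NADH dehydrogenase) is inhibited — plus a
cross-model transcriptomic consensus pipeline for deciding *why* cells
induce serine biosynthesis and folate cycling under such conditions.

## Who this is for

Researchers in mitochondrial (patho)biochemistry and metabolic
reprogramming who want auditable, exact cofactor bookkeeping for competing
glucose-degradation routes, and a reproducible way to compare gene-set
induction patterns across heterogeneous complex I inhibition models
(pharmacological, dietary, genetic) without pooling statistics across
incomparable experiments.

## The science in brief

Complex I inhibition raises NADH/NAD and throttles every NAD-dependent
oxidation, including the citric acid cycle. Three routes can still take one
glucose all the way to 6 CO₂, differing in which cofactor accepts the 24
electrons:

| route | per glucose | electron acceptors |
|---|---|---|
| glycolysis + PDH + citric acid cycle | 10 NADH, 2 FADH₂, +4 ATP | almost all NAD |
| pentose phosphate pathway (PPP), recycling via gluconeogenesis | 12 NADPH, −1 ATP | all NADP |
| partial glycolysis + serinogenesis + mitochondrial folate cycling + glycine cleavage (the *serine–folate shunt*) | 4 NADH, 8 NADPH, 0 ATP | mostly NADP (NADP:NAD = 2:1) |

NADPH has no respiratory entry point of its own; it can be disposed of by
concurrent fatty acid synthesis and β-oxidation ("fatty acid cycling"),
whose only net redox effect is NADPH → FADH₂ at 1:1 — FADH₂ then feeds the
chain via ETF, downstream of the blocked complex I. Pricing cofactors in ATP
equivalents (NADH +5/2, FADH₂ +3/2, NADPH −3/2 through cycling) gives
**+32** ATP for the canonic route, **−19** for the pure PPP/cycling axis,
and **−2** for the shunt: the shunt is a nearly energy-neutral way to keep
oxidizing glucose while sparing 60% of the limiting NAD. The same three
routes take 19, 12, and 15 enzymatic steps respectively (aggregate
complexes counted once, transport not counted).

Everything is computed from a curated reaction knowledgebase with signed
rational stoichiometry; carbon and nitrogen are conserved exactly in every
reaction (folate species carry only their transferable C₁ unit), and an
exhaustive integer-multiplicity solver independently proves the bundled
pathway definitions.

The transcriptomic half classifies pathway gene sets (induced / suppressed /
mixed / unchanged / low-expression) per model under model-specific
significance regimes (BH-adjusted p < 10⁻⁶ for the RNA-seq models, p < 0.05
for the microarray model — never compared across models), then applies a
purpose-rule table to decide which candidate purpose of serinogenesis
(catabolic NADPH production, oxidative-stress repair, purine synthesis, DNA
synthesis, methylation) is supported universally, partially, or not at all.
A synthetic-data generator emulates the three study models as DE summary
tables with planted effects, so the whole pipeline runs without downloads.

## Worked example

```bash
$ shunt-ledger compare
Pathway comparison (per glucose; reference: canonic_full)

pathway         NADH  NADPH  FADH2  subATP  ATP-bal  steps   spared%  NADP:NAD
canonic_full      10      0      2       4       32     19         0         0
axis_full          0     12      0      -1      -19     12       100       inf
shunt_full         4      8      0       0       -2     15        60         2
```

Each row is one complete oxidation of glucose: the net cofactor ledger, the
ATP balance under the default equivalence scenario, the enzymatic step
count, the percentage of the canonic route's NAD demand avoided, and the
NADP:NAD production ratio (`inf` = fully NAD-independent).

```bash
$ shunt-ledger compose shunt_full
pathway shunt_full
delta   co2     6
delta   glc     -1
ledger  NADH    4
ledger  NADPH   8
...
complete_oxidation      true    complete oxidation of glucose to six CO2
steps   15
```

The transcriptomic pipeline end to end, on synthetic tables:

```bash
shunt-ledger simulate de --model model1 --seed 17 --out m1.tsv
shunt-ledger simulate de --model model2 --seed 17 --out m2.tsv
shunt-ledger simulate de --model model3 --seed 17 --out m3.tsv
shunt-ledger consensus m1.tsv m2.tsv m3.tsv --models model1,model2,model3
```

prints a JSON report classifying `catabolic_nadph` as `universal` and
`oxidative_stress` / `purine_synthesis` as `partial`, with
`dna_synthesis` / `methylation` `rejected` — i.e. only catabolic NADPH
production is consistent with the induction patterns of all three models.

Other subcommands: `kb validate` (element-balance checking of reaction-set
files), `solve` (exhaustive multiplicity search), `atp`, `classify`,
`simulate network`.

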