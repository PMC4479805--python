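# acarflux

Constraint-based metabolic analysis toolkit for the acarbose producer
*Actinoplanes* sp. SE50/110 — and, more generally, for any small-to-genome-scale
stoichiometric model of a secondary-metabolite producer.

*Actinoplanes* sp. SE50/110 makes acarbose, an α-glucosidase inhibitor used
against type 2 diabetes. Engineering such a producer needs answers to a fixed
set of in-silico questions: how fast can the cell grow on a given medium, how
much product can it secrete at a given growth rate, which genes are essential
for growth or for product formation, which reactions should be overexpressed to
pull flux toward the product, and how does the production rate respond to the
oxygen supply. `acarflux` implements that whole workflow on top of a single
flux-balance core.

## The model and the analyses

A metabolic model is the steady-state linear system over reaction fluxes
*v* (mmol · gDCW⁻¹ · h⁻¹):

```
maximize  c·v     subject to   S v = 0,   lb ≤ v ≤ ub
```

where `S` is the stoichiometric matrix and the objective `c` selects the
biomass reaction (growth, h⁻¹) or a product exchange. Exchange reactions use
the standard convention (negative flux = uptake); a medium is a set of uptake
caps on exchanges. On this core the package provides:

* **FBA simulation modes** — growth under fitted uptake rates, maximal product
  secretion at fixed growth, robustness scans (objective vs. one fixed flux,
  e.g. acarbose production vs. oxygen uptake rate), and pathway flux ratios
  (e.g. pentose phosphate pathway vs. glycolysis). Degenerate alternate optima
  are tamed with parsimonious tie-breaking (secondary minimization of Σ|v|).
* **Biomass-equation construction** from macromolecular mass fractions and
  monomer tables: coefficient of monomer *i* in class *m* is
  `1000·f_m·x_i / M̄_m` mmol/gDCW, with DNA monomer fractions derived from the
  genomic G+C content (dGMP = dCMP = GC/2).
* **Essentiality screens** — single-gene and single-reaction deletions through
  boolean gene-protein-reaction (GPR) rules; a target is essential when
  grRatio = knockout/wild-type objective < 10⁻⁶. Product essentiality uses the
  production objective instead of growth.
* **FSEOF** (flux scanning based on enforced objective flux) — step the product
  flux up toward its maximum, re-optimize growth, classify every reaction's
  trajectory (increased / decreased / unchanged / irregular) and rank the
  increased ones as overexpression candidates.
* **Phenotype screens** — qualitative sole-carbon / sole-nitrogen growth calls
  against observed +/− tables.
* **Synthetic models with known ground truth** — a linear chain with a
  closed-form optimum, a branched growth/product trade-off with an analytic
  production frontier, and a ~40-reaction miniature acarbose producer
  (`make_mini_acb`) with maltose uptake, a glycolysis/PPP split feeding the
  C7-cyclitol precursor, a glutamate-dependent amination step, oxygen-coupled
  ATP generation, an exported condensation product and a TreY-like byproduct
  branch — all element-balanced, fully deterministic, and exercised by the
  test suite in place of the (non-public) published genome-scale model.

Models are read and written in a tabular (TSV) reaction-list dialect and in
SBML Level 3 with `fbc` bounds/GPRs (via python-libsbml); media are flat
YAML/JSON maps. The LP engine is `scipy.optimize.linprog` (HiGHS).

## Worked example

Generate the miniature producer model and run the pipeline on it:

```bash
acarflux make-fixture mini-acb --out demo
acarflux growth     --model demo/mini_acb.tsv --medium demo/synthesis.yaml --out demo/run
acarflux production --model demo/mini_acb.tsv --medium demo/synthesis.yaml \
                    --product EX_acb --out demo/run
acarflux essentiality --model demo/mini_acb.tsv --medium demo/synthesis.yaml --out demo/run
acarflux fseof      --model demo/mini_acb.tsv --medium demo/synthesis.yaml \
                    --product EX_acb --out demo/run
```

prints

```
mu=1.18238 /h
production=0.5 mmol/gDCW/h
10/26 targets essential
16 increased-class target reactions; genes: acbA, acbB, rmlB, acbC, acbI, acbJ, acbM, acbS
```

Reading: on the maltose/ammonium minimal medium the wild type grows at
1.18 h⁻¹; with growth pinned to zero every available hexose can be routed into
the product, giving the stoichiometric maximum of 0.5 mmol acarbose per
2 × 0.5 mmol maltose (two maltose per product molecule). Ten of the 26 genes
are growth-essential; the FSEOF scan nominates the product-pathway genes plus
the S7P-forming transketolase (`tkt1`) and the glutamate-forming step (`gdh1`)
for overexpression.

The oxygen robustness scan (substrate capped at 0.1, growth fixed at 0, oxygen
exchange fixed point-by-point):

```bash
acarflux robustness --model demo/mini_acb.tsv --medium demo/robustness.yaml \
                    --scan EX_o2 --grid "-1:0:21" --objective EX_acb \
                    --fix BIOMASS=0 --out demo/run
# -> peak objective 0.0487179 at EX_o2=-0.25
```

i.e. the production rate rises with oxygen uptake up to 0.25 mmol/gDCW/h and
falls beyond it — the rise-then-fall response of product formation to
dissolved oxygen, reproduced by the miniature model's redox/ATP architecture.

Every command drops a `manifest.json` (hashed inputs, echoed parameters,
solver identity) next to its TSV/JSON artifacts; identical configs yield
byte-identical artifacts.

## Layout

```
src/acarflux/
  model.py        core types, stoichiometric matrix, balance check, deletions
  gpr.py          GPR boolean rules (parser + evaluation)
  medium.py       medium specs and their application to exchange bounds
  fba.py          LP engine, growth/production/robustness/ratio modes
  biomass.py      biomass-equation construction from composition data
  essentiality.py gene/reaction deletion screens and subsystem summaries
  fseof.py        FSEOF scan, profile classification, target ranking
  phenotype.py    sole-source growth screens and observed-table comparison
  synthetic.py    deterministic generators (chain, branched, mini producer)
  io.py           tabular + SBML model I/O, medium configs, flux tables
  cli.py          `acarflux` command-line entry point
docs/methods.md   modelling assumptions, parameter choices, limitations
```
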