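# Methods

## Flux balance analysis

The core computation is the linear program

    maximize (or minimize)  v_obj
    subject to              S v = 0,   lb <= v <= ub

over the flux vector *v* in mmol·gDCW⁻¹·h⁻¹ (the biomass reaction's flux is
the specific growth rate in h⁻¹). The steady-state assumption means internal
metabolite pools neither accumulate nor deplete; everything entering the cell
leaves as biomass, secreted products, CO₂ or water. The LP is solved with
HiGHS through `scipy.optimize.linprog`; the solver is deterministic, so optima
are reproducible across runs to well below 10⁻⁹.

**Sign conventions.** Negative stoichiometric coefficients are substrates.
Exchange reactions are written `M[e] <=> (boundary)`, so uptake is negative
flux. Media are specified with positive uptake caps and converted to lower
bounds internally; equality constraints (fitted rates, enforced product
fluxes, fixed growth) are implemented as `lb = ub`. Applying a medium first
closes *all* exchanges to uptake, so an empty medium supports no growth and a
medium is a complete statement of what the cell may consume.

**Alternate optima.** FBA optima are typically degenerate: the objective value
is unique but individual fluxes are not. The contract of this package is
therefore the objective value; whenever downstream analyses consume flux
*vectors* (FSEOF trajectories, pathway flux ratios, flux tables) a
parsimonious tie-break is applied — total absolute flux Σ|v| is minimized in a
second LP with the objective pinned at its optimum. Without this step the
FSEOF classes would depend on solver vagaries.

**Statuses.** Infeasible and unbounded solves are reported as such, never as
silent zeros. A *blocked* objective (feasible model, zero attainable flux)
reports `optimal` with value 0, which is the scientifically meaningful answer
for "can this cell grow / produce here".

## Biomass equation

One unit of biomass flux drains 1 g of dry cell mass in monomer precursors.
For macromolecule class *m* with mass fraction `f_m` (g/gDCW) and monomer mole
fractions `x_i` with residue molar masses `M_i` (g/mol, polymerized form —
water of condensation removed), the coefficient of monomer *i* is

    coeff_i = 1000 * f_m * x_i / M̄_m,   M̄_m = Σ_i x_i M_i    [mmol/gDCW]

Residue masses rather than free-monomer masses are used because the measured
mass fractions refer to polymer mass; with them the reconstruction identity
Σ coeff_i·M_i/1000 = 1 g holds exactly by construction, and the test suite
verifies it to 10⁻³ g over randomized valid compositions.

Defaults encode the organism's composition: 58% protein, 1% DNA, 11% RNA, 5%
lipid, 22% cell wall, 3% small molecules; DNA monomer fractions follow from
the genomic G+C content of 71.3% via base pairing (dGMP = dCMP = GC/2,
dAMP = dTMP = (1−GC)/2, purine fraction always ½); the RNA pool is split
5/75/20 into mRNA/rRNA/tRNA. The monomer mole-fraction tables (amino acid
profile, RNA base composition, lumped lipid / cell-wall / small-molecule
precursors) are **editable synthetic templates**, clearly marked as such in
the code: the measured profiles live only in non-public supplementary data,
and the template values are stand-ins chosen at biologically plausible
magnitudes. The growth-associated ATP requirement (GAM) defaults to
40 mmol ATP/gDCW, a typical actinomycete-scale value; it is a free parameter
of `BiomassComposition`. Composition is treated as independent of the
cultivation environment.

## Essentiality

Gene deletions act through GPR rules: a reaction is disabled (bounds set to
zero) when its boolean rule evaluates false with the deleted genes set to
false; empty rules never disable. grRatio is the knockout optimum divided by
the wild-type optimum, with the wild type solved once per screen so every
ratio shares a denominator; a target is essential when grRatio < 10⁻⁶. Genes
in no GPR are still reported (grRatio 1) so gene counts match the model.
The medium is applied *before* the deletions so that knocking out a
medium-opened exchange reaction is honoured rather than silently re-opened.

Product essentiality replaces the growth objective by the product exchange
with biomass fixed at a configurable rate (default 0 = pure capability). On
the miniature producer model this cleanly separates the single-copy product-
pathway genes (product-essential, growth-dispensable) from the isozyme pair
guarding the dehydratase step (neither member essential) and from the
TreY-like byproduct gene (dispensable for both, but its deletion abolishes
byproduct capability).

## FSEOF

The theoretical maximum product flux v_max is found first; step *k* of *n*
then fixes the product flux at `(k/n)·f·v_max` and maximizes growth with the
parsimonious tie-break. The enforcement fraction defaults to f = 0.9 with
n = 10 steps: points at or near v_max leave no room for growth and are often
infeasible, and ten steps are enough for the four-way classification to be
stable (the suite checks 10 vs. 20 steps). A trajectory is *increased* when
every successive difference is ≥ −tol and the total change is > tol,
*decreased* symmetrically, *unchanged* when all differences are within tol,
otherwise *irregular*; tol defaults to 10⁻⁶·max(1, |mean flux|) and is
configurable. Whether to fix or maximize biomass during scanning is a genuine
design fork; maximization is used here (the standard formulation), which also
yields the expected monotone decline of growth along the scan.

## Robustness scans

A robustness curve fixes one reaction's flux at each point of a strictly
increasing grid and re-optimizes the objective; infeasible points are recorded
as such rather than interpolated. The headline use is product formation versus
oxygen uptake rate (OUR): the oxygen exchange flux is fixed point-by-point
while the substrate is capped and growth fixed. In the miniature model the
curve is zero at OUR = 0 (respiration is the only NADH sink, and the product
pathway is obligately NADH-generating), rises while oxygen relieves the
ATP/redox limitation, and falls once the *forced* oxygen turnover burns
substrate carbon to CO₂ that product synthesis needs — the rise-then-fall
response of secondary-metabolite formation to dissolved oxygen. The scan
conditions packaged with the model (substrate cap 0.1 mmol/gDCW/h, growth
fixed at 0, OUR grid 0–1) put the peak in the grid interior; the suite checks
unimodality and that a 21-point and a 201-point grid locate the same peak
within one coarse step.

## The synthetic models

`make_linear_chain(n, y, cap)` — n lossy conversion steps; optimum `cap·yⁿ`
in closed form. `make_branched_tradeoff(cap, Y_b, Y_p)` — growth and product
compete linearly for one substrate; at fixed growth μ the production frontier
is `Y_p·(cap − μ/Y_b)`. Both serve as analytic oracles for the LP engine, and
an exhaustive vertex-enumeration oracle in the test suite independently
confirms every toy optimum.

`make_mini_acb()` emulates the architecture the real producer's analyses rely
on, at ~40 reactions and 26 genes: an ATP-driven maltose importer and kinase;
a lumped glycolysis competing with the oxidative PPP; the PPP supplying both
NADPH and sedoheptulose 7-phosphate, the C7-cyclitol precursor; a glutamate
node (glutamate dehydrogenase) feeding biomass and the glutamate-dependent
aminotransferase of the dTDP-aminosugar branch, with glutamate recycled
through 2-oxoglutarate; condensation, glucosyl extension, dephosphorylation
and ATP-driven export of the product through a two-subunit (AND-rule)
transporter; a dehydratase step guarded by an isozyme pair (OR rule); and a
TreY-like branch diverting the phosphorylated precursor to an exported
byproduct. Stoichiometry uses simplified elemental bookkeeping — C/H/O/N/P
plus opaque carrier cores (A, D, Q, T for the adenylate, NAD, NADP and dTDP
moieties) — so that every internal reaction is exactly element-balanced and
the balance checker runs with zero skips. All coefficients are synthetic
package constants; the model is a structural analogue, not a fit. The
extracellular product is terminal by design: the hypothesised extracellular/
intracellular product-recycling cycle is deliberately absent, and a test
asserts its absence.

What the miniature model does *not* emulate: genome-scale redundancy (most
real subsystems contain parallel routes, so real essentiality fractions are
far lower), thermodynamic or enzyme-capacity constraints, maintenance energy
magnitudes (the maintenance ATPase exists but is not forced), and realistic
yields — its numbers are internally consistent, not literature values. Tests
passing on it therefore demonstrate the correctness of the *algorithms* and
the qualitative network behaviour, not quantitative predictions for the real
organism.

## Numerical choices and degenerate inputs

* LP feasibility/steady-state tolerance asserted at 10⁻⁶; optimum
  reproducibility at 10⁻⁹ (deterministic solver, fixed construction order).
* Growth/no-growth and essentiality threshold: 10⁻⁶ h⁻¹ (grRatio < 10⁻⁶).
* Default bounds where a file states none: (−1000, 1000) reversible,
  (0, 1000) irreversible — the de-facto convention.
* Balance checking skips (and lists) metabolites with unknown formulas
  instead of failing, because curated and auto-generated entries coexist in
  real reconstructions; exchanges and the biomass pseudo-reaction are exempt.
* The phenotype screens use a 10 mmol/gDCW/h uptake cap; qualitative calls
  are cap-invariant above zero, asserted by screening at two caps.
* Zero-denominator pathway ratios raise an explicit error rather than
  returning infinity.
* Empty or non-increasing robustness grids, sub-3-step FSEOF scans and
  unproducible products are rejected with diagnostics up front.

## Problem sizes

The packaged analyses run on the synthetic models (≤ 41 reactions); the full
test suite and the acceptance script each complete in a few seconds on one
CPU. The same code paths scale to genome-scale models (a ~1200-reaction LP
solves in well under a second with HiGHS); only the exhaustive test oracles
(vertex enumeration, truth tables) are restricted to toy sizes by design.
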