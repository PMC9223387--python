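# Methods

This note documents the models, algorithms, numerical choices, and known
limitations behind `finflux`. It is the companion to the API docstrings: the
docstrings say what each function does; this note says why it is built the
way it is and what a passing test does and does not establish.

## Constraint-based growth prediction

All growth predictions are flux balance analysis (FBA): maximize a linear
objective c·v over flux vectors v subject to steady state S·v = 0 and bounds
lb ≤ v ≤ ub, where S is the stoichiometric matrix. The biomass
pseudo-reaction drains precursors in mass-normalized proportions, so its
flux is the specific growth rate μ (h⁻¹ per gDW). Parsimonious FBA (pFBA)
fixes growth at a fraction of the FBA optimum (default 1.0) and minimizes
Σ|v|; because the optlang backend already represents each flux as the
difference of two non-negative variables, the L1 norm is minimized exactly
by a second LP over the split variables, not by an objective-weight
heuristic. Solver: GLPK through COBRApy/optlang, with LP tolerance 1e-9 and
a separate validation tolerance of 1e-6 used wherever a quantity is compared
against zero (steady-state residuals, "zero growth", bound activity). These
two values are pinned so that limiting-reaction detection is reproducible
across machines.

Reduced costs are reported with cobra's convention — the derivative of the
objective with respect to the flux variable. Because dual solutions are not
unique at degenerate vertices, no algorithm in this package relies on a
reduced-cost *sign or value* alone for a yes/no decision (see the feed
analysis below).

Degenerate alternate optima are accepted: any optimal vertex may be
returned, and all tests assert only solution-invariant quantities
(objective values, limiting sets, secretion totals, L1 norms).

## The synthetic salmon-like core model

`synthetic_data.generate_toy_model` builds a ~100-reaction model with
compartments extracellular/cytosol/mitochondrion that reproduces the traits
the downstream analyses depend on:

* **Amino acids.** All 20 proteinogenic amino acids have exchange,
  import-only transport, and oxidizable degradation (to pyruvate + NH3).
  The ten fish-essential ones (Arg, His, Ile, Leu, Lys, Met, Phe, Thr, Trp,
  Val) have no synthesis route; the other ten are synthesizable from
  pyruvate + NH3 + ATP. Import-only amino-acid transport encodes the fact
  that fish retain or catabolize amino acids rather than excreting them, and
  it is what makes the minimal secretion set {CO2, NH3} unique.
* **Energy.** Lumped glycolysis (glc → 2 pyr + 2 ATP), mitochondrial
  respiration (pyr + 2.5 O2 → 3 CO2 + 12.5 ATP), gluconeogenesis, and an
  optional lactate fermentation route. Without the fermentation route the
  model is an obligate aerobe on a glucose-free feed.
* **Nitrogen disposal.** Ammonia export is ATP-free; the urea cycle costs
  2 ATP per urea and carries a curated capacity of 0.05 mmol/gDW/h,
  representing the low ureotelic capacity of teleosts. The cap is what makes
  ammonia irreplaceable at physiological growth rates.
* **Biomass.** Macromolecule mass fractions default to protein 0.55, lipid
  0.35, carbohydrate 0.04, nucleic acid 0.06 (representative of salmonid
  whole-body dry matter); protein is an equal-mass blend of the included
  amino acids, lipid is phosphatidylcholine (choline + glucose carbon +
  phosphate), carbohydrate a glycogen unit, nucleic acid a generic NTP.
  Monomer coefficients are 1000·fraction·w/M mmol/gDW with amino acids
  priced at residue mass (free mass − water), so one unit of biomass flux
  drains exactly 1 g of precursors. Protein synthesis costs 30 mmol ATP per
  g protein by default — a free parameter of the model class, not a measured
  value.
* **Choline.** Required for lipid synthesis and degradable by a lumped
  oxidative betaine/glycine route (choline + O2 → pyruvate + NH3). The
  degradation route matters: feed bundles deliver nutrients in fixed ratios,
  and a nutrient with no catabolic route and no exporter would otherwise pin
  growth to zero whenever it is over-supplied.

Lumped reactions are *mass*-closed with a fractional water makeweight
(stoichiometry · molar mass sums to zero); elemental balance is not enforced
for lumped conversions. Metabolite masses ride along in SBML/JSON notes.

What the generator does **not** emulate: genome-scale redundancy (isozymes,
alternative pathways), compartment-specific cofactor pools, thermodynamic
constraints, and realistic absolute flux scales. A green test on the toy
establishes algorithmic correctness against constructed ground truth, not
quantitative agreement with any real organism.

## Randomized oxygen-limited growth

Each condition draws uniform feed ratios in [1, 100] for the minimal-feed
nutrients (essential amino acids + choline) and lognormal capacity bounds
ln b ~ N(0, 2²), one per direction of every internal/transport reaction that
carries the default big bound (curated capacities such as the urea cap are
treated as knowledge, not uncertainty, and kept). A master seed spawns
per-condition child seeds, so the full sweep is reproducible from one
integer.

Per condition, the feed becomes a boundary reaction normalized to deliver
1 g of nutrients per unit flux and capped at `feed_total_mass`
(default 10 g·gDW⁻¹·h⁻¹ — arbitrary, chosen large enough that feed is not
the binding constraint; only relative growth is interpreted). Phosphate and
water are freely exchanged, all other uptakes are closed, and secretion of
feed nutrients is disabled. The oxygen axis is a 50-point (configurable)
log-spaced grid on (0, r_max], where r_max is the minimal oxygen uptake
supporting that condition's unconstrained-oxygen optimum; the top grid point
is included so relative growth reaches 1 (a documented deviation from a
fully open interval). pFBA is solved at every grid point; infeasible or
zero-growth points are recorded with their status and excluded from means
rather than dropped silently.

The canonical experiment runs the obligate-aerobe model variant: on the
minimal feed the modeled system grows strictly aerobically, and with a
fermentation route present the bundle-forced surplus carbon would exit as
lactate at low oxygen, distorting the CO2/NH3-dominated secretion profile
the sweep is meant to exhibit.

Downstream summaries: percentile bootstrap (1,000 resamples over conditions)
for 95% bands on the mean relative growth; limiting reactions = flux within
1e-6 of a non-zero bound (zero bounds never flag); flux clustering = per
reaction and condition, |v| normalized by its maximum over that condition's
oxygen levels, then Ward/Euclidean agglomeration cut into k = 8 clusters
(fixed k, since a height cut is not well defined across runs); pathway
enrichment = one-sided hypergeometric tails with Benjamini–Hochberg
adjustment over pathways, model genes as background, recall = fraction of a
pathway's genes found in the cluster.

## Growth-versus-saturation curve fitting

Three forms map water oxygen saturation x (fraction of air saturation) to
relative growth μ/μ_max:

* metabolic: r/r_max = clip((x − x0)/(x1 − x0), 0, 1) composed with a
  linear interpolator f of metabolic-model predictions, μ/μ_max = f(r/r_max);
* logistic: 2/(1 + e^{k(x0 − x)}) − 1 (asymptotes −1 and 1, zero at x0);
* Monod with intercept: (x − x0)/(Ks + x − x0) for x ≥ x0, half-maximal at
  x0 + Ks.

Fitting is nonlinear least squares (Levenberg–Marquardt; trust-region for
the piecewise form, whose Jacobian is discontinuous at the knots), with
data-driven starting values — x0 from the smallest x with μ_rel > 0.05, x1
from the smallest x with μ_rel > 0.95, k = 4/(x1 − x0), Ks = (x1 − x0)/2.
Standard errors come from the Jacobian covariance σ²(JᵀJ)⁻¹ at the optimum;
R² = 1 − SS_res/SS_tot. Non-convergence is returned as a flagged result.
The interpolator f is anchored at (0, 0): zero oxygen uptake means zero
aerobic growth.

## Feed limiting-amino-acid analysis

A feed composition (mass % per amino acid, with combined Asn/Asp and
Gln/Glu entries split half/half) becomes a boundary reaction with
coefficients 1000·w_i/M_i mmol per unit flux, so one unit of feed flux
supplies 1 g of amino-acid mass; free (hydrolysate) molar masses are used
for feed accounting. With growth fixed (default 1 — arbitrary, since only
relative efficiencies are interpreted), glucose/oxygen/phosphate/choline
freely available, amino-acid import blocked (surplus export open), total
purchased mass is minimized. The candidate limiting amino acid is the one
maximizing |M_i · reduced cost| on its closed exchange; because duals are
non-unique at degenerate optima (perfectly balanced feeds, fully
supplemented end states), the winner is confirmed by one perturbation solve
— supplementing a truly limiting amino acid at mass parity must strictly
lower the total cost — and candidates failing confirmation are skipped.
Supplementation opens the winner's exchange import-only, prices it at its
molar mass (cost parity with feed; a `penalty_scale` hook allows costlier
supplements), and repeats until nothing is limiting. Feed efficiency is
growth over total purchased mass (gDW/g) with the inverse (mg consumed per
gDW) also reported; it is non-decreasing along the trace because each step
adds an option priced at parity.

The `balanced_feed` helper computes a provably none-limiting feed from the
model's cheapest amino-acid diet LP rather than from protein stoichiometry
alone: nucleotide synthesis consumes nitrogen beyond protein demand, so a
protein-proportional feed is slightly nitrogen-short and its densest
nitrogen carrier would register as limiting.

## Capability screens and minimal sets

Essentiality: with every boundary reaction open in both directions, each
nutrient's import is disabled alone and growth re-maximized; essential means
growth ≤ 1e-6 (the zero-growth threshold is a package choice — "required
for growth" needs a numeric cutoff).

Metabolic tasks specify required uptakes (caps) and secretions (minimum
rates) by metabolite; all other boundaries are closed (water stays free),
task metabolites from compartments the model lacks are remapped to the
cytosol via a temporary boundary reaction, and the task passes when LP
feasibility matches its expectation. Entirely absent metabolites report
"unmappable".

Minimal uptake/secretion sets are enumerated by MILP: one binary indicator
per candidate boundary metabolite gates its import (or forces a minimum
efflux of 1e-3 for secretion candidates), the active-indicator count is
minimized, and exclusion cuts (Σ_{i∈S} y_i ≤ |S|−1) enumerate successive
sets. Each returned set is additionally verified support-minimal by
re-solving with each member removed. Uptake sets are enumerated with all
secretions open; secretion sets with the previously found uptakes open.
Water is treated as free and never reported. The enumeration runs on a
private model copy because binary variables do not roll back cleanly
through the GLPK context history.

## Model comparison

Models sharing a reaction namespace are reduced to binary vectors over the
union of non-boundary reactions whose metabolites all lie in shared
intracellular compartments (default: cytosol, mitochondrion, peroxisome
intersected with what the models have). Sixteen dissimilarity measures
(eight boolean: Jaccard, Dice, Hamming, Rogers–Tanimoto, Sokal–Sneath,
Russell–Rao, Yule, Kulczynski; eight numeric on the binary rows: Euclidean,
cityblock, cosine, correlation, Chebyshev, Canberra, Bray–Curtis, squared
Euclidean) are combined with five linkage methods (single, complete,
average, weighted, Ward) for an 80-tree sweep. Kulczynski's 1927 coefficient
is implemented in-package (removed from scipy 1.17); non-finite distances
from ratio-based measures on degenerate profiles are replaced by the largest
finite distance so linkage stays defined. The cophenetic correlation
coefficient is the Pearson correlation between the strict upper triangles of
the input dissimilarities and the dendrogram's merge-height distances,
computed against the same dissimilarity used to build the tree (the standard
definition; pass a Euclidean matrix explicitly to force the literal
alternative). Clade support for a group of models is the fraction of the 80
trees containing a node whose leaf set equals the group exactly. Zero
variance in either distance vector raises an explicit error instead of
propagating NaN.

## Known limitations

* The toy model's absolute rates (growth ~3.6 h⁻¹ on the reference feed)
  are not physiological; every analysis interprets ratios only.
* Russell–Rao does not satisfy identity of indiscernibles by definition;
  it is kept in the registry because the comparison sweep uses the field's
  standard (scipy) definitions.
* The MILP enumerator uses big-M indicator constraints (M = 1000); bounds
  beyond that magnitude would need a larger M.
* Growth-curve fitting pools observations unweighted; if observations come
  from multiple studies with different noise levels, the user must weight
  or normalize beforehand.
* Conditionally essential amino acids (e.g. glycine, proline in some
  species) are treated as strictly non-essential in the toy.
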