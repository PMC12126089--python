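# Methods

This note documents the models, defaults and design choices behind
`butyrnet`, in the order data flows through the package.

## Community flux-balance model

Each organism is a set of reactions with flux bounds (mmol·gDW⁻¹·h⁻¹).
Exchange reactions follow the export convention: the exchanged metabolite
has coefficient −1, positive flux is secretion, negative flux is uptake, and
a growth medium is one nonnegative maximum-uptake rate per metabolite.

A community of *n* members is block-joined: every metabolite a member
touches is balanced inside that member's namespace; each medium-visible
metabolite *m* gets a community-wide balance row
Σ<sub>k</sub> a<sub>k</sub>·v<sup>ex</sup><sub>k,m</sub> − u<sub>m</sub> = 0
and one community exchange u<sub>m</sub> ∈ [−cap(m), 1000]. Abundances are
uniform, a<sub>k</sub> = 1/n, and fixed — the package models defined
consortia under idealized even colonisation, not abundance dynamics.
Butyrate can never be taken up from the medium (its cap is forced to 0), so
reported butyrate is always community-made.

### Staged objective

Butyrate export is computed by a cooperative-tradeoff scheme in four linear
programs, all solved with HiGHS (scipy):

1. **Growth.** max μ = Σ a<sub>k</sub> v<sub>bio,k</sub> → μ\*.
2. **Butyrate.** max u<sub>but</sub> subject to μ ≥ τ·μ\*. The optimum b\*
   is the reported `butyrate_flux`. Default tradeoff τ = 0.5: the community
   must retain at least half its optimal growth while export is probed. τ is
   a free parameter in (0, 1]; butyrate is non-increasing in τ by
   construction.
3. **Growth again**, at u<sub>but</sub> ≥ b\*: makes the reported growth a
   unique optimum value rather than an arbitrary point of a degenerate face.
4. **Parsimony.** min Σ|v| at the fixed optima (slack 10⁻⁷). This resolves
   alternate optima, making flux vectors — and everything derived from them,
   notably the cross-feeding labels — reproducible across solvers and
   platforms. Without it, metabolite transfers that contribute nothing to
   growth or butyrate would appear or vanish arbitrarily.

Numerical tolerances: solver primal feasibility 10⁻⁹; reported invariants
(mass balance of returned vectors, growth bookkeeping) 10⁻⁶. Infeasible
communities are reported as `infeasible` with NaN butyrate — never silently
as zero — and excluded from training sets. A community with no butyrate
exchange yields flux 0 with a warning.

This staged scheme is a deliberate, fully specified approximation of
cooperative-tradeoff community simulators in the MICOM family; per-member
growth regularisation and abundance optimisation are out of scope.

## Synthetic pool generator

The generator emulates a gut-bacteria candidate pool in which every member
ferments carbon and a minority can convert fermentation products to
butyrate. Toy metabolite masses (carbon 4, precursor 2, acetate 2,
intermediate 4, butyrate 6) make every interior conversion reaction
mass-consistent; biomass and the precursor sink are boundary drains, as in
any constraint-based model.

Planted route:

* `CAT_c<i>`: 1 carbon → 1 precursor + 1 acetate (acetate is secretable);
* `BUTS`: 2 acetate + 1 precursor → 1 butyrate;
* `BIOMASS`: 1 precursor + 1 mineral → growth.

The 2:1 acetate demand is the load-bearing choice: a producer growing alone
is acetate-limited, so acetate secreted by a partner strictly increases
community butyrate. This gives cross-feeding a real optimum-changing effect
rather than a degenerate alternative solution, which is what the pair
labelling, the classifier and ultimately the regressors are asked to
recover. Generic intermediates (`SEC_im<j>`/`USE_im<j>`) add a second,
rarer cross-feed channel; decoy reactions (isolated metabolite pairs, forced
to zero flux) pad the descriptor universe with structure that carries no
signal.

Defaults, chosen once as the package's reference conditions:

| parameter | default | rationale |
|---|---|---|
| carbon sources | 2 | sparse carbon repertoires drive label variance |
| intermediates | 2 (acetate + 1 generic) | one dominant, one rare cross-feed route |
| decoy reactions | 14 | universe of 27 reactions ≥ the 25 kept descriptors |
| carbon-module inclusion | 0.45 per organism | members differ in carbon access |
| default uptake cap | 10 mmol·gDW⁻¹·h⁻¹ | conventional flux-balance magnitude |
| pool | 19 organisms, 6 producers | a gut-pool-sized roster with a producer minority |

Organisms are random universe subsets that always contain biomass, the
acetate exchange, the mineral exchange and at least one medium-open carbon
module; exactly the designated producers carry `BUTS` and the butyrate
exchange. Feasibility is enforced at generation (every organism must grow
alone on the medium; infeasible draws are resampled, up to 50 retries)
rather than filtered afterwards. Generation is deterministic per seed, to
the byte, across runs.

What the generator does **not** emulate: real reaction inventories,
curated media, thermodynamics, regulation, abundance dynamics or noise in
measured butyrate. Passing tests therefore demonstrate that the pipeline
recovers a planted, mechanistically consistent signal — not that it
predicts butyrate in vivo.

## Pair labelling and the cross-feeding classifier

A pair is labelled cross-feeding (1) when, at the two-member stage-2
optimum, some medium metabolite is secreted by one member and taken up by
the other with flux ≥ ε on both sides (ε = 10⁻⁶ mmol·gDW⁻¹·h⁻¹). The rule
is this package's operational definition; thanks to the parsimony stage it
captures transfers the community actually exploits. Infeasible pairs are
excluded. The classifier is a gradient-boosted tree ensemble (200 trees,
depth 4, learning rate 0.1, single-thread, seeded — deterministic) on the
concatenated presence vectors of the lexicographically ordered pair;
probabilities are symmetric because pairs are canonicalised before
featurisation.

## Encoding

Reactions are ranked by summed gradient-boosting importance over their two
positional copies in the pair features; ties break lexicographically by
reaction id, so selection is total and reproducible. One **shared** top-25
set represents every member — this single-set reading is what yields the
51/78/106 dimension law 25·n + C(n, 2) exactly, and the per-size column
naming is positional (block index, not organism id) so one model serves all
consortia of a size. Consortia are enumerated as all size-s subsets with at
least one producer (count C(n, s) − C(n−p, s)); members and pair slots are
ordered lexicographically, making the encoding invariant to input order.

## Regression

Per-size regressors with the default grids: elastic net (α ∈ {0.1, 1, 10,
100}, l1 ratio ∈ {0.1, 0.5, 0.7, 1.0}), k-nearest neighbours (k 1–21,
uniform/distance, euclidean/manhattan), random forest (trees {50, 100, 150,
200}, features sqrt/log2, depth {None, 10, 20, 30}), SVR (C ∈ {0.1, 1, 10},
rbf/linear, γ scale/auto, ε = 0.1), gradient boosting (trees {50, 100,
200}, learning rate {0.01, 0.1, 0.2}, depth {3, 5, 7}). The forest grids
state endpoints only in their source ranges; the intermediate values above
are this package's choice. Selection minimises mean validation MSE under
5-fold CV (k unspecified upstream; 5 is the conventional default,
configurable), ties broken by grid order; binary/probability features are
standardised on the training fold only for the scale-sensitive families
(elastic net, SVR) and left raw for tree/neighbour families. Splits are
seeded 75/25 with a floor rule on the training size.

## Evaluation

Pearson and Spearman (average ranks on ties) with two-sided p-values,
significance at p < 0.05; "linear correlation" is reported as an ordinary
least-squares fit (slope, intercept, r²); MSE. Zero-variance inputs make
correlations undefined and are reported as missing with a reason, never as
0. The mechanistic simulator itself is carried as a baseline row in every
comparison table. An external CSV of measured butyrate can replace the
simulator's holdout as the reference (blind-validation mode); no measured
dataset ships with the package, so bundled checks use simulator holdouts
only. Units are flux units (mmol·gDW⁻¹·h⁻¹) throughout; no conversion to
culture concentrations (mmol/L) is attempted, and reports label units
explicitly.

## Problem sizes in the bundled checks

The reference ("quickstart") conditions used by the test suite: the
19-organism / 6-producer pool above, all 776 consortia of sizes 2–3
(93 + 683), all 171 pairs, k = 25, τ = 0.5, seed 1. At these sizes the full
five-family grid search and every simulation complete in a few minutes on a
single CPU. Larger consortium sizes (up to 13) are supported by the same
code paths; enumeration grows combinatorially, and users scale by sampling
sizes rather than by any change to the method. The solver-versus-oracle
checks use randomly generated single-member communities with at most 8 LP
variables so that brute-force vertex enumeration remains exact.

## Known limitations

* The staged LP is an approximation of richer community-simulation
  objectives; absolute flux values depend on the tradeoff τ.
* Uniform abundances are assumed everywhere; no dynamic or spatial effects.
* The cross-feeding label is binary and thresholded; weak or condition-
  dependent interactions below ε are labelled 0.
* Descriptor selection is driven by pair-interaction labels, not by
  butyrate itself; descriptors that matter for butyrate but not for pairwise
  interaction can be dropped when the universe is much larger than k.
* Synthetic pools are structurally simple; performance numbers obtained on
  them do not transfer to real genome-scale reconstructions.
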