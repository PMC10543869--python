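# Methods

`bednetopt` is a deterministic simulator-plus-optimizer for the design of
long-lasting insecticidal nets (LLINs): given two candidate insecticides,
a resistance-management strategy and a public-health budget, it searches
exhaustively over loading concentrations and deployment lifespans for the
designs that are optimal under several policy-relevant criteria.

## The model

### Net properties

Four idealised curves in net age *t* (years since deployment):

* **Chemical decay** — residual concentration `L(t) = c · exp(−d_c t)`,
  with loading `c` in relative units (1 = the AI's standard solo dose).
* **Mortality decay** — `M(t) = q · σ(d_m (t + x) + h_m)` with
  `σ` the standard logistic and `x = −ln(c)/d_c`. The midpoint shift `x`
  guarantees that equal residual concentrations always produce equal
  mortality, whatever the starting loading. `q ∈ [0,1]` is the mosquito's
  resistance phenotype (1 = fully susceptible). An unloaded panel
  (`c = 0`) kills nothing; this is the `c → 0⁺` limit of the shifted
  logistic when `d_m < 0`.
* **Physical decay** — barrier probability `P(t) = u · σ(d_p t + h_p)`,
  where `u` is the proportional use rate at receipt. Mortality requires
  an intact, in-use net: fitness effects are always `V · P · M`.
* **Price and coverage** — a net costs `a + c₁k₁ + c₂k₂` (mixture) or
  `a + (c₁k₁ + c₂k₂)/2` (mosaic/rotation, whose purchases split
  half-and-half between two single-AI net types; the same averaging is
  applied to rotations as a deliberate assumption about alternating
  purchase cycles). Coverage is
  `V = min(1, lifespan · budget / (3 · price))` — normalised so that a
  budget equal to the price at the standard 3-year lifespan buys exactly
  universal coverage. The cap at 1 is a modelling choice: more-than-
  universal coverage has no meaning here.

Sign convention: `d_m` and `d_p` are stored as signed logistic slopes
(negative = decay); the time of half-maximal effect is `−h/d`. Profiles
with non-negative slopes trigger a warning, not an error, so users can
explore non-decaying curves.

### Resistance evolution and population dynamics

One biallelic haploid locus per insecticide, random mating, linkage
equilibrium, no recombination modelling, no dominance, no drift, no
migration, no fitness costs. Each mutational step multiplies mortality by
`(1 − d_q)`, so a genotype with `s` steps has phenotype
`q = (1 − d_q)^s` regardless of AI (a geometric-model assumption made in
the absence of knowledge about future resistance mechanisms).

Per generation:

1. genotype fitness `w = 1 − V·P·M_eff`, where `M_eff` combines the two
   single-AI mortalities by strategy (mixture `1−(1−M₁)(1−M₂)`, mosaic
   `(M₁+M₂)/2`, rotation = the cycle-active AI's `M`);
2. allelic fitnesses are genotype-frequency-weighted means over the other
   locus; allele frequencies follow the haploid replicator recursion
   `f' = f w_R / (f w_R + (1−f) w_S)`;
3. population update `N' = N ω̄ (1 + r (1 − N ω̄ / K))` with mean fitness
   `ω̄` from the pre-update frequencies — density dependence is applied
   after insecticide mortality; `N` is continuous (no rounding) to keep
   the recursion smooth and deterministic;
4. a deterministic mutation clock: once the resident resistant allele
   exceeds 0.99 frequency, post-update population sizes are accumulated;
   when the sum reaches `1/μ` individuals, the next-step allele replaces
   it at frequency `1/N` (the displaced allele becomes the new
   susceptible allele at `(N−1)/N`) and the clock resets. No introduction
   occurs at `N ≤ 1`. The 0.99 threshold encodes the assumption that
   selective interference would purge a new mutation arising during an
   ongoing sweep.

Initial state: `N = K`; at each locus the rare allele (frequency
`f_init`) carries `max(1, initial_steps)` steps and the resident allele
one step fewer. For pyrethroid-like AIs with `initial_steps = 3` this
puts two steps of widespread background resistance in the resident allele
and the third step in the rare allele; fresh modes of action start from a
susceptible resident and a rare one-step allele.

### Scenarios, grid and optima

A scenario runs 12 years at 12 generations per year by default. Nets are
replaced every `lifespan` years (net age = absolute time mod lifespan);
decay curves are evaluated at each generation's start age. Coverage is
constant within a run. Rotations deploy AI 1 in even-numbered cycles.
Solo usage forces the partner loading to zero; inside a mosaic or
rotation this structurally leaves half the coverage (or alternate
cycles) with untreated nets that keep their physical barrier but kill
nothing.

`run_grid` sweeps loadings `{0, Δc, …, c_max}` (both AIs) × lifespans
`{Δl, …, l_max}` for each usage variant, using a vectorised engine that
advances all designs simultaneously; it is verified against the scalar
generation-by-generation runner. Reported per design: average control
`mean(1 − N/K)`, price, coverage, cone-test bioefficacy at 3 years of
net age against the start-of-simulation and end-of-simulation
population-mean phenotypes (the cone test forces exposure, so neither
barrier nor coverage enters), their ratio (end/start, a resistance
readout), and the population-mean resistance steps reached.

Optimality criteria (exhaustive filter-and-sort, never gradient-based):
**BL** both AIs at loading 1.0, 3-year lifespan; **MC** unconstrained
argmax of average control; **CW** cheapest design with 3-year lifespan
and > 80% bioefficacy at 3-year net age (equal-cost ties go to higher
control, then lower loadings); **MW** maximum control under the same WHO
constraint; **UC** maximum control among universal-coverage designs.
The strict `> 0.8` and `coverage = 1` comparisons carry a 1e-9 numeric
slack. An empty feasible set is reported as an explicit no-solution row.
The bioassay for the WHO filter uses the whole net's combined mortality
(the prequalification cone test is of the finished net, not each AI
separately); a `susceptible` bioassay-reference mode mirrors the WHO
practice of testing pyrethroids against susceptible colonies.

### Decay fitting

Mortality and physical-integrity time-series (binomial counts) are fitted
by maximum-likelihood binomial logistic regression of outcome on net age
(statsmodels GLM), returning the signed slope and intercept used by the
property curves; fits are at reference loading `c = 1`, with the loading
shift applied downstream, never estimated. Chemical series are fitted by
OLS on log concentration — closed-form and exact on noiseless input.
Complete separation is flagged, not fatal. A seeded generator draws
synthetic bioassay tables from the model curves for parameter-recovery
tests.

## Parameters, units, defaults

Time in years, prices in budget currency (USD per person per standard
3-year cycle), loadings relative to each AI's solo dose.

The original application's fitted default constants are not published in
print and were unavailable here; the packaged registry
(`bednetopt/data/defaults.yaml`) is a **synthetic stand-in** chosen once
for order-of-magnitude plausibility: a cheap pyrethroid
(`k = 0.3`/unit, three steps of pre-existing resistance) versus an
expensive new AI (`k = 3.0`, one rare resistance step), net fabric at
`a = 1.5`, use rate `u = 0.88`, logistic decay constants giving ~80–95%
fresh-net kill decaying past the 80% threshold around 3 years of age.
Ecology/genetics: `r = 1.0` per generation (stable logistic regime),
`K = 10⁶`, `μ = 5·10⁻⁸` (≈20 generations at carrying capacity per new
step once a sweep completes), `d_q = 0.5` (one step halves mortality; two
background pyrethroid steps quarter it), `f_init = 10⁻³`. Generation
time is 1/12 year. Default grid: loadings to 3.0 by 0.2 (0.1 reproduces
the published search interval), lifespans 1–6 years by 1.

**What a green test establishes.** With synthetic constants, tests of
*structure* are meaningful — identities of the curves, the selection
recursion against an independent oracle, criterion ordering
(MC ≥ MW ≥ BL), budget monotonicity, and the resistance-management
benefit of mixing a new AI with a cheap partner, all of which hold in
this world. Numeric agreement with the published example figures is
*not* expected and the corresponding acceptance test documents the gap;
supplying the original constants as a config override is the intended
route to a quantitative comparison.

## Numerical choices

* Deterministic throughout; the only randomness is the seeded fixture
  generator.
* Grid values are rounded to 10 decimals to make lifespan/loading
  equality filters exact; optima tie-breaks are total (control/price,
  then lower `c1`, `c2`, lifespan), so results are invariant to row
  order.
* Degenerate inputs: zero total allelic fitness leaves the frequency
  unchanged while the population crashes to zero; a 12-year horizon not
  divisible by the lifespan simply truncates the final cycle.

## Known limitations

No malaria transmission layer (mosquito control is the terminal output);
no diploid genetics or linkage disequilibrium; no physio-chemical
interaction between co-formulated AIs (PBO is just another profile); no
net-attrition model beyond the fitted physical-decay curve; budgets and
prices are static over the horizon.
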