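# bednetopt

Optimization of long-lasting insecticidal bed nets (LLINs): how much of
each insecticide to load onto a net, and how often to replace it, when
the mosquito population both shrinks under control and evolves
resistance?

`bednetopt` is for vector-control modellers and product-design analysts.
It couples four idealised LLIN property curves (chemical decay,
mortality decay with a loading-dependent midpoint shift, physical decay,
and a linear price/coverage model) to a deterministic two-locus haploid
selection model with density-dependent logistic population dynamics, then
searches exhaustively over loading concentrations `c₁, c₂` and deployment
lifespans `l` for the designs that are optimal under five policy
criteria.

## Model core

Mortality of insecticide *i* at net age *t* against resistance phenotype
*q*:

```
Mᵢ(t) = q · σ(dᵢᵐ (t + xᵢ) + hᵢᵐ),   xᵢ = −ln(cᵢ)/dᵢᶜ
```

with `σ` the logistic function; a mixture kills with
`M₁₂ = 1 − (1−M₁)(1−M₂)`. Genotype fitness each generation is
`w = 1 − V·P·M` (coverage × intact-barrier probability × mortality),
allele frequencies follow the haploid replicator recursion
`f' = f w_R / (f w_R + (1−f) w_S)`, and population size follows
`N' = N ω̄ (1 + r(1 − N ω̄/K))`. Each resistance step multiplies
mortality by `(1 − d_q)`; new steps arrive via a deterministic mutation
clock (`1/μ` individuals after the current sweep completes). Coverage is
`V = min(1, l·b / (3·price))`: a budget `b` equal to the net price at the
standard 3-year lifespan buys universal coverage.

Criteria: **BL** (standard loadings, 3-year lifespan), **MC**
(unconstrained maximum of average control `1 − N/K` over 12 years),
**CW** (cheapest net passing the WHO >80% cone-test mortality at 3-year
net age), **MW** (maximum control within that WHO constraint), **UC**
(maximum control with universal coverage).

> The packaged default constants are clearly-labelled synthetic
> stand-ins (the original application's fitted values are unpublished);
> see `docs/methods.md`. Qualitative structure is meaningful with them,
> product-specific numbers are not.

## Worked example

```
$ bednetopt optimize --out results/
criterion  usage  feasible  c1  c2  lifespan  price  coverage  avg_control  start_bioefficacy  relative_change
       BL  joint      True 1.0 1.0       3.0   4.80  0.416667     0.079979           0.833354         0.553199
       MC  joint      True 0.6 2.2       6.0   3.96  1.000000     0.350559           0.632197         0.611956
       CW  joint      True 1.0 0.0       3.0   4.50  0.444444     0.068474           0.817166         0.500187
       MW  joint      True 1.0 0.8       3.0   4.74  0.421941     0.080264           0.829456         0.540650
       UC  joint      True 0.6 2.2       6.0   3.96  1.000000     0.350559           0.632197         0.611956
...
```

Reading the joint-usage rows for the default scenario (an expensive new
AI mixed with a cheap, partially-resisted pyrethroid, $2/person budget):
the baseline net (both AIs at standard loading, 3-year replacement) is
expensive, so it covers only 42% of people and averages 8.0% mosquito
suppression over 12 years. The unconstrained optimum **MC** instead cuts
the new AI to 0.6× loading, raises the cheap partner, and stretches
replacement to 6 years — reaching 100% coverage and 35.1% average
control. The cheapest WHO-passing net (**CW**) drops the partner
entirely (`c2 = 0`): its 3-year bioefficacy is 81.7% (> 80%, feasible)
at a price of 4.50. `relative_change` is end/start bioefficacy — 0.55
for the baseline means resistance evolution roughly halved the net's
kill rate over the simulation. A `False` in `feasible` (e.g. CW for the
solo pyrethroid) is an explicit no-solution: that net class cannot pass
the WHO threshold at any searched loading.

Other entry points: `bednetopt simulate` (one design, full trace),
`bednetopt grid` (the raw control/coverage/cost landscape),
`bednetopt batch --budgets 0.5,1,2 --pairs "new_ai_1,pyrethroid;new_ai_1,"`
(budget × partner sweeps with a combined index), and `bednetopt fit` (decay
constants from bioassay tables). All accept `--config my.yaml`, merged
over the packaged defaults. The same operations are importable:
`bednetopt.run_scenario`, `run_grid`, `find_optimum`, `fit_logistic_decay`, …

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline check from scratch — it builds the
default net design, prices it with the linear pricing model, sets the
per-person budget equal to that price and evaluates the coverage
function at the standard 3-year lifespan, writing the resulting coverage
percentage as JSON.
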