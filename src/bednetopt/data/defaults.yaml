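# Default parameter registry (SYNTHETIC stand-in values).
#
# The fitted constants used by the original application are not published
# in print and could not be obtained here; the values below are plausible
# order-of-magnitude choices for each insecticide class, fixed once and
# documented in docs/methods.md.  Results computed from them illustrate
# the model's behaviour; they are not product-specific predictions.
#
# Units: time in years, prices in budget currency units (USD per person
# per standard 3-year purchase cycle), loadings relative to each AI's
# standard solo dose.  Logistic slopes are signed (negative = decay).

insecticides:
  pyrethroid:
    d_c: 0.67      # chemical decay rate, per year
    d_m: -1.2      # mortality-logistic slope, per year
    h_m: 3.0       # mortality-logistic intercept
    k: 0.3         # price per relative loading unit (cheap, mature AI)
    initial_steps: 3   # widespread target-site + metabolic resistance
  new_ai_1:
    d_c: 0.40
    d_m: -1.0
    h_m: 4.5
    k: 3.0         # an order of magnitude dearer than a pyrethroid
    initial_steps: 1
  new_ai_2:        # hypothetical: same properties, different mode of action
    d_c: 0.40
    d_m: -1.0
    h_m: 4.5
    k: 3.0
    initial_steps: 1
  chlorfenapyr:
    d_c: 0.50
    d_m: -1.1
    h_m: 3.5
    k: 1.5
    initial_steps: 1
  pyriproxyfen:
    d_c: 0.45
    d_m: -0.9
    h_m: 3.0
    k: 1.2
    initial_steps: 1
  pbo:
    d_c: 1.0
    d_m: -1.5
    h_m: 2.0
    k: 0.8
    initial_steps: 1
  none:            # placeholder partner for solo deployments: free, inert
    d_c: 1.0
    d_m: -1.0
    h_m: -30.0     # logistic pinned to ~0: kills nothing at any age
    k: 0.0
    initial_steps: 1

physical:
  u: 0.88          # proportional use rate at receipt
  d_p: -0.7        # physical-decay logistic slope, per year
  h_p: 2.5         # physical-decay logistic intercept
  a: 1.5           # base fabric price

economics:
  budget: 2.0      # USD per person per standard 3-year cycle
  reference_lifespan: 3.0

evolution:
  r: 1.0           # intrinsic growth rate per generation
  K: 1.0e+6        # carrying capacity
  mu: 5.0e-8       # nominal mutation rate (1/mu individuals per new step)
  d_q: 0.5         # proportional mortality reduction per resistance step
  f_init: 1.0e-3   # starting frequency of the rare resistant allele

scenario:
  duration: 12.0           # years
  generations_per_year: 12 # roughly monthly mosquito generations
  strategy: mixture
  insecticide_1: new_ai_1
  insecticide_2: pyrethroid
  bioassay_reference: initial_population

grid:
  loading_max: 3.0
  loading_interval: 0.2    # paper mode: 0.1
  lifespan_max: 6.0
  lifespan_interval: 1.0
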