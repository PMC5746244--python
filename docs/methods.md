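# Methods

## Scope and model

`cpbsim` estimates (1) the uncertainty distribution of QALYs saved per 10^3
preventive-health interventions via Monte Carlo propagation through a
birth-cohort clinically-preventable-burden (CPB) chain, and (2) the annual
health (QALYs/year) and economic (dollars/year) impact of a clinic service
menu via exact moment propagation. The two layers share one currency —
QALYs per 10^3 interventions — so simulated and literature-derived rates
plug into the same impact accounting.

### The CPB chain

A birth cohort (default 4,000,000 persons) is partitioned into age strata,
each with its own person-years at risk and current intervention coverage.
Within a stratum, each event channel (mortality, hospitalization, illness)
follows:

1. attributable events = incidence (per 100,000 person-years) / 10^5 ×
   person-years;
2. counterfactual burden = current / (1 − coverage × efficacy). This is the
   standard multiplicative back-calculation: the observed burden is what
   remains after the currently covered fraction has had its preventable
   share removed. It requires coverage × efficacy < 1 and always yields
   counterfactual ≥ current, with equality exactly when coverage or
   efficacy is zero;
3. effectiveness = adherence × efficacy — offering the intervention to the
   whole cohort only protects those who accept it;
4. prevented events = counterfactual × effectiveness;
5. QALYs = Σ prevented × weight. A prevented death counts a full 1 QALY;
   morbidity channels use a health-utility decrement in [0, 1].

Strata are computed independently and summed; there is no transmission
modelling (no herd-immunity credit for vaccinating adults) and no
discounting of future QALYs.

**Intervention denominator.** The per-10^3 scaling divides by delivered
interventions, Σ person-years × adherence, on the view that an
"intervention" is a service actually delivered. `CohortSpec.denominator`
also accepts `offered` (person-years regardless of uptake) and `cohort`
(birth-cohort size) for users who define the unit differently. With the
`delivered` denominator, adherence cancels from the rate (it scales both
QALYs and interventions), which the tests treat as the flat case of the
monotonicity property. Zero adherence delivers no interventions and saves
no QALYs; the rate is defined as 0 there rather than 0/0.

### Monte Carlo layer

Each parameter carries a literature `[min, max]` range, interpreted as a
uniform distribution — ranges are typically the only distributional
information the source literature provides. One iteration draws every
parameter independently and evaluates the chain; the default run is 10^6
iterations (estimates stabilise from ~10^4; the extra draws sharpen the
quantile-interval tails at negligible cost since sampling is vectorised,
under two seconds per 10^6 iterations of the influenza model on one core).
Summaries are the mean, the sample SD (n−1 denominator, fixed so results
are bit-reproducible), and the empirical quantile interval at levels
(0.025, 0.975) using numpy's linear-interpolation quantile rule — the rule
is stated because different conventions shift the interval by fractions of
a draw spacing.

The distributional-sensitivity mode replaces U(a, b) with
N((a+b)/2, (b−a)²/12), i.e. a normal matched to the uniform's first two
moments. Normal draws can leave the physical domain, so they are clamped —
probabilities and QALY weights to [0, 1], rates and counts to ≥ 0. Clamping
(rather than rejection resampling) keeps the draw count and random stream
aligned between modes and is seed-stable; with the shipped ranges the
clamped mass is far below 1% per parameter, so the induced moment bias is
negligible next to Monte Carlo error. Reproducibility contract: a
`SimulationConfig` (iterations, seed, distribution) yields a bit-identical
sample; parameters are drawn in the order the ranges are listed.

### Literature-only rates

Interventions whose published CPB estimates lack simulable detail carry
sd = mean/3. The 1/3 coefficient of variation sits inside the 15–40% CV
band the simulated interventions span, toward its conservative end. The
shipped rate table stores both the published rounded SDs (two significant
figures) and supports the exact mean/3 (`sd="derived"`); reproducing
published downstream tables requires the printed values, so those are the
default.

### Clinic impact

Annual QALYs for a service = rate × volume / 1000 with rate and volume
independent; volume fluctuates year-to-year with sd = volume_cv × volume
(default 20%, interpreted directly as a standard deviation). The product
variance uses the exact formula for independent factors,
μx²σy² + μy²σx² + σx²σy², including the cross term — it is
distribution-free given the first two moments, which is why a normal-based
Monte Carlo oracle reproduces it in the tests.

Dollar rows multiply by a constant $132,200 per QALY (a 2017
inflation-adjusted conservative willingness-to-pay value; no CPI machinery
is included — the constant is configurable). The default `row` mode scales
both the mean and SD by the cost mean; this is what published clinic
tables reflect. A `with_cost_variance` mode additionally treats cost per
QALY as a third independent factor with a 20% CV, which widens dollar SDs
by ~10–15%; both modes are exposed because the accounting convention
differs between sources. Totals sum means and, by independence, variances.
ROI = total dollars saved / operating budget. The uninsured-exam side
calculation (patients × uninsured fraction × $230 exam cost) is a separate
un-propagated line item.

## Synthetic data

Product-chain fixtures multiply n independent uniforms, giving closed-form
output moments (E[U] = midpoint, E[U²] = (a² + ab + b²)/3); they validate
the sampling/summary machinery to within Monte Carlo standard error and
are what the generated-fixture CLI (`cpbsim make-fixtures`) writes, with
oracle sidecars. They exercise code paths, not epidemiology: real CPB
chains are non-multiplicative (the counterfactual step is a ratio) and
their inputs are bounded rates, so product-chain agreement validates the
Monte Carlo plumbing, not any disease model.

The influenza-like model is the realistic-shape fixture: two strata
(50–64, 65+) × three channels. Published ranges cover the senior mortality
rate (9.4–15.6 per 100k), mortality efficacy (0.35–0.55), illness efficacy
(0.10–0.30), senior coverage (0.43–0.72), adherence (0.75–0.95) and the
sickness QALY weight (0.20–0.40). Everything else is a **placeholder**
flagged in the parameter units and `PLACEHOLDER_PARAMETERS`: 50–64
mortality 1–3 per 100k (influenza mortality is an order of magnitude below
the senior rate), senior/50–64 hospitalization 90–210 / 20–60 per 100k,
illness 2,000–8,000 per 100k (a 2–8% annual attack rate), 50–64 coverage
0.30–0.50, hospitalization efficacy 0.25–0.45, illness QALY weight
0.02–0.10 (roughly one to five weeks of substantially reduced quality of
life per case — deliberately far below the hospitalization weight, since
applying 0.2–0.4 to millions of mild illnesses would dominate the total
implausibly). These were chosen once for epidemiological plausibility;
absolute outputs of this model are therefore illustrative, and tests assert
its structural behaviour (midpoint chain identities, monotonicity,
convergence, distribution sensitivity), not a published rate. The 50–64
person-years (60,000,000) follow from the 4M cohort crossing a 15-year
band; the senior figure (50,000,000) is the literature's round number.

## Numerical and design choices

- All chain operations accept scalars or numpy arrays; the Monte Carlo
  driver evaluates the whole batch at once. Domain violations (negative
  rates, coverage × efficacy ≥ 1, missing parameters) are reported by name
  before or during evaluation rather than per-iteration.
- Degenerate (point-mass) ranges are legal and encode constants; a
  constant sample summarises to sd 0 (up to float summation roundoff) and
  a width-zero quantile interval, and the KDE export refuses constant
  samples (a density estimate is undefined; use a histogram).
- KDE export uses scipy's Gaussian KDE with Scott's-rule bandwidth
  (configurable), on an even grid padded by three bandwidths so the curve
  integrates to ~1; curve data only, no figure rendering.
- Rendering follows the published house style — two significant figures
  with trailing zeros kept, dollar columns as integers from 10k up — and
  rounding is strictly a rendering concern; stored values keep full
  precision.
- Config files (parameter sets, cohort models, service menus, rate tables)
  are small YAML documents; read/write round-trips are lossless and
  validated on read.

## Known limitations

- The influenza-like model's absolute output depends on placeholder
  ranges; only users supplying a complete published parameter set should
  quote its rate.
- Independence is assumed everywhere variance is propagated (rate, volume,
  cost; services in a total). Correlated service volumes would widen total
  SDs.
- The CV = 1/3 rule is a stated convention, not an estimate; literature
  rows carry no quantile intervals.
- No transmission effects, no QALY discounting, no referral-attribution
  split, and no inflation adjustment beyond the fixed cost constant.
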