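# Methods

## Model class and assumptions

`metsburden` is a prevalence-based (snapshot-year) cost-of-illness model of
the hypertensive population aged 20+ from a health-service perspective. It
is deliberately static: one year's stock of prevalent hypertensives is split
into risk groups, one year's events and diabetes cases are attributed to the
groups, and one year's costs are aggregated. There is no event history, no
within-year competing mortality, and the cardiovascular event rates are
first-event rates on a population initially free of cardiovascular disease;
costs of established CVD survivors, indirect/productivity costs and
quality-of-life outcomes are out of scope by design.

The diagnostic definition is the ATP III three-of-five rule with the blood
pressure criterion at 140/90 mm Hg (the epidemiological sources and current
treatment guidelines use this threshold; the unmodified 135/85 profile ships
as an alternative `Atp3Thresholds` preset). Inequality directions are pinned
by boundary tests: waist strictly >, HDL strictly <, TG/FPG/BP inclusive ≥,
and known diabetes forces the glucose component regardless of measured FPG.
Subjects on antihypertensive medication count as hypertensive even when
measured BP is controlled below 140/90 — the model covers the treated
population, and the alternative (dropping controlled patients) would shrink
the denominator in a way no data source here supports. Non-hypertensive
subjects are refused by `assign_risk_category` rather than silently dropped,
so upstream filtering errors surface immediately.

## Conditional structure and its calibration

The key structural object is, per age/sex stratum, the distribution of the
four non-BP components conditional on hypertension — 16 subset
probabilities. It is estimated as weighted relative frequencies among
hypertensive survey records and transferred to a country by iterative
proportional fitting (IPF) of the 16-cell table to the country's four
single-component marginal prevalences among hypertensives.

IPF was chosen over alternatives (re-sampling, log-linear refits) because it
is the minimal-change transfer: the fitted table is the I-projection of the
reference onto the target margins, preserving all interaction (odds-ratio)
structure, which is exactly what "apply the survey's conditional structure
to country prevalences" should mean. Numerical choices: cells with zero
reference mass are lifted to 1e-9 before fitting so all margins stay
reachable; targets are clipped to [1e-9, 1−1e-9]; convergence tolerance
1e-8 on the worst marginal discrepancy with a 10,000-sweep cap, the
discrepancy history is logged and is non-increasing. The country's
hypertension prevalence itself is taken from the parameter pack per stratum;
the matrix only distributes the other four components, mirroring the
conditioning on hypertension. Strata are matched band-for-band between the
reference and the pack; no re-weighting of the reference to the target
country's age structure is applied (with matched bands it would have no
effect on the stratum-wise transfer).

Decomposition is exact: group k receives the stratum's hypertensive count
times the total probability of the size-k subsets, so persons are conserved
to floating-point accuracy (tested at 1e-9 relative).

## Synthetic microdata generator

The generator stands in for the survey microdata the conditional structure
is estimated from. Each stratum draws a latent 5-vector from N(0, R) with a
user-supplied correlation matrix R (unit diagonal, PSD-checked before
sampling) and thresholds it at the Gaussian quantiles of the stratum's
component marginals — a Gaussian copula over five binary indicators. One
matrix thus spans independence through strong risk-factor clustering, which
is the feature of real cardiometabolic survey data that matters for this
pipeline. The default spec uses age-graded prevalences (hypertension rising
steeply with age, metabolic components gently), latent correlations of
0.25–0.40 among the metabolic components and 0.10–0.25 with hypertension,
and log-normal survey weights (σ = 0.5, mean-normalised); default seed
20080101, logged by every CLI run. Sub-band ages are drawn uniformly; the
open 80+ band is capped at 89.

What the generator does **not** emulate: raw continuous measurements (flags
are drawn directly), survey design effects (clusters/PSUs — weights are
i.i.d.), item non-response, and any non-Gaussian tail dependence between
components. Passing tests therefore demonstrate that the estimation and
calibration machinery is correct and stable under realistic marginals and
dependence, not that any specific national survey is reproduced.

## Rates, attribution and costs

Group rates are anchored to sourced overall rates per 1,000 hypertensives
via relative risks rr_k (rr₀ = 1, enforced non-decreasing in k): rate_k =
b·rr_k with b chosen so the population-weighted mean equals the overall rate
exactly. This keeps national totals consistent with their sources while
expressing the risk gradient. "Death" appears both among CV events and as
attributable mortality; they are separate configurable outcomes, and death
carries no downstream management cost, so costs are never double counted.
Treated and untreated patients carry the same event rates; treatment affects
costs and new-onset diabetes only.

Drug and physician costs are distributed evenly across the five risk groups
per treated patient (no usable data distribute antihypertensive drug mix by
risk group; this is conservative in the sense that it understates the MetS
share of drug costs). The continuation (adherence) rate scales dispensed
drug cost and treatment-dependent new-onset diabetes; it does not rescale
physician visits. A consequence worth knowing: in the base case diabetes is
costed from the prevalence pool, so a ±20 % continuation scenario moves
exactly the same euros as a ±20 % drug-unit-cost scenario; they separate
only under the incident-only diabetes toggle, where new-onset cases enter
the costed pool. All internal math is unrounded; reports round € to the
nearest million and percentages to integers (half away from zero) at
serialisation only, and the JSON summary keeps the unrounded values.

## Projection, discounting, sensitivity

Projection factorises the two drivers: component (and hypertension)
prevalences grow by per-component CAGRs, p(t) = min(1, p₀(1+g)^t), and
demographic change enters only through horizon-year stratum populations —
each driver is independently testable. The horizon matrix is re-calibrated
by IPF to the projected marginals; prices stay at base-year level.
Discounting uses the single-snapshot convention — the horizon-year annual
cost divided by (1+r)^(horizon−base) — which is the only convention
consistent with all three published discounted 2020 totals.

Sensitivity analysis is strictly univariate: each scenario deep-copies the
parameter pack and changes exactly one factor (verified bit-identical
otherwise), and the report orders scenarios by the absolute spread of the
presence totals (tornado ordering). The incident-only scenario needs an
incident diabetes rate the base case does not use, so packs carry both
prevalence and incidence, with validation requiring incidence ≤ prevalence.

## Parameter packs and the demo defaults

Packs are plain CSV/JSON directories validated up front with *all*
violations reported at once (shares summing to 1, rr₀ = 1, monotone rr,
incidence ≤ prevalence, non-negative costs, EUR currency, matched strata).
The shipped `demo_pack` styles ("DE", "ES", "IT") are **illustrative, not
sourced national data**: a high-clustering style (obesity 62 % among
hypertensives at the anchor band, treated share 0.74) and two
lower-prevalence styles (obesity 40–44 %, other components 15–21 %). The
default relative-risk gradients — (1, 1.45, 2.1, 2.9, 3.8) for events and
mortality, (1, 3, 9, 16, 24) for diabetes — were set so the shipped packs
express the headline gradients of this literature: roughly two-fold MetS vs
non-MetS event and mortality rates and roughly six-fold diabetes prevalence,
with per-patient cost rising monotonically in k. Demo CAGRs (obesity
1.8–3.0 %/yr, IFG 2.4–4.5 %/yr, hypertension 0.4–0.8 %/yr) and an ageing
population-multiplier profile per band play the same illustrative role.

## Problem sizes and determinism

Default runs estimate the reference from 50,000 synthetic records (the
library-level closed-loop recovery checks use 100,000, where every 16-cell
probability lands within 3 binomial SEs of its Gaussian-orthant value);
these sizes give sampling noise well below the effects of interest while
keeping a full three-country run in seconds. Every run is deterministic
given config + seed: repeated runs write byte-identical reports, and the
provenance block records the config hash, seed, package version and IPF
iteration counts.

## Known limitations

Static one-year attribution (no multi-year cost streams between base and
horizon years); no probabilistic sensitivity analysis (the engine is
univariate by construction); no IDF or BMI-surrogate diagnostic criteria; no
policy-scenario modelling of prevention programmes; illustrative rather than
sourced parameter packs, so absolute country figures from the demo packs are
demonstrations of the machinery, not national estimates.
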