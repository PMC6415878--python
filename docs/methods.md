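# Methods

`besurv` is a decision-analytic model of endoscopic surveillance for
Barrett's esophagus (BE) in NHS England, comparing two strategies over a
7-year horizon:

* **NBI arm** — narrow-band-imaging-guided targeted biopsy, adopted across
  the market share of NBI-capable installations (84%); the remaining 16% of
  procedures continue with HD-WLE.
* **HD-WLE arm** — high-definition white-light endoscopy with the Seattle
  protocol (random four-quadrant biopsies every 2 cm plus targeted
  biopsies) in 100% of procedures.

The model combines a decision tree for the diagnostic phase with a 6-month
cycle Markov model for disease progression, and produces cost-consequence,
budget-impact, cost-effectiveness (ICER), and deterministic one-way
sensitivity analyses. All money is GBP 2017; costs after year 1 are
discounted at 3.5%/year; clinical event counts are reported undiscounted.

## Cohort projection

The year-1 population attending endoscopy (161,657 nationally; 649 per
hospital under the hospital perspective) grows at 20%/year. The engine
carries the exact geometric sequence `n1·(1+g)^(t−1)` and rounds half-up
only at report time; this reproduces both the printed yearly populations
(161,657 → 482,705) and the printed 7-year total (2,087,946), which
sequential per-year integer rounding misses by one. A `rounding="yearly"`
mode implementing the sequential convention is provided and property-tested
against the geometric closed form.

Discount factors are `(1+r)^−(t−1)`: year 1 undiscounted. Note the
published discounted money totals imply a patient weighting ≈0.4% below
this convention (the exact mid-year/rounding convention is not stated);
we keep the standard convention and the residual shows up as a ≈0.5%
difference in the grand totals.

## Diagnostic phase (decision tree)

True disease states {ND, LG, HG, EAC} follow the observed cohort counts
(1791/751/106/48 of 2,696); the integer counts are carried rather than the
rounded percentages because downstream outputs (e.g. the 77,331
eradications) are only reproduced by the exact fractions. The index test is
binary (dysplastic vs not): dysplastic patients are detected with
sensitivity Se, ND patients cleared with specificity Sp; false positives
are labelled LG (they enter 6-month surveillance, but are never resected);
grade assignment among detected dysplastics is taken as correct, since only
binary Se/Sp are available. In the base case both arms use the per-patient
meta-analytic accuracy (Se 94.2% / Sp 94.4%); per-lesion scenarios use
technique-specific accuracy (NBI 89.0%/80.0%, HD-WLE 79.1%/81.0%), blended
by market share within the NBI arm like every other technique-dependent
input. An optional histopathology confirmation layer (Se 100% / Sp 62.9%)
re-tests endoscopy positives; it is off by default because the base-case
outputs are reproduced without it.

Detected HG patients receive EMR+RFA (eradication rate 94.9%); detected
EAC patients receive cancer treatment at the same tariff. The reported
"successful eradications" follow the published convention (detected HG);
the stricter count (×0.949) drives the Markov reset.

Endoscopy adverse events (strictures 0.01%, perforations 1.4%/3.0%,
bleedings 0.2%/0.5%) scale by default with the procedure count
(`ae_exposure_basis="per_procedure"`; `per_biopsy` and `per_treated` are
available because the published AE counts are not reproducible from any
single basis — the implied exposure differs by AE type). NBI-arm rates are
market-share blended. Treatment AEs (33.5%/1.3%/7.5%) scale with treated
patients in both arms.

All cohort quantities are expected values (fractional); rounding happens
only in the report layer.

## Long-term phase (Markov model)

Six-month transition matrix over (ND, LG, HG, EAC), forward-only, EAC
absorbing:

|      | ND    | LG     | HG     | EAC    |
|------|-------|--------|--------|--------|
| ND   | 0.95  | 0.05   | 0      | 0      |
| LG   | 0     | 0.9318 | 0.0682 | 0      |
| HG   | 0     | 0      | 0.9048 | 0.0952 |
| EAC  | 0     | 0      | 0      | 1      |

No half-cycle correction is applied (none is stated for the source model);
cycle `c` maps to calendar year `⌈c/2⌉` for discounting. Surveillance
intervals: believed-ND 36 months, diagnosed LG / post-treatment HG / EAC 6
months. The engine tracks four diagnosis pools, each a 4-vector of true
state mass (believed-ND, diagnosed-LG, diagnosed-HG, diagnosed-EAC). At an
attended visit, true-state mass beyond the pool's diagnosis is re-detected
with the arm's index sensitivity; between visits no detection occurs.
Newly found HG is treated (successes reset to ND under the 36-month
interval, failures stay diagnosed-HG); newly found EAC moves to cancer
management, which accrues £7,647/2 per 6-month cycle per prevalent
*diagnosed* EAC patient (undiagnosed cancer generates no management cost).
Mortality, regression and post-eradication recurrence are not modelled (the
matrix has no backward transitions).

In long-term scenarios every annual entry cohort is followed from its entry
year to the end of the 7-year horizon (the year-t cohort gets 14−2(t−1)
cycles); surveillance endoscopies, follow-up treatments and cancer
management are added on top of the diagnostic pipeline. Incident EAC is the
cumulative first entry into the EAC state. Because the published scenario
report does not state its surveillance bookkeeping, the long-term outputs
are validated by direction (fewer incident cancers under higher
sensitivity) and by the microsimulation oracle, not against the printed
magnitudes. The avoided-cancer count for the year-1 cohort alone is also
exposed, since that is the published framing.

Per-lesion scenarios count detected lesions as `λ` lesions per dysplastic
patient times the arm's per-lesion sensitivity; the lesion multiplicity `λ`
is a parameter (default 1) because no multiplicity is published.

## Costing

**NHS perspective** — payer outlays: the endoscopy tariff (£517) per
procedure, the EMR+RFA tariff (£2,101) per treated patient, histopathology
(£82 × biopsies: 7.6/procedure HD-WLE, 3.6 NBI, 4.24 blended), AE
management (£392 stricture/bleeding, £2,852 perforation), and capital
equipment. Staff and consumable micro-costs are excluded (covered under
tariff).

**Hospital perspective** — procedures are micro-costed: staff time × hourly
rates (£186.99/endoscopy HD-WLE; £167.72 NBI, the nurse non-contact time
scaling with biopsies 0.89 h × 3.6/7.6 = 0.42 h) plus consumables (one
forceps unit £21 per endoscopy, one snare unit £12 per treatment; treatment
staff time is taken equal to the arm's endoscopy profile, the only
published profile), plus maintenance; tariffs are booked as income and the
margin (income − cost) is reported.

**Capital equipment** — the adopting arm buys NBI systems for the
non-capable share of Olympus rooms (249 × 0.84 × 0.17 × 3.25 ≈ 115.6
systems at £41,316), HD scopes for the non-HD share of Olympus-room scopes
(× (1−0.40) at £30,487), and trains half its endoscopists (2 days at
£1,136/day). Purchases are amortized as equal annual charges over 7 years,
then discounted (the order is commutative). Both arms accrue annual scope
replacement (2.9%/year of the installed base; the adopting arm applies it
only to its non-upgraded, non-Olympus share). Maintenance (arm-specific
rates) accrues in the hospital perspective only. The published capital
totals exceed what these stated formulas yield; the package reports its
formula-based totals (the increment remains positive, which is the decision-
relevant property).

## Analyses

* **Cost-consequence** — per-category discounted costs and undiscounted
  event counts per arm, with absolute and relative differences.
* **Budget impact** — per-year totals; the Total row equals the
  cost-consequence grand totals exactly (additivity is asserted).
* **ICER** — Δcost/Δeffect with dominance labels; equal-accuracy
  comparisons yield "cost-saving-equal-effect" rather than a finite ratio.
  Ratios are displayed in £K to three significant figures.
* **Scenario grid** — six scenarios: {per-patient, per-lesion} × {NHS,
  hospital} × {±long-term}, the hospital perspective having no long-term
  variants.
* **OWSA** — ±10% relative bounds on demographics, accuracy, AE rates and
  unit costs; 2.0%–5.0% for the discount rate; probabilities clipped to
  [0,1] with a warning. The accuracy confidence-interval bounds used in the
  published tornado are not printed anywhere, so accuracy items fall back
  to ±10% with a warning unless explicit CI bounds are supplied. Items are
  ranked by outcome range; the ranking is invariant to input order
  (stable sort, ties broken by parameter name).
* **Equal-AE analysis** — NBI endoscopy AE rates set equal to HD-WLE and
  the pipeline re-run; under the per-procedure exposure basis the result
  equals the base difference minus the AE-category difference exactly,
  which is asserted as an identity on arbitrary parameter sets.

## Microsimulation oracle

`besurv.microsim` draws individual patients with exactly the cohort
model's probabilistic structure: state ~ the entry distribution, technique
~ Bernoulli(market share), detection ~ Bernoulli(Se or 1−Sp), biopsies by
technique, AEs ~ Bernoulli(rates), eradication ~ Bernoulli(0.949), and in
long-term mode a categorical Markov walk with the same pool/visit/
re-detection rules. `validate_against_cohort` flags any cohort expectation
outside the microsim mean ± 3 SE; zero-variance statistics must match
exactly. Draws are fully vectorized from a single seeded numpy Generator —
reproducible given (n, seed); there is no parallel execution path, so
per-patient substreams were not needed. The test suite and the acceptance
script validate at n = 10⁵ (runs in well under a second), with convergence
checked across n ∈ {10³, 10⁴, 10⁵}.

The simulator emulates the model's own stochastic reading, not real
patients: no age structure, BE segment length, operator variability,
mortality, or inter-pathologist variation. Agreement therefore verifies the
expected-value arithmetic of the cohort engine, not external validity.

## Numerical choices and degenerate inputs

* Half-up rounding at report time (`round_half_up`), matching the printed
  tables; never banker's rounding.
* Probability-mass conservation asserted to 1e-10 per cycle; stochastic
  matrix rows validated to 1e-12.
* Zero-cost, zero-rate, zero-growth, single-year and perfect-test inputs
  are all defined and tested (no division-by-zero paths; empty AE profiles
  cost zero).
* Parameter overrides are atomic and re-validated; probabilities out of
  [0,1], inconsistent disease counts, or a targeted-biopsy count above the
  Seattle-protocol count are rejected with messages naming the invariant.

## Known limitations

* The grand totals differ from the published ones by ≈0.5% (discounting
  convention) and the AE counts/costs, correctly-identified count
  (we compute TP+TN ≈ 1.970 mln vs the published 1.935 mln), capital totals
  and long-term magnitudes by more, for the convention reasons noted above.
  The reproducible quantities (populations, biopsies, eradications,
  per-patient histology costs, ICER arithmetic, equal-AE identity) are
  asserted exactly; the rest are asserted by direction, additivity and
  oracle agreement.
* One national average is used per input; no probabilistic sensitivity
  analysis (natural-unit outcomes only, no QALYs), per the source model's
  scope.
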