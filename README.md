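# besurv

Health-economic model of **narrow-band imaging (NBI) guided targeted
biopsy** versus **high-definition white-light endoscopy (HD-WLE) with the
Seattle protocol** for the surveillance of Barrett's esophagus (BE), from
the NHS England perspective.

Barrett's esophagus is a premalignant condition monitored by periodic
endoscopy. The current standard (Seattle protocol) takes random
four-quadrant biopsies every 2 cm plus targeted biopsies — on average 7.6
specimens per procedure. NBI guides targeted biopsies instead, achieving
the same per-patient dysplasia detection with 3.6 specimens. Since
histopathology is billed per biopsy (£82) and biopsy-related adverse events
scale with sampling, fewer biopsies translate into payer savings. This
package quantifies that trade-off for health-economics analysts and HTA
modellers: it implements the full decision tree + 6-month Markov cohort
model, a budget-impact projection, ICER/dominance statements, a
deterministic one-way sensitivity analysis (tornado), and an
individual-patient microsimulation used as a verification oracle for every
cohort expectation.

## Model in brief

* Cohort: 161,657 patients/year at year 1, +20%/year, 7-year horizon;
  costs discounted at 3.5% after year 1 (GBP 2017).
* Disease states {ND-BE, LG-BE, HG-BE, EAC} with entry distribution
  1791/751/106/48 out of 2,696; index test has per-patient Se = 94.2%,
  Sp = 94.4% in both arms (per-lesion scenarios: NBI 89.0%, HD-WLE 79.1%).
* The "NBI" arm is a mixed arm — 84% NBI / 16% HD-WLE by market share —
  so its biopsies per procedure are 0.84·3.6 + 0.16·7.6 = 4.24.
* Detected HG-BE receives EMR+RFA (eradication 94.9%, tariff £2,101);
  progression follows a 6-month transition matrix with absorbing EAC.
* Cost categories: endoscopy and treatment tariffs, histopathology,
  adverse events, capital equipment (NBI system/scope upgrades and
  training amortized over 7 years), and — in long-term scenarios — cancer
  management (£7,647/year per diagnosed EAC patient).

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```sh
besurv base-case --out outputs/
```

prints (£ mln for cost rows, counts for outcome rows; NBI vs HD-WLE):

```
                                 NBI      HD-WLE  absolute_difference  relative_difference_pct
category
endoscopy_staff_overheads      952.2       952.2                  0.0                      0.0
treatment_staff_overheads      208.2       208.2                  0.0                      0.0
histopathology                 640.4      1147.8               -507.5                    -44.2
adverse_events                 108.5       180.9                -72.4                    -40.0
capital_equipment               52.9        18.1                 34.8                    192.0
total_costs                   1962.2      2507.3               -545.1                    -21.7
correctly_identified       1969620.0   1969620.0                  0.0                      0.0
successful_eradications      77331.0     77331.0                  0.0                      0.0
biopsies                   8852892.0  15868392.0           -7015500.0                    -44.2
...
```

Reading it: both arms see the same 2,087,946 patients over 7 years and —
with equal per-patient accuracy — identify the same cases and eradicate the
same 77,331 HG dysplasias. The NBI arm takes 7.0 mln fewer biopsies
(−44.2%), saving £507.5 mln of histopathology and £72.4 mln of
adverse-event management, against a £34.8 mln capital increment for
upgrading systems, scopes and training: NBI is cost-saving overall at equal
effectiveness. (Costs here follow this package's stated discounting and
adverse-event conventions; see `docs/methods.md` for where published
convention detail was insufficient to reproduce a printed total.)

The same library surface is available in Python:

```python
import besurv

params = besurv.default_parameters()
cc = besurv.cost_consequence(params)
print(cc.table())                               # full precision
print(besurv.budget_impact(params))             # per-year costs + total row
print(besurv.run_scenario(4, params).summary()) # per-lesion, long-term: ICER
```

Other subcommands: `budget-impact`, `scenario --id 1..6`, `owsa`
(tornado-ranked sensitivity analysis and the equal-AE analysis),
`microsim --n N --seed S` (patient-level records as CSV), and
`validate --seed S` (checks every cohort expectation against the
microsimulation at 3 standard errors). All commands accept
`--config file.yaml` to override any input (the bundled
`src/besurv/data/defaults.yaml` documents every field) and write their
tables plus a `manifest.json` into `--out`.

### CSV column conventions

* cost-consequence: `category` × {`NBI`, `HD-WLE`, `absolute_difference`,
  `relative_difference_pct`}; a parallel `*_raw.csv` keeps full precision.
* budget impact: `year` (plus a `total` row) × {`population`, `NBI_mln`,
  `HD-WLE_mln`, `difference_mln`}.
* owsa: `parameter`, `low`, `high`, `outcome_low`, `outcome_high`,
  `base_outcome`, `range` (tornado order).

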