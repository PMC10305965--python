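# Methods

## The analysis

`eyecea` implements a retrospective micro-costing and cost-effectiveness
pipeline for eye-care case-finding strategies. The unit of analysis is a
strategy operated by one or more providers over one financial year. The
chain is:

1. **Ingestion and standardization.** Provider cost items arrive as flat
   rows (strategy, provider, free-text category, amount, capital flag,
   useful life, earmark tag). Free-text categories are mapped onto a closed
   set of standard categories; the four reporting categories are planning &
   preparation, clinical equipment & consumables, human resources, and other
   operating expenses. Relabelling never splits or merges lines, so total
   cost is conserved exactly.
2. **Currency and time.** Amounts recorded in INR are converted at 70.42 INR
   per 2020 USD. Capital outlays are converted to equivalent annual costs
   with the annuity formula `EAC = K·r / (1 − (1+r)^−L)` at discount rate
   `r = 3%/yr` over useful life `L`; the `r → 0` limit is straight-line
   `K/L`. The annuity form is the standard treatment in costing studies; the
   discounted EAC stream repays the outlay exactly, which the tests verify
   against an independent root-finding oracle.
3. **Pooling and normalization.** Provider datasets are pooled within
   strategy (cost lines concatenated, counts summed); point estimates are
   computed from pooled data. Costs are reported per 100,000 people screened
   for mobile/outreach strategies and per facility for vision centers and
   teleophthalmology.
4. **Apportionment and CFTI costs.** Pooled costs are split across URE,
   cataract, and other conditions proportionally to each strategy's
   diagnosis counts, except earmarked lines, which go wholly to their tag:
   vision-center follow-up for refractive error → URE; subsidized patient
   travel for cataract surgery → cataract; fundus-type equipment → other.
   The URE share divided by spectacles dispensed, and the cataract share by
   surgeries performed, give the case-finding-and-treatment-initiation
   (CFTI) cost per case. Division by a zero treatment count yields a
   flagged-undefined value, not an error (school screening performs no
   cataract surgery). The apportionment rule is a pluggable policy;
   proportional-to-diagnoses is the default.
5. **Effectiveness.** Each spectacle averts `f_URE` DALYs and each surgery
   `f_cataract`. By default these are discounted lifetime totals of 0.02 and
   0.85 DALYs per case: reconstructing strategy-level DALY totals from
   treatment counts under this reading reproduces the reference totals to
   within printed rounding, which the totals-vs-annual-weight ambiguity
   cannot otherwise survive. An `annual_weight_annuity` mode instead treats
   the factors as annual disability weights scaled by the discounted annuity
   over the benefit duration (3 years for spectacles — the useful life of a
   pair of glasses; 19.9 years for surgery — the average remaining life
   expectancy of cataract patients in India), for transparency and
   sensitivity analyses.
6. **Frontier.** Societal cost = CFTI cost + treatment costs (spectacles,
   surgeries) + patient access costs, compared against a no-intervention
   baseline at (0, 0). Strictly dominated strategies (another costs no more
   and averts at least as many DALYs) are removed, then extended-dominated
   strategies (whose removal restores strictly increasing ICERs) are removed
   iteratively; ICERs are incremental between adjacent survivors. Exact
   cost-and-effect ties break lexicographically with a warning.
7. **Uncertainty.** PSA draws each cost category independently from a gamma
   distribution (strictly positive, right-skewed — the standard choice for
   costs) with mean equal to the point estimate and a configurable
   coefficient of variation (default 0.25; lognormal and uniform-percent
   alternatives available). Earmarked amounts scale with their category
   draw. Each draw re-runs apportionment, CFTI division, DALY totals, and
   societal-cost assembly. Confidence intervals are empirical 2.5/97.5
   percentiles (linear interpolation). CEACs report, at each DALY valuation
   λ, the fraction of draws in which each strategy attains the maximal net
   monetary benefit λ·DALYs − cost; exact ties split the mass equally so
   probabilities sum to one at every λ. An optional provider-level shared
   multiplicative shock induces positive correlation across categories;
   outcome counts can optionally be redrawn binomially from diagnosis
   counts (`vary_outcomes`), with draws that annihilate a treatment count
   flagged and excluded from per-case CIs (the exclusion count is reported).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `exchange_rate` | 70.42 | INR per USD | 2020 market rate of the costing year |
| `discount_rate` | 0.03 | 1/yr | standard health-economic discounting, applied to both capital annualization and DALY streams |
| `daly.per_case_ure` | 0.02 | DALYs/case | lifetime total per pair of spectacles |
| `daly.per_case_cataract` | 0.85 | DALYs/case | lifetime total per surgery |
| `daly.duration_ure` | 3 | yr | useful life of spectacles (annuity mode) |
| `daly.duration_cataract` | 19.9 | yr | life expectancy of cataract patients (annuity mode) |
| `psa.n_sims` | 10,000 | draws | Monte Carlo resolution for CIs/CEACs |
| `psa.dispersion` | 0.25 | CV | chosen so simulated CI widths are of the order of the pooled-table CI widths; fully configurable per category |
| `unit_costs.*` | 3.5 / 70 / 20 | USD | spectacle, surgery, patient-access components of societal cost; placeholders for values a user must supply — frontier reproduction uses published totals and does not depend on them |
| `lambda_grid` | 0–2,500 step 25 | USD/DALY | CEAC evaluation range |
| vision-center capital life | 10 | yr | set-up costs amortized over roughly a decade; configurable |

## Synthetic data generator

The generator emulates six providers running the four screened strategies:
Poisson screening volumes per provider; diagnoses drawn multinomially from
per-strategy prevalence; treatments drawn binomially from conversion
probabilities; category costs drawn gamma with mean proportional to
screening volume (CV 0.35) under a provider-level gamma multiplier (CV 0.30)
reproducing between-provider heterogeneity and right skew. Default marginals
match the pooled reference tables at one tenth the screened volume (e.g.
vision centers ≈17,574 spectacles and ≈5,409 surgeries per 100,000 screened),
so tests run in seconds while preserving the analysis's scale relationships.
Clinical-equipment lines for vision centers are emitted as 10-year capital
outlays to exercise the annualization path; earmarked fractions are emitted
as tagged lines inside their category so category totals are unaffected.

The generator reproduces the statistical *structure* the analysis assumes —
it does not model geography or remoteness, seasonal screening patterns,
provider-specific operating models, repeat visits, or demand shocks such as
a pandemic year. Passing recovery tests therefore demonstrates that the
pipeline is an unbiased map from data of the assumed structure back to its
generating parameters; it does not validate the assumed structure against
real provider records.

## Numerical choices

- Apportionment conservation is enforced bit-exactly: after the proportional
  split, a one-ulp correction walk over the three components forces
  `(ure + cataract) + other == total` in floating point.
- Per-case costs, ICERs and table cells are stored at full precision;
  rounding (whole dollars, one decimal for per-case and per-person costs,
  integer ICERs) happens only at rendering.
- Break-even treatment counts round *up* (a fraction of a patient cannot be
  treated).
- NMB ties in a CEAC draw split probability mass equally; the λ-grid must be
  strictly increasing.
- Degenerate inputs: zero diagnoses with a positive residual pool is an
  error; zero treatment counts flag per-case costs undefined; a zero point
  estimate under a multiplicative PSA distribution degenerates to constant
  zero with a warning.

## Design decisions made where the design was open

- **Which per-case DALY reading is primary.** Lifetime-total (see §5);
  annuity mode retained as an option.
- **Extended dominance as "weak dominance".** Equal-effect/higher-cost is
  treated as strict dominance; ICER inversion as extended dominance.
- **PSA distribution family.** Gamma by default; the reference analysis's
  exact distributional spec is not public, so published CIs and curve
  probabilities are bracketed qualitatively rather than matched. In
  particular, with independent per-strategy cost draws and fixed DALYs the
  most effective strategy always leads the CEAC beyond its ICER; orderings
  below that region (baseline at low λ, camps peaking in the low hundreds)
  are reproduced and tested.
- **Teleophthalmology break-even split.** The split of the per-facility
  increment between URE and cataract case finding is a free parameter
  (default 0.5); published break-even ranges are reproduced qualitatively.
- **Counterfactual self-presentation.** Two models: pure DALY scaling by
  (1−f), and DALY scaling plus crediting the self-presenting fraction's
  treatment costs to the baseline. The offset magnitude is configurable
  rather than reverse-engineered from published scenario ICERs.

## Limitations

- Societal treatment-cost unit components are not recoverable from published
  totals (underdetermined); frontier reproduction therefore consumes the
  published strategy totals directly, and absolute societal costs computed
  from the synthetic pipeline depend on user-supplied unit costs.
- Only one analysis year is modelled; no multi-year cohorts, no equity
  weighting of child outcomes, no budget-impact ceilings, no
  value-of-information analysis.
- Per-case CFTI costs for "other" eye conditions are not reported (a
  heterogeneous residual category).
- The published confidence intervals and acceptability-curve probabilities
  are not reproduction targets: they depend on an unavailable distributional
  specification. All quantities this package's tests assert are recomputed
  by the package itself.
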