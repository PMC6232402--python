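# mortlink

Composite real-world mortality endpoints, built and validated the way a
real-world-evidence (RWE) group would do it.

Oncology EHR databases miss a large share of deaths: patients move, enter
hospice, or simply stop appearing, and nothing in routine clinical workflow
forces a death date into the chart. Survival analyses run on such data
systematically overestimate overall survival. The standard remedy is a
**composite mortality variable**: a single per-patient death date amalgamated
from several imperfect sources — structured EHR fields, a commercial death
dataset (CDD1), the public Social Security Death Index (SSDI), and targeted
chart abstraction (ABS) — each step benchmarked against a gold-standard
national death index (NDI).

`mortlink` implements that whole workflow as a reusable, tested pipeline:

- **simulate** — synthetic cohorts with known ground truth: per-source
  incomplete capture, date errors (small offsets and exact ±1-year typos),
  identifier corruption, practice-level heterogeneity, right censoring at a
  study cutoff, and an NDI-like gold standard with match-quality classes;
- **link** — deterministic multi-pass record linkage on first/last name,
  birth date and state (exact → single-typo first name → day/month birth-date
  swap), with ambiguity always resolved to *unmatched*;
- **compose** — conflict resolution: if two or more sources agree on a date
  that date wins; otherwise the hierarchy SSDI > CDD1 > EHR decides;
  implausible dates (before advanced diagnosis) are removed; ABS only fills
  residual gaps for patients without recent activity;
- **benchmark** — the 2×2 contingency table against the gold standard and its
  metrics, with Wald 95% CIs, windowed date agreement, and per-practice
  sensitivity summaries;
- **survive** — Kaplan–Meier curves per dataset version versus the gold-based
  curve, quantifying survival overestimation.

## The statistics in brief

With `A, B, C, D` the true/false positives and false/true negatives of
composite-vs-gold vital status:

```
sensitivity = A/(A+C)    specificity = D/(B+D)
PPV         = A/(A+B)    NPV         = D/(C+D)
```

each with a Wald interval `p ± 1.96·√(p(1−p)/m)` on its own denominator
`m`. Date agreement(±k) is the fraction of composite death dates within
k days of the gold date, counting composite-only deaths as disagreements.
Survival uses the product-limit estimator
`S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)` with censoring at
min(last activity, cutoff).

The package also includes a **contingency-reconstruction oracle**
(`reconstruct_contingency`): given a published row's cohort size and its
rounded specificity, PPV and NPV, an integer search over all consistent 2×2
tables recovers the full table — and hence the sensitivity — from summary
statistics alone.

## Worked example

```
mortlink run-all --seed 1 --outdir out
mortlink benchmark --outdir out
```

prints, for a 10,000-patient simulated advanced-NSCLC cohort under the
calibrated default error model:

```
          version  sensitivity  specificity    ppv    npv  date_agreement_exact
         EHR_only       66.71%       97.22% 98.40% 53.20%                87.79%
        SSDI_only       31.01%       98.89% 98.63% 35.81%                95.36%
         EHR_CDD1       84.66%       96.29% 98.32% 70.96%                91.85%
    EHR_CDD1_SSDI       89.34%       95.97% 98.27% 77.81%                93.49%
EHR_CDD1_SSDI_ABS       91.09%       95.90% 98.28% 80.74%                93.48%
```

Reading the table: structured EHR data alone finds only two-thirds of the
deaths the gold standard knows about; adding the commercial source, then
SSDI, then gap-targeted abstraction raises sensitivity to 91% while
specificity moves by barely one percentage point. `out/survival_comparison.csv`
shows the survival consequence (`S_365d` is one-year survival under each
version, against the gold-based value of 0.498):

```
          version  median_months  S_365d  S_gold_365d  max_overestimate
         EHR_only         17.183   0.612        0.498             0.120
         EHR_CDD1         13.437   0.537        0.498             0.039
    EHR_CDD1_SSDI         12.780   0.520        0.498             0.022
EHR_CDD1_SSDI_ABS         12.517   0.514        0.498             0.016
```

The EHR-only dataset inflates median survival by ~5 months and one-year
survival by 12 percentage points; the final composite brings the curve to
within 1.6 points of the gold-based curve everywhere.

Every stage is also available as a library function (`simulate_all`,
`match_records`, `build_dataset_versions`, `validation_report`,
`km_estimate`, …) on pandas DataFrames, and stage-by-stage subcommands
(`mortlink simulate/link/compose/benchmark/survive`) operate on the CSV
outputs of the previous stage.

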