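# Methods

## Problem and model

A composite mortality variable assigns each patient at most one death
date, amalgamated from four sources of very different character:

- **EHR** — the structured "date of death" field; moderately complete,
  with completeness varying strongly by practice;
- **CDD1** — a commercial death dataset (credit/insurance/obituary
  sourced); good coverage and recency, linked by identifiers;
- **SSDI** — the public Social Security Death Index; accurate dates but
  declining completeness since state-sourced records were withdrawn;
- **ABS** — death dates abstracted by chart review, commissioned only
  for patients with no date elsewhere and no recent clinic activity.

Resolution is rule-based, not probabilistic. When two or more sources
assert the same date, that date is used. When dates conflict, a fixed
reliability hierarchy SSDI > CDD1 > EHR decides. Dates before the
patient's advanced-diagnosis date are treated as known errors and
removed. ABS never competes in conflict resolution; it fills residual
gaps only. Vital status is derived purely from date presence — there is
no "dead, date unknown" state, a deliberate limitation shared with the
operational variable this models.

Validation crosses composite vital status against a gold-standard death
index assumed (nearly) complete, yielding the 2×2 counts A–D and the
four diagnostic proportions, each with a Wald 95% CI on its own
denominator. Date agreement uses the composite deaths (A+B) as
denominator; a composite death absent from the gold standard is a
disagreement at every window. Windows are inclusive (|Δ| ≤ k days).
The per-practice analysis recomputes sensitivity within each practice
of at least 100 patients and summarises the distribution with type-7
quartile hinges and 1.5·IQR whiskers.

## Synthetic data generator

Real sources of this kind are proprietary, so the package ships a
generator whose defaults *are* the study conditions for all shipped
analyses.

**Cohort.** Default 10,000 patients, advanced NSCLC, advanced-diagnosis
dates uniform over 2011-01-01..2015-12-31 (other tumor types enroll
from 2013), study cutoff 2015-12-31. Time from diagnosis to death is
Weibull with shape 1 (exponential) by default; per-tumor medians are
12 months (advNSCLC), 20 (advMelanoma), 24 (mCRC), 30 (mBC) — round
values in the range registries report for these advanced/metastatic
diagnoses, chosen once to span short versus long survival. Deaths after
the cutoff leave the patient alive at cutoff. Last activity falls
shortly before death (exponential gap, mean 14 days) for decedents;
survivors are active near the cutoff except a 10% lost-to-follow-up
fraction with activity uniform over their follow-up. Identifiers are
random names, birth dates (1930–1975) and states; patients spread over
40 practices with Dirichlet(2) size weights.

**Sources.** A true death is captured with a per-source probability;
captured dates are exact with probability `date_exact_prob`, an exact
±365-day typo with `year_typo_prob`, otherwise offset by a rounded
Gaussian (`small_offset_sd_days`). Alive patients acquire spurious
records with `false_record_prob`. Identifier corruption perturbs one
field per affected record: a single-character edit in either name, a
day/month swap in the birth date, or a changed state. EHR capture is
modulated per practice by a Beta distribution with mean equal to the
EHR capture probability and concentration κ = 12, which reproduces a
quartile spread of roughly 57–75% when the mean is 66%; κ = None
disables the heterogeneity for experiments that need homogeneous
Bernoulli capture. ABS is generated only for patients with no record
in any other source and no activity within 60 days of the cutoff.

**Calibration.** The default per-source capture probabilities are
back-solved, assuming independent capture, from the cumulative
sensitivity path 66% → 84% → 89% → 91% (EHR alone, +CDD1, +SSDI,
+ABS): EHR 0.660, CDD1 0.529, SSDI 0.313, ABS 0.182 (conditional on
being in the residual gap). False-record rates (0.1–0.5%) and the gold
standard's parameters — capture 0.998, match classes 87% exact / 12%
probable / 1% unclassifiable among captured deaths, a 5% likely-false
rate among survivors — are set so the specificity of the composite
drifts by about one percentage point across versions while sitting in
the 96–98% band, matching the regime the variable operates in. Date
mixtures (EHR 89% exact, CDD1 95%, SSDI 97%, offsets 3–7 days, typo
rates ≤ 0.4%) put exact agreement near 88% for EHR alone and ±15-day
agreement near 97–98%.

**Gold standard.** Captured deaths carry exact dates and a
match-quality class; likely-false records attach fabricated dates to
truly alive patients. The classifier is conservative: only exact and
probable matches count as dead; likely-false, unclassifiable, and no
record at all mean alive. Because gold capture is independent of
source capture, the small gold incompleteness does not bias measured
sensitivity; it surfaces instead as a slight depression of specificity
and PPV, as with a real benchmark index.

**What the generator does not emulate.** Real identifier distributions
(name frequency, shared surnames within families), duplicate patients,
cause of death, informative censoring (sicker patients lost earlier),
clerical correlation between sources (e.g. CDD1 scraping the same
obituary the clinic saw), and drift of source quality over calendar
time. Passing tests therefore demonstrate that the pipeline's rules and
metrics behave correctly and reproduce the calibrated regime — not that
any particular real data source has these properties.

## Linkage

Three deterministic passes of decreasing strictness: exact
(last, first, birth date); (last, birth date) with first-name
Levenshtein distance ≤ 1 (via edlib); (last, first, state) with the
birth date off by a valid day/month swap. Names are case-folded and
trimmed. The first pass with exactly one candidate wins; a tie of two
or more patients within a pass makes the record unmatched outright —
assigning a death to the wrong patient is the costlier error. Gold
match-quality classes are carried as data on the gold records rather
than recomputed from linkage scores: the scoring rules of a national
death index are not reproducible, and carrying the class keeps the
conservative classifier testable.

## Numerical and design choices

- **Wald intervals** without continuity correction, truncated to
  [0, 1]; exact intervals were not needed at these denominators and the
  operational reports this mirrors use the normal approximation.
- **Date-agreement denominator** is composite deaths (A+B), making the
  three windows comparable across versions; only the numerator set and
  the false-positive rule are forced by the metric's definition.
- **Composite order of operations** per version: resolve → plausibility
  filter; the final version then gap-fills from ABS (eligibility judged
  on the filtered composite) and re-filters so an implausible ABS date
  can never enter.
- **Survival censoring**: patients without a composite death are
  censored at min(last activity, study cutoff) — the standard EHR
  convention; the gold-based curve censors survivors at the cutoff,
  since a complete index's silence is evidence of survival. In the
  perfect-capture limit each curve equals the ground-truth curve
  computed under its own censoring convention; the two conventions
  deliberately differ, which is itself part of what incomplete capture
  does to real analyses.
- **Kaplan–Meier** estimation delegates to lifelines; ties are handled
  events-first; the median is the first time S(t) ≤ 0.5 and is
  reported as missing when never reached.
- **Reconstruction oracle**: for n ≤ 120 all integer tables are
  enumerated; for larger n the search walks the true-negative count D
  and visits B, C within ±4 of the values the printed specificity and
  NPV imply. The objective is the summed absolute deviation, in
  percentage points, of the recomputed metrics from the inputs; ties
  break toward smaller B, then smaller C, then larger A. Inputs more
  than 0.5 pp from every feasible table are declared infeasible.
  Against two-decimal rounded inputs the recovered sensitivity is
  accurate to well under 0.15 pp for cohort sizes in the thousands.

## Problem sizes

Shipped analyses use 10,000 patients for the calibrated benchmark (the
scale at which binomial error bands are a fraction of a percentage
point), 5,000 for linkage-recovery checks, and a few hundred per run
for property sweeps across many random configurations. These sizes were
chosen so each claim's sampling noise is small relative to the effect
it demonstrates.

## Known limitations

Independence of capture across sources is assumed by the calibration
back-solve; correlated capture would change the union path. The
ambiguity rule discards genuinely matchable records when identifiers
collide, slightly depressing sensitivity in cohorts with common names.
The reconstruction oracle presumes the printed metrics came from a
single coherent table with the stated n; it reports infeasibility, not
a best guess, when they did not.
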