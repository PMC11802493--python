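# Methods

`faerspv` implements a disproportionality-analysis pipeline for
spontaneous adverse-event reports in the FAERS quarterly-extract format,
organised around the use case of screening one suspect drug
(voriconazole by default) within one indication population
(hematological malignancies) and comparing child and adult strata.
Everything below is the package's own account of what is computed and
why; every number quoted is produced by the test suite, the analysis
scripts, or `scripts/acceptance.py`.

## Report model and preprocessing

A *report* is one case version spread over six `$`-delimited tables
(DEMO, DRUG, REAC, INDI, THER, RPSR) joined on `PRIMARYID`.  Cases are
deduplicated by the standard FAERS version rule: for records sharing a
`CASEID`, keep the one with the latest `FDA_DT`; on ties, keep the
higher `PRIMARYID` (numeric comparison when both IDs are numeric,
lexicographic otherwise).  Ancillary rows are joined on the retained
version's `PRIMARYID`, so superseded versions drop out with their
demography row.  Deduplication is idempotent by construction.

Dates are kept as (value, precision) pairs — `YYYYMMDD`, `YYYYMM`,
`YYYY`, or invalid — rather than coerced, because the time-to-onset
stage must distinguish *missing* from *inaccurate* dates.

Ages arrive in mixed units; the unit code is converted to years with
DEC×10, YR×1, MON÷12, WK÷52.18, DY÷365.25, HR÷8766.  A missing unit
with a present value is read as years; negative ages are treated as
missing and logged.  The child/adult cutoff is a config parameter
defaulting to 18 years with the half-open convention: age < 18 is
child, age ≥ 18 is adult, missing age is excluded from the stratified
comparison.  The cutoff is configurable because pediatric boundaries
differ between jurisdictions and studies.

Drug-name matching is exact after case-folding and trimming, not
substring matching, to avoid salt-form ambiguities ("voriconazole
hydrochloride" is not "voriconazole").  The hematological-malignancy
indication list ships as an editable term list (leukemias, lymphomas,
myeloma, MDS, ...) rather than a hard-coded constant.

MedDRA is licensed, so PT→SOC classification consumes a user-supplied
two-column mapping in which every PT belongs to exactly one SOC; PTs
absent from the mapping are routed to an `UNMAPPED` SOC and counted in
a warning.

## Disproportionality statistics

For one (term, stratum) cell the case-level 2×2 table is

|              | term | other terms |
|--------------|------|-------------|
| target drug  | a    | b           |
| other drugs  | c    | d           |

with N = a+b+c+d.  A case contributes at most once per term regardless
of repeated PTs.  The background (c, d) is every same-stratum case of
the ingested universe whose primary-suspect drug is not the target;
whether that universe is a whole database or an indication-restricted
slice is the caller's choice of input, made explicit rather than baked
in.

* **ROR** = ad/bc, CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)] / [c/(c+d)] with the 2×2 Pearson χ² (Yates
  correction off by default, switchable).
* **IC** (BCPNN) = log2(aN/((a+b)(a+c))).  IC025 = IC − 2√V.  The
  default V is the closed-form moment approximation of the posterior
  variance under the standard BCPNN priors (α₁ = β₁ = 1, α = β = 2,
  γ₁₁ = 1, γ scaled so the prior IC expectation is 0).  A second,
  count-based variant IC − 3.3·a^(−1/2) − 2.1·a^(−3/2) is selectable;
  the choice is recorded in the run manifest.  Two variants exist
  because published IC025 values in this literature do not identify a
  single closed form; offering both and logging the choice is more
  honest than pretending one is canonical.
* **EBGM** in *simple* mode is the observed/expected relative reporting
  ratio aN/((a+b)(a+c)) — so IC = log2(EBGM) holds exactly, which is
  the relation the consistency checks exploit — with
  EB05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)).

Zero cells make a statistic undefined (reported as NaN with a reason)
rather than silently corrected; a +0.5 continuity correction is
available behind a flag.  Undefined components fail their positivity
flag.

A cell is a **positive signal** only when all four algorithms pass
simultaneously: a ≥ 3 and ROR025 > 1; a ≥ 3, PRR ≥ 2 and χ² ≥ 4;
IC025 > 0; EB05 > 2.  All thresholds are config-exposed.

### Full empirical-Bayes mode (MGPS)

`eb_mode="full"` fits the DuMouchel gamma-Poisson shrinker: the
relative reporting ratio λ has a two-component gamma prior
w·Γ(α₁,β₁) + (1−w)·Γ(α₂,β₂), so the marginal of a given
E = (a+b)(a+c)/N is a mixture of negative binomials.  Hyperparameters
are estimated by maximizing that marginal likelihood over all screened
cells (≥ 20 required) with Nelder–Mead on log/logit-transformed
parameters from the classical starting point (0.2, 0.1, 2, 4, 1/3),
with two perturbed restarts; non-convergence raises an error carrying
the best-so-far fit.  The posterior per cell is again a two-component
gamma mixture; EBGM = exp(E[ln λ | a, E]) via digamma terms and EB05 is
the posterior 5th percentile found by bisection on the mixture CDF.
Per-cell posteriors are verified against brute-force grid integration
of prior × Poisson likelihood (agreement to 3 decimals in the tests).

The recovery simulation draws λ from 90% Γ(shape 5, mean 1) + 10%
Γ(shape 5, mean 5) with E uniform on [1, 50] and 5000 cells.  Shape 5
keeps the two components identifiably separated; with shape-2
components the marginal likelihood is nearly flat between the true
prior and blends with a heavier mixed component, and the MLE can sit
31% off the generating mean while *exceeding* the truth's likelihood —
a property of the model, not the optimizer.  Component means are
recovered within a few percent under the chosen design (25% is the
asserted bound).

## Stratified comparison

The volcano rows pair each (term, stratum) with log2 ROR and a raw
two-sided Fisher exact p (hypergeometric-tail enumeration; χ² is not
used as the raw test because many PT cells have a < 10), adjusted by
Benjamini–Hochberg jointly across both strata; significance is
q < 0.05 with no additional ROR floor.  SOC shares are percentages of
each stratum's total distinct (case, SOC) incidence count, so each
stratum's shares sum to 100 by construction; SOCs observed in only one
stratum are tagged `exclusive`.  The demographic table reports
within-stratum counts and percentages for sex, weight bins (<50,
50–100, >100 kg, missing), top-k reporter countries, and reporter type,
and the annual-count table groups cases by `FDA_DT` year with an
`unknown` bucket.

## Time-to-onset

TTO = EVENT_DT − START_DT in calendar days.  A case is included only
when both dates are day-precise and the interval is non-negative;
exclusions are audited by reason (`missing`, `partial-precision`,
`negative-interval`), and included + excluded always equals the input
count.  Bins are the closed integer ranges 0–30, 31–60, 61–90, 91–180,
181–360, >360 days (edges configurable; only the first two edges are
anchored by convention in this literature, the rest follow the usual
30/60/90/180/360 grid).  Medians are ordinary sample medians with
even-n averaging — which is what makes a non-integer median such as
8.5 days possible.

## Synthetic cohort generator

The generator emulates the FAERS file set with known ground truth.  Per
case it draws demographics (ages in mixed units, missing-age fraction
0.11 by default), one primary-suspect drug (the target with probability
0.10, otherwise one of 25 background drugs), concomitant drugs, a
hematological-malignancy indication (fraction configurable to exercise
the indication filter), reaction PTs as independent Bernoulli draws
from a background probability per PT (defaults drawn once, uniform on
0.005–0.04 over a 22-SOC × 5-PT dictionary), a therapy start date, and
an onset interval from a lognormal with median 10 days (σ = 1.1),
truncated to whole non-negative days — a right-skewed family consistent
with reported onset medians around 8–11 days.  Injected signals
multiply the baseline probability of one PT by a risk ratio for target
cases in the configured stratum (child/adult/both), clipped at 0.97.
The report date is onset plus a 0–180-day reporting delay.

Duplicates (default fraction 0.05) are emitted as an extra superseded
version per sampled case: half with an earlier `FDA_DT` (exercising the
recency clause), half with the same `FDA_DT` and a lower `PRIMARYID`
(exercising the tie-break clause).  Therapy start dates are missing for
50% of cases and month-precision for a further ~10%, so the TTO
exclusion paths are exercised at realistic rates (the study this
pipeline is shaped around retained only 81 of 605 reports for TTO).
Stratum ground truth is computed from the *emitted* age token through
the same normalization the pipeline uses, so unit rounding can never
flip a case across the cutoff between generation and analysis.

Identical config and seed produce byte-identical files; the manifest
records per-file row counts, per-stratum ground truth, and the injected
signal list.

What the generator does **not** emulate: correlated reporting across
PTs within a report (draws are independent given the stratum), secular
trends in reporting rates, country/occupation realism beyond categorical
sampling, FAERS schema drift across eras, and free-text drug-name noise.
Passing the recovery tests therefore shows the statistical machinery is
correct under the stated model, not that real-FAERS confounding
(notoriety bias, duplicate submitters, indication channeling) is
handled.

## Problem sizes and numerical choices

The end-to-end recovery runs use a 20 000-case cohort with one injected
child-only RR = 5 signal — about 340 child target cases, which puts the
injected cell near a ≈ 36 and gives all four algorithms comfortable
power while leaving 109 null PTs for the false-positive check (observed
false-positive fraction 0 at the joint rule; the asserted bound is 5%).
Type-I and FDR checks use a 4 000-case null cohort.  The gamma-mixture
fit uses 5000 cells.  Fisher p-values sum hypergeometric tail terms
with a 1e−7 relative tolerance against floating-point ties; BH
adjustment delegates to `statsmodels.multipletests` and is
cross-checked against a hand-stepped reference.  Ranked screens sort
positives first by descending ROR, ties by descending frequency then
term name, so output order is deterministic.

## Known limitations

* The printed per-term statistics of any real FAERS study cannot be
  reproduced without the database-wide background counts (b, c, d are
  not published); the package therefore validates against in-table
  arithmetic relations, printed marginal counts, and synthetic ground
  truth instead.
* The BCPNN IC025 closed form is an approximation; the full MCMC
  posterior of the original method is out of scope.
* The simple EBGM mode deliberately equals observed/expected (no
  shrinkage); use `eb_mode="full"` when shrinkage matters.
* Month-precision therapy dates are excluded from TTO rather than
  imputed; an imputation strategy would need a sensitivity analysis the
  pipeline does not currently provide.
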