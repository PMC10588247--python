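# Methods

## What this package models

The package implements an explicit (criterion-based) medication-review
tool for adults aged 60 and over, together with the expert-consensus
process that produced its criteria lists.  It has two connected halves:

1. **Consensus machinery** — the two-round Delphi decision rules,
   adjudication and stability statistics that turn per-item expert
   ratings (or their printed summaries) into final include/exclude
   labels for every candidate criterion.
2. **Screening engine** — the resulting knowledge base of 92
   disease-independent potentially-inappropriate-medication (PIM)
   criteria, 42 disease-conditional criteria and 35 prescribing-omission
   (PPO) statements, applied to patient medication records and
   aggregated into cohort reports.

## Consensus model

Items are rated on a 5-point Likert scale oriented so that 1 means
"definitely inappropriate" (or, for omission statements, "definitely
should be started") and 5 the opposite.  For each item and round the
panel's ratings are summarized as a mean with a two-sided 95% confidence
interval.  The decision rule is interval-based and strict:

- **positive consensus** iff the CI upper bound < 3.0;
- **negative consensus** iff the CI lower bound > 3.0;
- otherwise **undecided**, and the item is re-asked in round 2.

Items still undecided after round 2 go to a six-member geriatrician
subpanel and are resolved by strict majority (> 50%; a 3–3 tie is
negative).  Disease-conditional criteria instead use a percent-agreement
rule: consensus at ≥ 80% of the panel (17 of 21), computed as the
smallest integer k with k/n ≥ 0.8.

Numerical choices:

- When summaries are computed from raw ratings the default interval is
  the t-interval on n−1 degrees of freedom; a normal (z) interval is
  available.  The source tables print only the summaries, so all
  list-reconstruction results are driven by the printed two-decimal
  values verbatim — the interval method never touches them.
- Zero-variance panels collapse the interval onto the mean (not an
  error); classification then depends on the mean alone.
- Boundary cases resolve conservatively: a CI bound exactly on 3.0 is
  undecided; exactly half the adjudication votes is negative.

### Stability statistics

Round stability is summarized by Kendall's coefficient of concordance
W computed on within-rater midranks with the tie-correction term
(Likert data are heavily tied; the uncorrected statistic is not properly
bounded under ties):

    W = 12 S / (m²(n³−n) − m ΣTᵢ),  Tᵢ = Σ(t³−t) over tie groups.

A matrix in which every rater ties every item carries no ordering
information and is reported as trivial perfect concordance (W = 1).
The round coefficient of variation is the mean over items of
(sample SD / mean); values ≤ 0.25 are flagged acceptable.  The published
round CVs cannot be recomputed here because the raw rating matrices are
not public; the statistics are provided for use on new panels.

## Knowledge base and provenance

The criteria tables are shipped as hand-transcribed delimited-text
fixtures at printed precision, with one provenance row per item per
round (mean, CI bounds), adjudication outcomes, and footnote flags.
Every published final label is re-derivable from its provenance by the
decision rules above; `consensus-validate` performs exactly that check.

One row is a known anomaly: the enoxaparin candidate prints a round-1 CI
of 2.80–4.87 (straddling 3.0) yet is listed as a round-1 exclusion with
no round-2 statistics or adjudication footnote — most plausibly a
typographical CI bound.  It ships on an explicit allowlist: the
published label is carried, and the consistency check reports it loudly
instead of silently passing or failing.  Two other items (transdermal
fentanyl, sodium valproate) carry an interview footnote although their
round-2 intervals already satisfy the rule; the engine treats rule-based
consensus as decisive and records the footnote.

Adjudication vote tallies were never published, only outcomes; the
fixtures therefore store outcomes with empty tallies, and
`adjudicate()` computes from tallies whenever they are supplied.

The disease-conditional criteria carry no per-item round statistics (the
source prints none), so their provenance records the final list only.

## Screening semantics

Medication matching goes through a lexicon of canonical drugs, synonyms,
combination products and class memberships covering every drug and class
the criteria name, plus common salt/ester suffixes.  Matching is
deterministic; fuzzy matching is off by default and only ever produces
suggestions.  Combination products are screened both as themselves and
as their components.  Duplicate exposures collapse to one finding per
criterion.  Unknown names produce warnings, never findings.

Disease-conditional criteria fire when the condition is present and a
medication is in the target set net of exceptions; exceptions may be
drugs (quetiapine/clozapine for antipsychotics in parkinsonism) or route
tags (intra-articular corticosteroids).  Composite conditions are
vocabulary-derived (e.g. "delirium, dementia or cognitive impairment" is
any-of; "hypertension and urinary incontinence" is all-of).

Omission statements are three-valued.  Triggers and exceptions are small
predicates in disjunctive normal form over conditions, current
medications, age, measurements, vaccination history and end-of-life
status, evaluated with Kleene logic: an atom over an absent optional
attribute is *unknown*, and a criterion whose outcome depends on an
unknown is reported NOT_ASSESSABLE with the missing attributes listed —
screening must distinguish "no" from "unknown".  Indicated therapy on
the medication list suppresses the flag regardless of trigger state.
The single adjudicated "do-not-restart" statement (aspirin in atrial
fibrillation) is retained in the knowledge base but never emitted as a
recommendation.

Deliberate simplifications, each carried as a note on the criterion
rather than invented thresholds:

- "Consistently" elevated blood pressure is operationalized as a single
  measurement field (`sbp_mmHg`/`dbp_mmHg`).
- Qualitative dose/duration qualifiers ("high dose calcium", "temazepam
  short-term") do not gate matching; the note is attached to the finding.
- Disease severity grades (mild vs moderate-severe asthma) are not
  modelled; the condition code gates the rule.
- The two omission statements that read as conjunctions of therapies
  (bisphosphonate *and* vitamin D *and* calcium) follow the any-one-
  suffices contract of the indicated-therapy set; the conjunction
  semantics is recorded in the statement's note.
- Screening refuses patients under 60 unless explicitly overridden,
  matching the population the criteria were built for.

Patients with at least one *medication* criterion triggered (independent
or disease-conditional) define the "any PIM" cohort fraction; omission
findings are tallied separately.

## Synthetic data

The cohort generator emulates the shape of a hospitalized older-adult
population: ages uniform on 60–95, mixed chronic conditions at fixed
plausible prevalences (hypertension 0.55, diabetes 0.35, heart failure
0.12, atrial fibrillation 0.10, …), per-class medication exposures
(PPIs 0.25, statins 0.35, benzodiazepines 0.10, …) realised by sampling
a member drug of the class, real-looking distractor supplements to
exercise unmatched-name handling, and 20–30% missingness on
measurements and vaccination history to exercise the three-valued
contract.  All randomness flows from one `numpy` Generator seeded by the
config.

Ground-truth findings are derived constructively during generation: the
generator knows which class it sampled and which conditions it assigned
and walks the criterion definitions with its own naive loops — it never
calls the screening engine, so engine-vs-truth comparisons are not
circular.  A second, fully independent brute-force evaluator lives in
the test suite.

What the generator does **not** emulate: free-text prescription strings,
dose records, epidemiologically calibrated prevalences or correlated
comorbidity structure, and real-world coding noise.  Passing the
end-to-end gates therefore demonstrates rule-engine correctness on clean
structured input, not transcription robustness on raw hospital data.

The panel generator draws integer Likert ratings by rounding and
clipping normal draws at a configured per-item location and dispersion
for a 21-rater panel, which suffices to study the operating
characteristics of the CI rule (e.g. items with true location 2.0 and
dispersion 0.8 reach positive consensus in ≥ 99% of seeded replicates;
items located on the threshold with wide dispersion are usually
undecided).

## Problem sizes used in the shipped checks

List reconstruction runs over the full fixture set (125 + 36 provenance
items) in well under a second.  End-to-end screening gates use seeded
cohorts of 200 patients (exact ground-truth agreement), 20 patients
(brute-force oracle equivalence), and 100 patients (monotonicity under
random medication additions); consensus parameter recovery uses 1,000
seeded 21-rater panels.

## Known limitations

- The lexicon covers the drugs and classes named in the criteria tables
  plus representative class members, not a national formulary; coverage
  of the full merge lists behind the published classes is a data task,
  and unmatched names are surfaced as warnings by design.
- No drug–drug interaction checking and no alternative-therapy
  suggestions (both deliberately out of scope for this tool family).
- Whether a drug matching both an independent and a disease-conditional
  criterion should be deduplicated in a single "total PIMs" number is
  not specified by the source; both per-family tallies are reported.
- Published real-cohort validation figures are not reproducible desk-side
  (the dataset is not deposited); the synthetic gates above stand in.
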