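# malpip

Explicit prescribing-criteria screening for older adults: a rule engine
over a consensus-built list of **potentially inappropriate medications**
(PIMs, independent of or conditional on disease) and **potential
prescribing omissions** (PPOs), plus the Delphi consensus machinery that
produced the list.

It is written for pharmacists, clinicians and medication-safety
researchers who want to (a) screen patient medication records against an
explicit criteria list the way STOPP/START- or Beers-style tools are
used, and (b) audit or re-run the consensus process behind such a list.

## The model in brief

Criteria were decided by a 21-expert, two-round Delphi.  Each candidate
item is rated 1–5 (1 = definitely inappropriate / definitely start,
5 = the opposite) and summarized per round as a mean with a 95% CI.  An
item is included when the CI upper bound is **strictly below 3.0**,
excluded when the lower bound is strictly above 3.0, and otherwise
re-asked; items still undecided after round 2 are settled by strict
majority (> 50%) of a six-geriatrician panel.  Disease-conditional
criteria use an ≥ 80% agreement rule (17 of 21).  Round stability is
summarized by tie-corrected Kendall's W and a coefficient of variation
(≤ 0.25 acceptable).

The resulting knowledge base — 92 independent PIM criteria, 42
disease-specific criteria and 35 omission statements — ships in this
package as plain-text fixtures *with per-round provenance*, so every
published decision is re-derivable from its printed round statistics.

Screening is three-valued: an omission rule whose trigger depends on an
attribute the record does not carry (a missing blood pressure, an
unknown vaccination history) is reported `NOT_ASSESSABLE` with the
missing attributes listed, never silently passed.

## Worked example

```python
from malpip import load_kb, PatientRecord, screen_patient, run_delphi

kb = load_kb()

patient = PatientRecord(
    "demo-001", age_years=72,
    medications=["Cimetidine", "haloperidol", "glucosamine"],
    conditions={"parkinson_disease", "chronic_atrial_fibrillation"},
)
findings, warnings = screen_patient(patient, kb)
for f in findings:
    print(f.status, f.category, f.criterion_id, sorted(f.matched_drugs))
```

prints (abridged):

```
TRIGGERED INDEPENDENT_PIM h2_receptor_antagonists ['cimetidine']
TRIGGERED INDEPENDENT_PIM haloperidol ['haloperidol']
TRIGGERED DISEASE_PIM dp_parkinson ['haloperidol']
TRIGGERED PPO ppo_af_anticoagulant []
TRIGGERED PPO ppo_levodopa_parkinson []
NOT_ASSESSABLE PPO ppo_influenza_vaccine []
```

Reading: cimetidine is an H2-receptor-antagonist PIM; haloperidol is
both a PIM in its own right and specifically inappropriate in Parkinson
disease; the untreated atrial fibrillation and Parkinson disease each
trigger an omission (no anticoagulant, no levodopa/dopamine agonist);
the vaccination rules cannot be assessed because no history was
supplied; and glucosamine is reported as an unmatched name in
`warnings`, never guessed at.

Re-deriving the published list from its round statistics:

```python
paths, tally = run_delphi(kb.delphi_items("INDEPENDENT_PIM"))
print(tally.round1_positive, tally.assessed_r2, tally.round2_positive,
      tally.adjudicated, tally.positive)
# 60 43 32 11 92
```

## Command line

```
malpip kb counts                 # criteria census (92 / 42 / 35)
malpip kb lint                   # knowledge-base invariants, exit 2 on violation
malpip kb query --drug cimetidine
malpip consensus-validate        # re-derive every published decision
malpip normalize "valproate sodium"
malpip synth cohort --n 200 --seed 7 --out cohort/
malpip screen --meds cohort/medications.tsv --patients cohort/patients.tsv --out report/
```

Exit codes: 0 success, 1 usage error, 2 validation failure.

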