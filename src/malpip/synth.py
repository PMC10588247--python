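"""Seeded synthetic cohorts and expert panels with known ground truth.

The cohort generator emulates the shape of a hospitalized older-adult
population (age 60+, mixed chronic conditions, polypharmacy with both
criterion-relevant and irrelevant drugs, partly missing measurements and
vaccination histories).  Crucially, the expected screening findings are
derived *constructively while generating* — the generator knows exactly
which drug class it sampled and which conditions it assigned, and walks
the criterion definitions with its own naive loops rather than calling
the screening engine — so end-to-end tests compare the engine against an
independent bookkeeping of the truth.

The panel generator emulates a 21-expert Delphi round: integer 1-5
ratings drawn from a discretized normal with configurable per-item
location and dispersion.

No claim of epidemiological calibration is made; prevalences and
exposure rates are plausible defaults for this population, fixed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .kb import Category, KnowledgeBase, TriState
from .screening import (
    NOT_ASSESSABLE,
    NOT_TRIGGERED,
    TRIGGERED,
    MedicationEntry,
    PatientRecord,
    ScreenFinding,
)

__all__ = ["CohortConfig", "PanelConfig", "generate_cohort", "generate_panel"]


DEFAULT_EXPOSURES = {
    # class (or canonical drug) -> probability of exposure per patient
    "loop diuretics": 0.18,
    "thiazide diuretics": 0.12,
    "proton pump inhibitors": 0.25,
    "h2 receptor antagonists": 0.05,
    "benzodiazepines": 0.10,
    "z-hypnotics": 0.04,
    "atypical antipsychotics": 0.05,
    "first generation antipsychotics": 0.03,
    "first generation antihistamines": 0.06,
    "non-cox-2 selective nsaids": 0.12,
    "cox-2 selective inhibitors": 0.05,
    "statins": 0.35,
    "ace inhibitors": 0.25,
    "angiotensin receptor blockers": 0.12,
    "beta blockers": 0.25,
    "dihydropyridine calcium channel blockers": 0.30,
    "non-dihydropyridine calcium channel blockers": 0.05,
    "antiplatelets": 0.20,
    "vitamin k antagonists": 0.05,
    "direct thrombin inhibitors": 0.03,
    "opioids": 0.08,
    "ssris": 0.07,
    "tricyclic antidepressants": 0.05,
    "simple analgesics": 0.30,
    "biguanides": 0.20,
    "sulfonylureas": 0.10,
    "systemic corticosteroids": 0.07,
    "laxatives": 0.10,
    "acetylcholinesterase inhibitors": 0.04,
    "oral bisphosphonates": 0.05,
    "levodopa and dopamine agonists": 0.04,
    "vitamin d supplements": 0.10,
    "calcium supplements": 0.10,
    "clidinium-chlordiazepoxide": 0.02,
}

DEFAULT_PREVALENCES = {
    "hypertension": 0.55,
    "diabetes_mellitus": 0.35,
    "heart_failure": 0.12,
    "chronic_atrial_fibrillation": 0.10,
    "chronic_kidney_disease": 0.15,
    "coronary_artery_disease": 0.15,
    "copd": 0.08,
    "bronchial_asthma": 0.05,
    "parkinson_disease": 0.04,
    "dementia": 0.08,
    "delirium": 0.03,
    "falls": 0.10,
    "osteoporosis": 0.10,
    "constipation": 0.12,
    "gout": 0.07,
    "depression": 0.08,
    "epilepsy": 0.03,
    "urinary_incontinence": 0.06,
    "insomnia": 0.10,
    "peptic_ulcer_history": 0.06,
    "orthostatic_hypotension": 0.05,
    "benign_prostatic_hyperplasia": 0.10,
    "hyponatremia": 0.04,
    "hypokalemia": 0.04,
}

DISTRACTOR_NAMES = (
    "glucosamine",
    "vitamin c",
    "omega-3 fish oil",
    "lutein complex",
    "ginkgo biloba",
    "spirulina",
)

VACCINATION_RATES = {
    "influenza_past_year": 0.35,
    "pneumococcal_ever_after_65": 0.30,
    "zoster_ever": 0.10,
    "tdap_ever": 0.10,
}


@dataclass
class CohortConfig:
    n_patients: int = 200
    seed: int = 0
    age_range: tuple = (60, 95)
    exposures: dict = field(default_factory=lambda: dict(DEFAULT_EXPOSURES))
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    distractor_drug_rate: float = 0.30
    measurement_missing_rate: float = 0.30
    vaccination_missing_rate: float = 0.20
    end_of_life_rate: float = 0.02

    def validate(self):
        if self.n_patients <= 0:
            raise DomainError("n_patients must be positive")
        probs = [
            *self.exposures.values(),
            *self.prevalences.values(),
            self.distractor_drug_rate,
            self.measurement_missing_rate,
            self.vaccination_missing_rate,
            self.end_of_life_rate,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise DomainError("all probabilities must lie in [0, 1]")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise DomainError(f"bad age_range {self.age_range}")
        return self


@dataclass
class PanelConfig:
    n_raters: int = 21
    items: dict = field(default_factory=dict)  # item_id -> (true_mean, dispersion)
    seed: int = 0

    def validate(self):
        if self.n_raters < 2:
            raise DomainError("need at least 2 raters")
        if not self.items:
            raise DomainError("no items configured")
        for item_id, (mean, disp) in self.items.items():
            if not (1.0 <= mean <= 5.0):
                raise DomainError(f"{item_id}: true mean must be in [1, 5]")
            if not disp > 0:
                raise DomainError(f"{item_id}: dispersion must be positive")
        return self


# ---------------------------------------------------------------------------
# cohort generation


def _sample_patient(pid: str, cfg: CohortConfig, kb: KnowledgeBase, rng) -> PatientRecord:
    lo, hi = cfg.age_range
    age = int(rng.integers(lo, hi + 1))
    sex = "F" if rng.random() < 0.5 else "M"
    conditions = {c for c in sorted(cfg.prevalences) if rng.random() < cfg.prevalences[c]}

    meds: list[str] = []
    for key in sorted(cfg.exposures):
        if rng.random() >= cfg.exposures[key]:
            continue
        if key in kb.lexicon.entries:
            meds.append(key)
        else:
            members = kb.lexicon.members_of(key)
            if not members:
                raise DomainError(f"exposure key {key!r} is neither a drug nor a class")
            meds.append(members[int(rng.integers(len(members)))])
    if rng.random() < cfg.distractor_drug_rate:
        meds.append(DISTRACTOR_NAMES[int(rng.integers(len(DISTRACTOR_NAMES)))])

    measurements = {}
    for key, mu, sd, nd in (("sbp_mmHg", 135, 20, 0), ("dbp_mmHg", 78, 12, 0), ("bmd_t_score", -1.2, 1.2, 1)):
        if rng.random() >= cfg.measurement_missing_rate:
            measurements[key] = round(float(rng.normal(mu, sd)), nd)
    vaccinations = {}
    for key in VACCINATION_REGISTRY_ORDER:
        if rng.random() >= cfg.vaccination_missing_rate:
            vaccinations[key] = bool(rng.random() < VACCINATION_RATES[key])
    end_of_life: Optional[bool] = None
    if rng.random() < 0.9:
        end_of_life = bool(rng.random() < cfg.end_of_life_rate)

    return PatientRecord(
        patient_id=pid,
        age_years=age,
        sex=sex,
        medications=[MedicationEntry(m) for m in meds],
        conditions=conditions,
        measurements=measurements,
        vaccinations=vaccinations,
        end_of_life=end_of_life,
    )


VACCINATION_REGISTRY_ORDER = tuple(VACCINATION_RATES)


# --- constructive ground truth (naive loops; independent of the engine) ----


def _truth_meds(patient: PatientRecord, kb: KnowledgeBase):
    """(canonical, classes, route) for every known sampled drug, with
    combination components expanded; unknown names are skipped."""
    out = []
    for med in patient.medications:
        entry = kb.lexicon.entries.get(med.raw_name)
        if entry is None:
            continue  # distractor
        classes = set(entry.class_memberships)
        for comp in entry.combination_components:
            classes |= kb.lexicon.entries[comp].class_memberships
        out.append((entry.canonical_name, frozenset(classes), entry.default_route))
        for comp in entry.combination_components:
            centry = kb.lexicon.entries[comp]
            out.append((comp, centry.class_memberships, centry.default_route))
    return out


def _truth_hits(name, classes, target):
    return target == name or target in classes


def _truth_atom(atom, patient, meds, kb) -> TriState:
    if atom.kind == "cond":
        return (
            TriState.TRUE
            if kb.conditions.is_present(atom.key, patient.conditions)
            else TriState.FALSE
        )
    if atom.kind == "med":
        hit = any(_truth_hits(n, c, atom.key) for n, c, _ in meds)
        return TriState.TRUE if hit else TriState.FALSE
    cmp = {">": np.greater, ">=": np.greater_equal, "<": np.less, "<=": np.less_equal}
    if atom.kind == "age":
        return TriState.TRUE if cmp[atom.op](patient.age_years, atom.value) else TriState.FALSE
    if atom.kind == "meas":
        v = patient.measurements.get(atom.key)
        if v is None:
            return TriState.UNKNOWN
        return TriState.TRUE if cmp[atom.op](v, atom.value) else TriState.FALSE
    if atom.kind == "vacc":
        v = patient.vaccinations.get(atom.key)
        if v is None:
            return TriState.UNKNOWN
        return TriState.TRUE if bool(v) == atom.value else TriState.FALSE
    if patient.end_of_life is None:
        return TriState.UNKNOWN
    return TriState.TRUE if patient.end_of_life else TriState.FALSE


def _truth_predicate(pred, patient, meds, kb):
    if not pred.disjuncts:
        return TriState.FALSE, frozenset()
    missing = set()
    for clause in pred.disjuncts:
        states, clause_missing = [], set()
        for atom in clause:
            st = _truth_atom(atom, patient, meds, kb)
            states.append(st)
            if st is TriState.UNKNOWN:
                clause_missing.add(atom.attribute)
        if all(s is TriState.TRUE for s in states):
            return TriState.TRUE, frozenset()
        if TriState.FALSE not in states:
            missing |= clause_missing
    if missing:
        return TriState.UNKNOWN, frozenset(missing)
    return TriState.FALSE, frozenset()


def _ground_truth(patient: PatientRecord, kb: KnowledgeBase) -> list:
    meds = _truth_meds(patient, kb)
    findings = []

    for cid in sorted(kb.independent):
        crit = kb.independent[cid]
        if crit.final_status != "PIM":
            continue
        matched = set()
        for name, classes, route in meds:
            if crit.target_kind == "CLASS":
                hit = crit.target in classes
            else:
                # DRUG targets are stored as canonical lexicon names
                hit = crit.target == name
            if hit and crit.route and route and route != crit.route:
                hit = False
            if hit:
                matched.add(name)
        if matched:
            findings.append(
                ScreenFinding(
                    patient.patient_id,
                    cid,
                    Category.INDEPENDENT_PIM.value,
                    TRIGGERED,
                    matched_drugs=frozenset(matched),
                    practice_statement_ref=crit.practice_statement,
                )
            )

    for cid in sorted(kb.disease):
        crit = kb.disease[cid]
        if not kb.conditions.is_present(crit.condition_code, patient.conditions):
            continue
        matched = set()
        for name, classes, route in meds:
            if name in crit.drug_exceptions:
                continue
            if route and route in crit.route_exceptions:
                continue
            if any(_truth_hits(name, classes, t) for t in crit.drug_targets):
                matched.add(name)
        if matched:
            findings.append(
                ScreenFinding(
                    patient.patient_id,
                    cid,
                    Category.DISEASE_PIM.value,
                    TRIGGERED,
                    matched_drugs=frozenset(matched),
                    condition_code=crit.condition_code,
                    note=crit.qualifier_notes,
                )
            )

    for cid in sorted(kb.ppo):
        crit = kb.ppo[cid]
        if crit.final_status != "PPO":
            continue
        if any(_truth_hits(n, c, t) for t in crit.indicated_therapy for n, c, _ in meds):
            continue
        trig, trig_missing = _truth_predicate(crit.trigger, patient, meds, kb)
        if trig is TriState.FALSE:
            continue
        if trig is TriState.UNKNOWN:
            status, missing = NOT_ASSESSABLE, trig_missing
        else:
            exc, exc_missing = _truth_predicate(crit.exception, patient, meds, kb)
            if exc is TriState.TRUE:
                continue
            if exc is TriState.UNKNOWN:
                status, missing = NOT_ASSESSABLE, exc_missing
            else:
                status, missing = TRIGGERED, frozenset()
        findings.append(
            ScreenFinding(
                patient.patient_id,
                cid,
                Category.PPO.value,
                status,
                missing_attributes=missing,
                note=crit.notes,
            )
        )
    return findings


def generate_cohort(config: CohortConfig, kb: KnowledgeBase) -> tuple[list, list]:
    """Sample a cohort and its expected findings.

    Returns ``(patients, ground_truth)`` where ground_truth is the
    ordered list of ScreenFinding the screening engine must reproduce
    exactly.  Identical (config, seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_patients)))
    patients, truth = [], []
    for i in range(config.n_patients):
        patient = _sample_patient(f"p{i + 1:0{width}d}", config, kb, rng)
        patients.append(patient)
        truth.extend(_ground_truth(patient, kb))
    order = {Category.INDEPENDENT_PIM.value: 0, Category.DISEASE_PIM.value: 1, Category.PPO.value: 2}
    truth.sort(key=lambda f: (f.patient_id, order[f.category], f.criterion_id))
    return patients, truth


# ---------------------------------------------------------------------------
# panel generation


def generate_panel(config: PanelConfig) -> pd.DataFrame:
    """Rating matrix (raters x items) of integers 1..5: a normal draw at
    each item's configured location/dispersion, rounded and clipped."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cols = {}
    for item_id in config.items:  # insertion order: caller-controlled
        mean, disp = config.items[item_id]
        draws = rng.normal(mean, disp, size=config.n_raters)
        cols[item_id] = np.clip(np.rint(draws), 1, 5).astype(int)
    index = [f"rater{j + 1:02d}" for j in range(config.n_raters)]
    return pd.DataFrame(cols, index=index)
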