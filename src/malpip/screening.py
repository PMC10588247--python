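"""Apply the criteria to patient records and aggregate cohort statistics.

Screening is three-valued for omission criteria: a rule whose trigger
depends on an attribute the record does not carry is reported
NOT_ASSESSABLE (listing the missing attributes) rather than silently
passed — a screening tool must distinguish "no" from "unknown".
Medication matching goes through the drug lexicon: combination products
are expanded and their components screened individually, duplicate
exposures collapse to one finding per criterion, and names the lexicon
does not know produce warnings, never findings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import DomainError
from .kb import (
    _OPS,
    Category,
    CriterionDiseasePIM,
    CriterionIndependentPIM,
    CriterionPPO,
    KnowledgeBase,
    Predicate,
    TriState,
)

__all__ = [
    "MedicationEntry",
    "PatientRecord",
    "ScreenFinding",
    "CohortSummary",
    "screen_independent",
    "screen_disease",
    "screen_ppo",
    "evaluate_ppo",
    "screen_patient",
    "summarize_cohort",
]

MIN_SCREENING_AGE = 60

TRIGGERED = "TRIGGERED"
NOT_TRIGGERED = "NOT_TRIGGERED"
NOT_ASSESSABLE = "NOT_ASSESSABLE"


@dataclass(frozen=True)
class MedicationEntry:
    raw_name: str
    dose_mg: Optional[float] = None
    route: Optional[str] = None
    chronic: Optional[bool] = None
    frequency_note: Optional[str] = None

    def __post_init__(self):
        if self.dose_mg is not None and not self.dose_mg > 0:
            raise DomainError(f"dose_mg must be positive, got {self.dose_mg}")


@dataclass
class PatientRecord:
    patient_id: str
    age_years: int
    medications: list = field(default_factory=list)
    conditions: set = field(default_factory=set)
    measurements: dict = field(default_factory=dict)
    vaccinations: dict = field(default_factory=dict)
    sex: Optional[str] = None
    end_of_life: Optional[bool] = None

    def __post_init__(self):
        if self.age_years < 0:
            raise DomainError("age_years must be >= 0")
        self.medications = [
            m if isinstance(m, MedicationEntry) else MedicationEntry(m)
            for m in self.medications
        ]
        self.conditions = set(self.conditions)


@dataclass(frozen=True)
class ScreenFinding:
    patient_id: str
    criterion_id: str
    category: str
    status: str  # TRIGGERED | NOT_ASSESSABLE
    matched_drugs: frozenset = frozenset()
    condition_code: Optional[str] = None
    missing_attributes: frozenset = frozenset()
    practice_statement_ref: str = ""
    note: str = ""


# ---------------------------------------------------------------------------
# medication resolution


@dataclass(frozen=True)
class _ResolvedMed:
    canonical: str
    classes: frozenset
    route: Optional[str]
    components: tuple = ()


def _resolve_medications(patient: PatientRecord, kb: KnowledgeBase):
    """Resolve raw medication rows once; returns (resolved list, warnings)."""
    resolved: list[_ResolvedMed] = []
    warnings: list[str] = []
    for med in patient.medications:
        norm = kb.lexicon.normalize_drug(med.raw_name)
        if norm.status == "UNMATCHED":
            warnings.append(f"{patient.patient_id}: unmatched medication {med.raw_name!r}")
            continue
        route = med.route or kb.lexicon.default_route(norm.canonical)
        resolved.append(_ResolvedMed(norm.canonical, norm.classes, route, norm.components))
        # combination products: components are screened individually too
        for comp in norm.components:
            resolved.append(
                _ResolvedMed(
                    comp,
                    kb.lexicon.expand_classes(comp),
                    med.route or kb.lexicon.default_route(comp),
                )
            )
    return resolved, warnings


def _med_hits_target(med: _ResolvedMed, target: str, kb: KnowledgeBase) -> bool:
    if target in med.classes:
        return True
    norm = kb.lexicon.normalize_drug(target)
    return norm.status != "UNMATCHED" and norm.canonical == med.canonical


def _require_age(patient: PatientRecord, allow_under_60: bool):
    if patient.age_years < MIN_SCREENING_AGE and not allow_under_60:
        raise DomainError(
            f"patient {patient.patient_id} is {patient.age_years}; the criteria are "
            "designed for adults aged 60+ (pass allow_under_60 to override)"
        )


# ---------------------------------------------------------------------------
# the three screens


def screen_independent(
    patient: PatientRecord, kb: KnowledgeBase, allow_under_60: bool = False
) -> list:
    """Disease-independent medication criteria: one finding per criterion
    with any matching medication (PIM-status criteria only)."""
    _require_age(patient, allow_under_60)
    meds, _ = _resolve_medications(patient, kb)
    findings = []
    for cid in sorted(kb.independent):
        crit = kb.independent[cid]
        if crit.final_status != "PIM":
            continue
        matched = set()
        for med in meds:
            if crit.target_kind == "CLASS":
                hit = crit.target in med.classes
            else:
                norm = kb.lexicon.normalize_drug(crit.target)
                hit = norm.canonical == med.canonical
            if hit and crit.route and med.route and med.route != crit.route:
                hit = False
            if hit:
                matched.add(med.canonical)
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
    return findings


def screen_disease(
    patient: PatientRecord, kb: KnowledgeBase, allow_under_60: bool = False
) -> list:
    """Disease-conditional criteria: condition present AND a medication in
    the target set, net of drug and route exceptions."""
    _require_age(patient, allow_under_60)
    meds, _ = _resolve_medications(patient, kb)
    findings = []
    for cid in sorted(kb.disease):
        crit = kb.disease[cid]
        if not kb.conditions.is_present(crit.condition_code, patient.conditions):
            continue
        excluded_drugs = set()
        for e in crit.drug_exceptions:
            norm = kb.lexicon.normalize_drug(e)
            if norm.canonical:
                excluded_drugs.add(norm.canonical)
        matched = set()
        for med in meds:
            if med.canonical in excluded_drugs:
                continue
            if med.route and med.route in crit.route_exceptions:
                continue
            if any(_med_hits_target(med, t, kb) for t in crit.drug_targets):
                matched.add(med.canonical)
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
    return findings


def _eval_atom(atom, patient: PatientRecord, meds, kb: KnowledgeBase) -> TriState:
    if atom.kind == "cond":
        present = kb.conditions.is_present(atom.key, patient.conditions)
        return TriState.TRUE if present else TriState.FALSE
    if atom.kind == "med":
        hit = any(_med_hits_target(m, atom.key, kb) for m in meds)
        return TriState.TRUE if hit else TriState.FALSE
    if atom.kind == "age":
        return TriState.TRUE if _OPS[atom.op](patient.age_years, atom.value) else TriState.FALSE
    if atom.kind == "meas":
        val = patient.measurements.get(atom.key)
        if val is None:
            return TriState.UNKNOWN
        return TriState.TRUE if _OPS[atom.op](val, atom.value) else TriState.FALSE
    if atom.kind == "vacc":
        val = patient.vaccinations.get(atom.key)
        if val is None:
            return TriState.UNKNOWN
        return TriState.TRUE if bool(val) == atom.value else TriState.FALSE
    if atom.kind == "flag":
        if patient.end_of_life is None:
            return TriState.UNKNOWN
        return TriState.TRUE if patient.end_of_life else TriState.FALSE
    raise DomainError(f"unknown atom kind {atom.kind}")  # pragma: no cover


def _eval_predicate(pred: Predicate, patient, meds, kb) -> tuple[TriState, frozenset]:
    """Kleene evaluation of a DNF predicate; returns (state, missing attrs
    that made the result unknown)."""
    if pred.is_empty:
        return TriState.FALSE, frozenset()
    any_unknown: set = set()
    for clause in pred.disjuncts:
        clause_state = TriState.TRUE
        clause_missing: set = set()
        for atom in clause:
            st = _eval_atom(atom, patient, meds, kb)
            if st is TriState.FALSE:
                clause_state = TriState.FALSE
                break
            if st is TriState.UNKNOWN:
                clause_state = TriState.UNKNOWN
                clause_missing.add(atom.attribute)
        if clause_state is TriState.TRUE:
            return TriState.TRUE, frozenset()
        if clause_state is TriState.UNKNOWN:
            any_unknown |= clause_missing
    if any_unknown:
        return TriState.UNKNOWN, frozenset(any_unknown)
    return TriState.FALSE, frozenset()


def evaluate_ppo(
    patient: PatientRecord, crit: CriterionPPO, kb: KnowledgeBase, meds=None
) -> tuple[str, frozenset]:
    """Three-valued evaluation of one omission criterion for one patient.

    Returns (status, missing_attributes) with status one of TRIGGERED /
    NOT_TRIGGERED / NOT_ASSESSABLE.  Indicated therapy on the medication
    list suppresses the flag regardless of trigger state.
    """
    if meds is None:
        meds, _ = _resolve_medications(patient, kb)
    therapy_present = any(
        _med_hits_target(m, t, kb) for t in crit.indicated_therapy for m in meds
    )
    if therapy_present:
        return NOT_TRIGGERED, frozenset()
    trig, trig_missing = _eval_predicate(crit.trigger, patient, meds, kb)
    if trig is TriState.FALSE:
        return NOT_TRIGGERED, frozenset()
    if trig is TriState.UNKNOWN:
        return NOT_ASSESSABLE, trig_missing
    exc, exc_missing = _eval_predicate(crit.exception, patient, meds, kb)
    if exc is TriState.TRUE:
        return NOT_TRIGGERED, frozenset()
    if exc is TriState.UNKNOWN:
        return NOT_ASSESSABLE, exc_missing
    return TRIGGERED, frozenset()


def screen_ppo(
    patient: PatientRecord, kb: KnowledgeBase, allow_under_60: bool = False
) -> list:
    """Prescribing-omission criteria; the adjudicated do-not-restart item
    is never emitted as a recommendation."""
    _require_age(patient, allow_under_60)
    meds, _ = _resolve_medications(patient, kb)
    findings = []
    for cid in sorted(kb.ppo):
        crit = kb.ppo[cid]
        if crit.final_status != "PPO":
            continue
        status, missing = evaluate_ppo(patient, crit, kb, meds)
        if status == NOT_TRIGGERED:
            continue
        findings.append(
            ScreenFinding(
                patient.patient_id,
                cid,
                Category.PPO.value,
                status,
                condition_code=None,
                missing_attributes=missing,
                note=crit.notes,
            )
        )
    return findings


_CATEGORY_ORDER = {
    Category.INDEPENDENT_PIM.value: 0,
    Category.DISEASE_PIM.value: 1,
    Category.PPO.value: 2,
}


def screen_patient(
    patient: PatientRecord, kb: KnowledgeBase, allow_under_60: bool = False
) -> tuple[list, list]:
    """All three screens, deterministically ordered (category then
    criterion id); returns (findings, warnings)."""
    _require_age(patient, allow_under_60)
    _, warnings = _resolve_medications(patient, kb)
    findings = (
        screen_independent(patient, kb, allow_under_60)
        + screen_disease(patient, kb, allow_under_60)
        + screen_ppo(patient, kb, allow_under_60)
    )
    findings.sort(key=lambda f: (_CATEGORY_ORDER[f.category], f.criterion_id))
    return findings, warnings


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_with_any_pim: int
    pct_with_any_pim: float
    total_pim_findings: int
    total_ppo_findings: int
    n_not_assessable: int
    per_criterion_counts: tuple  # ((criterion_id, count), ...) desc, then alpha
    top_drugs: tuple  # ((canonical, count), ...) desc, then alpha


def summarize_cohort(findings: Iterable[ScreenFinding], patients: Iterable[PatientRecord]) -> CohortSummary:
    """Cohort-level metrics: patients with at least one medication
    criterion triggered, totals by family, per-criterion and per-drug
    tallies (counts descending, ties alphabetical)."""
    patients = list(patients)
    if not patients:
        raise DomainError("cannot summarize an empty cohort")
    findings = list(findings)
    pim_cats = {Category.INDEPENDENT_PIM.value, Category.DISEASE_PIM.value}
    with_pim = {
        f.patient_id for f in findings if f.category in pim_cats and f.status == TRIGGERED
    }
    known_ids = {p.patient_id for p in patients}
    stray = {f.patient_id for f in findings} - known_ids
    if stray:
        raise DomainError(f"findings reference unknown patients: {sorted(stray)}")
    total_pim = sum(1 for f in findings if f.category in pim_cats and f.status == TRIGGERED)
    total_ppo = sum(1 for f in findings if f.category == Category.PPO.value and f.status == TRIGGERED)
    n_na = sum(1 for f in findings if f.status == NOT_ASSESSABLE)

    crit_counts: dict[str, int] = {}
    drug_counts: dict[str, int] = {}
    for f in findings:
        if f.status != TRIGGERED:
            continue
        crit_counts[f.criterion_id] = crit_counts.get(f.criterion_id, 0) + 1
        for d in f.matched_drugs:
            drug_counts[d] = drug_counts.get(d, 0) + 1

    def ranked(counts: dict) -> tuple:
        return tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))

    n = len(patients)
    return CohortSummary(
        n_patients=n,
        n_with_any_pim=len(with_pim),
        pct_with_any_pim=100.0 * len(with_pim) / n,
        total_pim_findings=total_pim,
        total_ppo_findings=total_ppo,
        n_not_assessable=n_na,
        per_criterion_counts=ranked(crit_counts),
        top_drugs=ranked(drug_counts),
    )
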