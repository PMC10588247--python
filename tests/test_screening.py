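"""Screening engine: per-family rules, three-valued omission logic,
properties (monotonicity, exception soundness) and a naive brute-force
oracle."""

import numpy as np
import pytest

from conftest import sort_findings
from malpip.errors import DomainError
from malpip.kb import TriState
from malpip.screening import (
    NOT_ASSESSABLE,
    NOT_TRIGGERED,
    TRIGGERED,
    MedicationEntry,
    PatientRecord,
    evaluate_ppo,
    screen_disease,
    screen_independent,
    screen_patient,
    screen_ppo,
    summarize_cohort,
)
from malpip.synth import CohortConfig, generate_cohort


def patient(pid="p1", age=72, meds=(), conditions=(), measurements=None, vaccinations=None, **kw):
    return PatientRecord(
        pid,
        age,
        medications=list(meds),
        conditions=set(conditions),
        measurements=measurements or {},
        vaccinations=vaccinations or {},
        **kw,
    )


class TestIndependentScreen:
    def test_h2_antagonist_triggers(self, kb):
        found = screen_independent(patient(meds=["cimetidine"]), kb)
        assert [f.criterion_id for f in found] == ["h2_receptor_antagonists"]
        assert found[0].matched_drugs == frozenset({"cimetidine"})
        assert found[0].practice_statement_ref.startswith("S2:")

    def test_not_pim_drug_produces_nothing(self, kb):
        assert screen_independent(patient(meds=["paracetamol"]), kb) == []

    def test_empty_medication_list(self, kb):
        assert screen_independent(patient(), kb) == []

    def test_combination_components_screened_individually(self, kb):
        found = screen_independent(patient(meds=["clidinium–chlordiazepoxide"]), kb)
        ids = {f.criterion_id for f in found}
        assert "clidinium_chlordiazepoxide" in ids  # the product's own criterion
        assert "benzodiazepines" in ids  # component class match

    def test_duplicate_rows_collapse_to_one_finding(self, kb):
        found = screen_independent(patient(meds=["diazepam", "Diazepam", "lorazepam"]), kb)
        benzo = [f for f in found if f.criterion_id == "benzodiazepines"]
        assert len(benzo) == 1
        assert benzo[0].matched_drugs == frozenset({"diazepam", "lorazepam"})

    def test_route_exclusion_on_transdermal_criterion(self, kb):
        # parenteral fentanyl does not trigger the patch criterion but is
        # still an opioid-class PIM
        found = screen_independent(
            patient(meds=[MedicationEntry("fentanyl", route="parenteral")]), kb
        )
        ids = {f.criterion_id for f in found}
        assert "fentanyl_patch" not in ids
        assert "opioids" in ids

    def test_age_gate(self, kb):
        with pytest.raises(DomainError):
            screen_independent(patient(age=59), kb)
        assert screen_independent(patient(age=59), kb, allow_under_60=True) == []


class TestDiseaseScreen:
    def test_antipsychotic_in_parkinson(self, kb):
        found = screen_disease(patient(meds=["haloperidol"], conditions=["parkinson_disease"]), kb)
        assert [f.criterion_id for f in found] == ["dp_parkinson"]

    def test_exception_drug_never_triggers(self, kb):
        assert (
            screen_disease(patient(meds=["quetiapine"], conditions=["parkinson_disease"]), kb)
            == []
        )

    def test_nsaid_in_heart_failure(self, kb):
        found = screen_disease(patient(meds=["diclofenac"], conditions=["heart_failure"]), kb)
        assert [f.criterion_id for f in found] == ["dp_heart_failure"]

    def test_no_condition_no_finding(self, kb):
        assert screen_disease(patient(meds=["haloperidol"]), kb) == []

    def test_composite_condition_any_of(self, kb):
        # delirium alone satisfies the delirium/dementia/cognitive-impairment group
        found = screen_disease(patient(meds=["oxybutynin"], conditions=["delirium"]), kb)
        assert "dp_cognitive" in {f.criterion_id for f in found}

    def test_composite_condition_all_of(self, kb):
        loop_med = ["frusemide"]
        only_htn = screen_disease(patient(meds=loop_med, conditions=["hypertension"]), kb)
        assert "dp_htn_incontinence" not in {f.criterion_id for f in only_htn}
        both = screen_disease(
            patient(meds=loop_med, conditions=["hypertension", "urinary_incontinence"]), kb
        )
        assert "dp_htn_incontinence" in {f.criterion_id for f in both}

    def test_route_exception_intra_articular_steroid(self, kb):
        p = patient(
            meds=[MedicationEntry("triamcinolone", route="intra-articular")],
            conditions=["osteoporosis"],
        )
        assert "dp_oa_op" not in {f.criterion_id for f in screen_disease(p, kb)}
        p2 = patient(meds=[MedicationEntry("prednisolone")], conditions=["osteoporosis"])
        assert "dp_oa_op" in {f.criterion_id for f in screen_disease(p2, kb)}


class TestPPOScreen:
    def test_untreated_af_triggers_anticoagulant_omission(self, kb):
        found = screen_ppo(patient(conditions=["chronic_atrial_fibrillation"]), kb)
        assert any(f.criterion_id == "ppo_af_anticoagulant" and f.status == TRIGGERED for f in found)

    def test_anticoagulated_af_is_silent(self, kb):
        found = screen_ppo(
            patient(meds=["warfarin"], conditions=["chronic_atrial_fibrillation"]), kb
        )
        assert not any(f.criterion_id == "ppo_af_anticoagulant" for f in found)

    def test_pneumococcal_vaccination_gap(self, kb):
        p = patient(age=70, vaccinations={"pneumococcal_ever_after_65": False})
        found = screen_ppo(p, kb)
        hit = [f for f in found if f.criterion_id == "ppo_pneumococcal_vaccine"]
        assert hit and hit[0].status == TRIGGERED

    def test_statin_age_exception(self, kb):
        p = patient(age=87, conditions=["peripheral_vascular_disease"])
        assert not any(
            f.criterion_id == "ppo_statin_vascular" and f.status == TRIGGERED
            for f in screen_ppo(p, kb)
        )
        p2 = patient(age=80, conditions=["peripheral_vascular_disease"], end_of_life=False)
        assert any(
            f.criterion_id == "ppo_statin_vascular" and f.status == TRIGGERED
            for f in screen_ppo(p2, kb)
        )

    def test_missing_blood_pressure_is_not_assessable(self, kb):
        found = screen_ppo(patient(), kb)
        hit = [f for f in found if f.criterion_id == "ppo_antihypertensive"]
        assert hit and hit[0].status == NOT_ASSESSABLE
        assert {"sbp_mmHg", "dbp_mmHg"} <= set(hit[0].missing_attributes)

    def test_not_ppo_item_never_emitted(self, kb):
        p = patient(conditions=["chronic_atrial_fibrillation"])
        assert not any(f.criterion_id == "ppo_aspirin_af" for f in screen_ppo(p, kb))

    def test_three_valued_completeness(self, kb):
        """Every omission criterion evaluates to exactly one of the three
        states for a spectrum of partially-specified patients."""
        patients_ = [
            patient(),
            patient(measurements={"sbp_mmHg": 170, "dbp_mmHg": 95, "bmd_t_score": -3.0}),
            patient(
                conditions=["heart_failure", "osteoporosis", "chronic_atrial_fibrillation"],
                vaccinations={k: False for k in ("influenza_past_year", "pneumococcal_ever_after_65", "zoster_ever", "tdap_ever")},
                end_of_life=False,
            ),
        ]
        for p in patients_:
            for crit in kb.ppo.values():
                status, missing = evaluate_ppo(p, crit, kb)
                assert status in (TRIGGERED, NOT_TRIGGERED, NOT_ASSESSABLE)
                assert (status == NOT_ASSESSABLE) == bool(missing)


class TestScreenPatient:
    def test_cross_category_example(self, kb):
        p = patient(
            meds=["cimetidine", "haloperidol"],
            conditions=["parkinson_disease", "chronic_atrial_fibrillation"],
        )
        findings, warnings = screen_patient(p, kb)
        triggered = {(f.category, f.criterion_id) for f in findings if f.status == TRIGGERED}
        assert ("INDEPENDENT_PIM", "h2_receptor_antagonists") in triggered
        assert ("DISEASE_PIM", "dp_parkinson") in triggered
        assert ("PPO", "ppo_af_anticoagulant") in triggered
        assert warnings == []

    def test_unmatched_drugs_warn_and_never_trigger(self, kb):
        p = patient(meds=["glucosamine", "unicorn tears"])
        findings, warnings = screen_patient(p, kb)
        assert not any(f.status == TRIGGERED and f.category != "PPO" for f in findings)
        assert len(warnings) == 2

    def test_deterministic_ordering(self, kb):
        p = patient(meds=["diazepam", "diclofenac"], conditions=["heart_failure", "gout"])
        f1, _ = screen_patient(p, kb)
        f2, _ = screen_patient(p, kb)
        assert f1 == f2
        keys = [({"INDEPENDENT_PIM": 0, "DISEASE_PIM": 1, "PPO": 2}[f.category], f.criterion_id) for f in f1]
        assert keys == sorted(keys)


class TestProperties:
    """Randomized monotonicity / soundness suites over seeded cohorts."""

    def _cohort(self, kb, n, seed):
        patients, _ = generate_cohort(CohortConfig(n_patients=n, seed=seed), kb)
        return patients

    def test_adding_a_medication_never_removes_pim_findings(self, kb):
        rng = np.random.default_rng(42)
        drugs = sorted(kb.lexicon.entries)
        for p in self._cohort(kb, 40, seed=9):
            before, _ = screen_patient(p, kb)
            before_pim = {
                (f.criterion_id) for f in before if f.category != "PPO" and f.status == TRIGGERED
            }
            extra = drugs[int(rng.integers(len(drugs)))]
            p.medications = p.medications + [MedicationEntry(extra)]
            after, _ = screen_patient(p, kb)
            after_pim = {
                (f.criterion_id) for f in after if f.category != "PPO" and f.status == TRIGGERED
            }
            assert before_pim <= after_pim

    def test_adding_indicated_therapy_suppresses_its_omission_flag(self, kb):
        """Supplying a criterion's indicated therapy silences that
        criterion, and the only omission flags that may newly appear are
        the medication-triggered ones the new drug itself activates
        (e.g. laxatives for a patient newly on regular opioids)."""
        rng = np.random.default_rng(7)
        ppo_crits = [c for c in kb.ppo.values() if c.final_status == "PPO" and c.indicated_therapy]
        med_triggered = {
            c.criterion_id
            for c in kb.ppo.values()
            if any(a.kind == "med" for a in c.trigger.atoms())
        }
        for p in self._cohort(kb, 40, seed=10):
            crit = ppo_crits[int(rng.integers(len(ppo_crits)))]
            therapy = crit.indicated_therapy[0]
            name = (
                therapy
                if therapy in kb.lexicon.entries
                else kb.lexicon.members_of(therapy)[0]
            )
            before = {f.criterion_id for f in screen_ppo(p, kb) if f.status == TRIGGERED}
            p.medications = p.medications + [MedicationEntry(name)]
            after = {f.criterion_id for f in screen_ppo(p, kb) if f.status == TRIGGERED}
            assert after <= before | med_triggered
            assert crit.criterion_id not in after

    def test_exception_soundness(self, kb):
        """A drug listed among a criterion's exceptions never contributes a
        finding for that criterion."""
        for crit in kb.disease.values():
            for exc in crit.drug_exceptions:
                p = patient(meds=[exc], conditions=[crit.condition_code])
                found = screen_disease(p, kb)
                for f in found:
                    if f.criterion_id == crit.criterion_id:
                        canonical = kb.lexicon.normalize_drug(exc).canonical
                        assert canonical not in f.matched_drugs


# ---------------------------------------------------------------------------
# brute-force oracle


def _oracle_screen(p, kb):
    """Naive evaluator looping over every (criterion, medication) pair with
    no shared machinery beyond name normalization."""
    resolved = []
    for med in p.medications:
        r = kb.lexicon.normalize_drug(med.raw_name)
        if r.status == "UNMATCHED":
            continue
        group = [(r.canonical, med.route or kb.lexicon.default_route(r.canonical))]
        for comp in r.components:
            group.append((comp, med.route or kb.lexicon.default_route(comp)))
        for name, route in group:
            resolved.append((name, kb.lexicon.expand_classes(name), route))

    out = set()
    for cid, crit in kb.independent.items():
        if crit.final_status != "PIM":
            continue
        matched = set()
        for name, classes, route in resolved:
            ok = crit.target in classes if crit.target_kind == "CLASS" else kb.lexicon.normalize_drug(crit.target).canonical == name
            if ok and crit.route and route and route != crit.route:
                ok = False
            if ok:
                matched.add(name)
        if matched:
            out.add((cid, "INDEPENDENT_PIM", TRIGGERED, frozenset(matched)))
    for cid, crit in kb.disease.items():
        if not kb.conditions.is_present(crit.condition_code, p.conditions):
            continue
        matched = set()
        for name, classes, route in resolved:
            if any(kb.lexicon.normalize_drug(e).canonical == name for e in crit.drug_exceptions):
                continue
            if route and route in crit.route_exceptions:
                continue
            if any(t == name or t in classes for t in crit.drug_targets):
                matched.add(name)
        if matched:
            out.add((cid, "DISEASE_PIM", TRIGGERED, frozenset(matched)))
    for cid, crit in kb.ppo.items():
        if crit.final_status != "PPO":
            continue
        status, _ = evaluate_ppo(p, crit, kb)
        if status != NOT_TRIGGERED:
            out.add((cid, "PPO", status, frozenset()))
    return out


@pytest.mark.parametrize("seed", [3, 17, 23])
def test_engine_equals_brute_force_oracle_on_small_cohorts(kb, seed):
    patients, _ = generate_cohort(CohortConfig(n_patients=20, seed=seed), kb)
    for p in patients:
        engine, _ = screen_patient(p, kb)
        engine_set = {
            (f.criterion_id, f.category, f.status, f.matched_drugs) for f in engine
        }
        assert engine_set == _oracle_screen(p, kb)


class TestSummarizeCohort:
    def test_fraction_arithmetic(self, kb):
        ps = [patient(pid=f"p{i}") for i in range(3)]
        ps[0].medications = [MedicationEntry("diazepam"), MedicationEntry("diclofenac")]
        findings = []
        for p in ps:
            f, _ = screen_patient(p, kb)
            findings.extend(f)
        s = summarize_cohort(findings, ps)
        assert s.n_patients == 3 and s.n_with_any_pim == 1
        assert s.pct_with_any_pim == pytest.approx(100 / 3)
        assert s.total_pim_findings == 2

    def test_empty_cohort_rejected(self, kb):
        with pytest.raises(DomainError):
            summarize_cohort([], [])

    def test_matches_generator_bookkeeping(self, kb):
        patients, truth = generate_cohort(CohortConfig(n_patients=50, seed=4), kb)
        findings = []
        for p in patients:
            f, _ = screen_patient(p, kb)
            findings.extend(f)
        s_engine = summarize_cohort(findings, patients)
        s_truth = summarize_cohort(truth, patients)
        assert s_engine == s_truth
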