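"""Tabular input/output and report rendering.

Patient rosters travel as two delimited text files: a medications table
(one row per patient-medication) and a patients table (demographics,
semicolon-separated condition codes, measurements, vaccination
booleans).  Reports render as plain text, versioned JSON, or delimited
summaries; all renderings of one run carry identical numbers and stable
ordering so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DomainError
from .kb import MEASUREMENT_REGISTRY, VACCINATION_REGISTRY
from .screening import CohortSummary, MedicationEntry, PatientRecord, ScreenFinding

REPORT_SCHEMA_VERSION = "1.0"

_PATIENT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "conditions",
    *MEASUREMENT_REGISTRY,
    *VACCINATION_REGISTRY,
    "end_of_life",
)
_MED_COLUMNS = ("patient_id", "raw_name", "dose_mg", "route", "chronic")


def _parse_bool(cell: str):
    cell = cell.strip().lower()
    if cell in ("", "na", "none"):
        return None
    if cell in ("true", "1", "yes"):
        return True
    if cell in ("false", "0", "no"):
        return False
    raise DomainError(f"cannot parse boolean {cell!r}")


def read_cohort(meds_path, patients_path) -> list[PatientRecord]:
    """Load a cohort from the medications and patients tables."""
    meds_path, patients_path = Path(meds_path), Path(patients_path)
    for p in (meds_path, patients_path):
        if not p.exists():
            raise FileNotFoundError(p)
    meds_df = pd.read_csv(meds_path, sep="\t", dtype=str, keep_default_na=False)
    pat_df = pd.read_csv(patients_path, sep="\t", dtype=str, keep_default_na=False)

    meds_by_patient: dict[str, list] = {}
    for _, row in meds_df.iterrows():
        entry = MedicationEntry(
            raw_name=row["raw_name"],
            dose_mg=float(row["dose_mg"]) if row.get("dose_mg", "").strip() else None,
            route=row.get("route", "").strip() or None,
            chronic=_parse_bool(row.get("chronic", "")),
        )
        meds_by_patient.setdefault(row["patient_id"], []).append(entry)

    patients = []
    for _, row in pat_df.iterrows():
        measurements = {
            k: float(row[k]) for k in MEASUREMENT_REGISTRY if row.get(k, "").strip()
        }
        vaccinations = {
            k: v
            for k in VACCINATION_REGISTRY
            if (v := _parse_bool(row.get(k, ""))) is not None
        }
        patients.append(
            PatientRecord(
                patient_id=row["patient_id"],
                age_years=int(row["age_years"]),
                sex=row.get("sex", "").strip() or None,
                medications=meds_by_patient.get(row["patient_id"], []),
                conditions={c.strip() for c in row.get("conditions", "").split(";") if c.strip()},
                measurements=measurements,
                vaccinations=vaccinations,
                end_of_life=_parse_bool(row.get("end_of_life", "")),
            )
        )
    return patients


def write_cohort(patients: Iterable[PatientRecord], meds_path, patients_path) -> None:
    """Write a cohort in exactly the format :func:`read_cohort` accepts."""
    med_rows, pat_rows = [], []
    for p in patients:
        for m in p.medications:
            med_rows.append(
                {
                    "patient_id": p.patient_id,
                    "raw_name": m.raw_name,
                    "dose_mg": "" if m.dose_mg is None else m.dose_mg,
                    "route": m.route or "",
                    "chronic": "" if m.chronic is None else str(m.chronic).lower(),
                }
            )
        row = {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "sex": p.sex or "",
            "conditions": ";".join(sorted(p.conditions)),
            "end_of_life": "" if p.end_of_life is None else str(p.end_of_life).lower(),
        }
        for k in MEASUREMENT_REGISTRY:
            row[k] = "" if p.measurements.get(k) is None else p.measurements[k]
        for k in VACCINATION_REGISTRY:
            v = p.vaccinations.get(k)
            row[k] = "" if v is None else str(v).lower()
        pat_rows.append(row)
    pd.DataFrame(med_rows, columns=_MED_COLUMNS).to_csv(meds_path, sep="\t", index=False)
    pd.DataFrame(pat_rows, columns=_PATIENT_COLUMNS).to_csv(patients_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report rendering


def _summary_dict(summary: CohortSummary) -> dict:
    return {
        "n_patients": summary.n_patients,
        "n_with_any_pim": summary.n_with_any_pim,
        "pct_with_any_pim": round(summary.pct_with_any_pim, 1),
        "total_pim_findings": summary.total_pim_findings,
        "total_ppo_findings": summary.total_ppo_findings,
        "n_not_assessable": summary.n_not_assessable,
        "per_criterion_counts": [list(kv) for kv in summary.per_criterion_counts],
        "top_drugs": [list(kv) for kv in summary.top_drugs],
    }


def _finding_dict(f: ScreenFinding) -> dict:
    return {
        "patient_id": f.patient_id,
        "criterion_id": f.criterion_id,
        "category": f.category,
        "status": f.status,
        "matched_drugs": sorted(f.matched_drugs),
        "condition_code": f.condition_code,
        "missing_attributes": sorted(f.missing_attributes),
        "practice_statement_ref": f.practice_statement_ref,
    }


def render_report(
    findings: Iterable[ScreenFinding], summary: CohortSummary, format: str = "text"
) -> str:
    """Render per-patient findings plus the cohort section."""
    findings = list(findings)
    if format == "json":
        return json.dumps(
            {
                "schema_version": REPORT_SCHEMA_VERSION,
                "cohort": _summary_dict(summary),
                "findings": [_finding_dict(f) for f in findings],
            },
            indent=2,
            sort_keys=False,
        )
    if format == "delimited":
        rows = [
            "patient_id\tcriterion_id\tcategory\tstatus\tmatched_drugs\tcondition_code\tmissing_attributes"
        ]
        for f in findings:
            rows.append(
                "\t".join(
                    [
                        f.patient_id,
                        f.criterion_id,
                        f.category,
                        f.status,
                        "|".join(sorted(f.matched_drugs)),
                        f.condition_code or "",
                        "|".join(sorted(f.missing_attributes)),
                    ]
                )
            )
        return "\n".join(rows) + "\n"
    if format != "text":
        raise DomainError(f"unknown report format {format!r}")

    lines = ["Cohort screening report", "======================="]
    s = _summary_dict(summary)
    lines.append(f"patients screened      : {s['n_patients']}")
    lines.append(
        f"with >=1 PIM triggered : {s['n_with_any_pim']} ({s['pct_with_any_pim']}%)"
    )
    lines.append(f"PIM findings (total)   : {s['total_pim_findings']}")
    lines.append(f"PPO findings (total)   : {s['total_ppo_findings']}")
    lines.append(f"not assessable         : {s['n_not_assessable']}")
    if s["top_drugs"]:
        lines.append("top implicated drugs   :")
        for drug, count in s["top_drugs"][:10]:
            lines.append(f"  {drug:<32s} n={count}")
    lines.append("")
    by_patient: dict[str, list] = {}
    for f in findings:
        by_patient.setdefault(f.patient_id, []).append(f)
    for pid in sorted(by_patient):
        lines.append(f"Patient {pid}")
        for f in by_patient[pid]:
            extra = ""
            if f.matched_drugs:
                extra = " [" + ", ".join(sorted(f.matched_drugs)) + "]"
            if f.missing_attributes:
                extra = " missing: " + ", ".join(sorted(f.missing_attributes))
            ref = f" ({f.practice_statement_ref})" if f.practice_statement_ref else ""
            lines.append(f"  {f.status:<14s} {f.category:<15s} {f.criterion_id}{extra}{ref}")
    return "\n".join(lines) + "\n"
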