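"""Machine-readable knowledge base of the prescribing criteria.

Three criterion families are shipped as delimited-text fixtures
transcribed at printed precision: medication criteria independent of
disease (with the per-round Delphi provenance that produced each final
label), disease-conditional criteria, and prescribing-omission
statements.  Loading cross-links every criterion against the drug
lexicon and the condition vocabulary and fails loudly on dangling
references.

Omission triggers and exceptions use a small predicate language in
disjunctive normal form: ``;``-separated alternatives, each a ``&``-joined
conjunction of atoms::

    cond:<code>            condition present (vocabulary-aware)
    med:<drug-or-class>    a current medication is / belongs to this
    meas:<key><op><num>    measurement comparison (>, >=, <, <=)
    vacc:<key>=true|false  vaccination-history flag
    flag:end_of_life       end-of-life status
    age<op><num>           patient age comparison

Atoms over absent optional attributes evaluate to *unknown* and
propagate by Kleene three-valued logic, which is what lets the screening
engine distinguish "not indicated" from "cannot assess".
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .consensus import AdjudicationRecord, DelphiItem, FinalLabel, RoundSummary
from .errors import KBLoadError, LinkingError
from .lexicon import Lexicon, LexiconEntry

__all__ = [
    "CriterionIndependentPIM",
    "CriterionDiseasePIM",
    "CriterionPPO",
    "ConditionVocabulary",
    "KnowledgeBase",
    "Predicate",
    "TriState",
    "load_kb",
    "kb_counts",
    "lint_kb",
    "query",
]

MEASUREMENT_REGISTRY = ("sbp_mmHg", "dbp_mmHg", "bmd_t_score")
VACCINATION_REGISTRY = (
    "influenza_past_year",
    "pneumococcal_ever_after_65",
    "zoster_ever",
    "tdap_ever",
)
ROUTE_TAGS = ("oral", "topical", "transdermal", "parenteral", "intra-articular", "inhaled", "vaginal")


class TriState(enum.Enum):
    TRUE = "TRUE"
    FALSE = "FALSE"
    UNKNOWN = "UNKNOWN"


# ---------------------------------------------------------------------------
# Predicate mini-language (DNF with three-valued atoms)

_ATOM_RE = re.compile(
    r"^(?:"
    r"cond:(?P<cond>[a-z0-9_]+)"
    r"|med:(?P<med>[a-z0-9 &/'().-]+)"
    r"|meas:(?P<mkey>[A-Za-z_]+)(?P<mop>>=|<=|>|<)(?P<mval>-?\d+(?:\.\d+)?)"
    r"|vacc:(?P<vkey>[a-z0-9_]+)=(?P<vval>true|false)"
    r"|flag:(?P<flag>end_of_life)"
    r"|age(?P<aop>>=|<=|>|<)(?P<aval>\d+)"
    r")$"
)

_OPS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
}


@dataclass(frozen=True)
class Atom:
    kind: str  # cond | med | meas | vacc | flag | age
    key: str
    op: Optional[str] = None
    value: object = None

    @property
    def attribute(self) -> str:
        """Name reported in missing_attributes when this atom is unknown."""
        return self.key if self.kind in ("meas", "vacc") else (
            "end_of_life" if self.kind == "flag" else self.key
        )


@dataclass(frozen=True)
class Predicate:
    """A parsed DNF predicate: any conjunction true makes it true."""

    source: str
    disjuncts: tuple  # tuple of tuples of Atom

    @classmethod
    def parse(cls, text: str) -> "Predicate":
        text = (text or "").strip()
        if not text:
            return cls("", ())
        disjuncts = []
        for clause in text.split(";"):
            atoms = []
            for raw in clause.split("&"):
                raw = raw.strip()
                m = _ATOM_RE.match(raw)
                if not m:
                    raise KBLoadError(f"unparseable predicate atom {raw!r} in {text!r}")
                g = m.groupdict()
                if g["cond"]:
                    atoms.append(Atom("cond", g["cond"]))
                elif g["med"]:
                    atoms.append(Atom("med", g["med"].strip()))
                elif g["mkey"]:
                    atoms.append(Atom("meas", g["mkey"], g["mop"], float(g["mval"])))
                elif g["vkey"]:
                    atoms.append(Atom("vacc", g["vkey"], "=", g["vval"] == "true"))
                elif g["flag"]:
                    atoms.append(Atom("flag", g["flag"]))
                else:
                    atoms.append(Atom("age", "age_years", g["aop"], float(g["aval"])))
            disjuncts.append(tuple(atoms))
        return cls(text, tuple(disjuncts))

    @property
    def is_empty(self) -> bool:
        return not self.disjuncts

    def atoms(self):
        for clause in self.disjuncts:
            yield from clause

    def referenced_attributes(self) -> set:
        return {a.attribute for a in self.atoms()}


# ---------------------------------------------------------------------------
# Criterion types


class Category(str, enum.Enum):
    INDEPENDENT_PIM = "INDEPENDENT_PIM"
    DISEASE_PIM = "DISEASE_PIM"
    PPO = "PPO"


@dataclass(frozen=True)
class CriterionIndependentPIM:
    criterion_id: str
    atc_group: str
    target: str
    target_kind: str  # DRUG | CLASS
    final_status: str  # PIM | NOT_PIM
    route: Optional[str] = None
    practice_statement: str = ""
    footnotes: frozenset = frozenset()


@dataclass(frozen=True)
class CriterionDiseasePIM:
    criterion_id: str
    section: str
    condition_code: str
    drug_targets: tuple
    exceptions: tuple = ()  # drug names or 'route:<tag>'
    qualifier_notes: str = ""

    @property
    def drug_exceptions(self) -> tuple:
        return tuple(e for e in self.exceptions if not e.startswith("route:"))

    @property
    def route_exceptions(self) -> tuple:
        return tuple(e.split(":", 1)[1] for e in self.exceptions if e.startswith("route:"))


@dataclass(frozen=True)
class CriterionPPO:
    criterion_id: str
    domain: str
    trigger: Predicate
    indicated_therapy: tuple
    exception: Predicate
    final_status: str  # PPO | NOT_PPO
    notes: str = ""


@dataclass(frozen=True)
class Condition:
    code: str
    display_name: str
    synonyms: frozenset = frozenset()
    any_of: tuple = ()
    all_of: tuple = ()


class ConditionVocabulary:
    """Flat controlled vocabulary of condition codes with synonym lookup
    and derived (any-of / all-of) composite codes."""

    def __init__(self, conditions: list[Condition]):
        self.conditions = {c.code: c for c in conditions}
        if len(self.conditions) != len(conditions):
            raise KBLoadError("duplicate condition codes")
        self._index = {}
        for c in conditions:
            for alias in {c.code, c.display_name.casefold(), *c.synonyms}:
                self._index[alias.casefold().strip()] = c.code
        for c in conditions:
            for ref in (*c.any_of, *c.all_of):
                if ref not in self.conditions:
                    raise LinkingError(f"condition {c.code}: unknown component {ref!r}")

    def __contains__(self, code: str) -> bool:
        return code in self.conditions

    def resolve(self, text: str) -> Optional[str]:
        return self._index.get(text.casefold().strip())

    def is_present(self, code: str, patient_codes: set) -> bool:
        """Composite-aware presence test."""
        if code in patient_codes:
            return True
        cond = self.conditions.get(code)
        if cond is None:
            return False
        if cond.any_of:
            return any(self.is_present(c, patient_codes) for c in cond.any_of)
        if cond.all_of:
            return all(self.is_present(c, patient_codes) for c in cond.all_of)
        return False


# ---------------------------------------------------------------------------
# Knowledge base


@dataclass
class KnowledgeBase:
    independent: dict
    disease: dict
    ppo: dict
    lexicon: Lexicon
    conditions: ConditionVocabulary
    provenance: dict  # item_id -> (DelphiItem, FinalLabel printed)
    allowlist: dict  # item_id -> reason

    def criteria(self):
        yield from self.independent.values()
        yield from self.disease.values()
        yield from self.ppo.values()

    def delphi_items(self, category: str) -> list:
        """DelphiItems of one provenance category in stable id order."""
        prefix_is_ppo = category == Category.PPO.value
        out = []
        for item_id, (item, _printed) in sorted(self.provenance.items()):
            is_ppo = item_id in self.ppo or item_id.startswith("ppo_")
            if is_ppo == prefix_is_ppo:
                out.append(item)
        return out


def _read_tsv(path: Path, name: str) -> pd.DataFrame:
    fp = path / name
    if not fp.exists():
        raise KBLoadError(f"missing fixture file {fp}")
    try:
        df = pd.read_csv(fp, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise KBLoadError(f"cannot parse {fp}: {exc}") from exc
    return df


def _split(cell: str) -> tuple:
    return tuple(s.strip() for s in cell.split("|") if s.strip()) if cell else ()


def default_kb_path() -> Path:
    return Path(resources.files("malpip") / "data")


def load_kb(path=None) -> KnowledgeBase:
    """Load and cross-link the knowledge base from a fixture directory
    (the packaged criteria when ``path`` is omitted)."""
    path = Path(path) if path is not None else default_kb_path()
    if not path.is_dir():
        raise KBLoadError(f"knowledge-base directory {path} does not exist")

    lex_df = _read_tsv(path, "lexicon.tsv")
    entries = [
        LexiconEntry(
            canonical_name=row["canonical"].strip(),
            synonyms=frozenset(_split(row["synonyms"])),
            class_memberships=frozenset(_split(row["classes"])),
            combination_components=_split(row["components"]),
            default_route=row["route"].strip() or None,
        )
        for _, row in lex_df.iterrows()
    ]
    lexicon = Lexicon(entries)

    cond_df = _read_tsv(path, "conditions.tsv")
    vocabulary = ConditionVocabulary(
        [
            Condition(
                code=row["condition_code"].strip(),
                display_name=row["display_name"].strip(),
                synonyms=frozenset(_split(row["synonyms"])),
                any_of=_split(row["any_of"]),
                all_of=_split(row["all_of"]),
            )
            for _, row in cond_df.iterrows()
        ]
    )

    # provenance -----------------------------------------------------------
    items_df = _read_tsv(path, "delphi_items.tsv")
    rounds_df = _read_tsv(path, "delphi_rounds.tsv")
    adj_df = _read_tsv(path, "adjudications.tsv")
    allow_df = _read_tsv(path, "allowlist.tsv")
    allowlist = {r["item_id"]: r["reason"] for _, r in allow_df.iterrows()}

    rounds: dict[tuple[str, int], RoundSummary] = {}
    for _, row in rounds_df.iterrows():
        rnd = int(row["round"])
        summary = RoundSummary(
            row["item_id"], rnd, float(row["mean"]), float(row["ci_low"]), float(row["ci_high"])
        ).validate()
        key = (row["item_id"], rnd)
        if key in rounds:
            raise KBLoadError(f"duplicate round row for {key}")
        rounds[key] = summary

    adjudications = {}
    for _, row in adj_df.iterrows():
        votes = int(row["votes_positive"]) if row["votes_positive"].strip() else None
        outcome = FinalLabel(row["outcome"]) if row["outcome"].strip() else None
        adjudications[row["item_id"]] = AdjudicationRecord(
            row["item_id"], int(row["panel_size"]), votes, outcome
        )

    provenance: dict[str, tuple[DelphiItem, FinalLabel]] = {}
    footnotes_by_item: dict[str, frozenset] = {}
    for _, row in items_df.iterrows():
        item_id = row["item_id"]
        if item_id in provenance:
            raise KBLoadError(f"duplicate provenance item {item_id}")
        proposed = row["proposed_round2"].strip() == "1"
        footnotes = frozenset(s.strip() for s in row["footnotes"].split(",") if s.strip())
        item = DelphiItem(
            item_id,
            round1=rounds.get((item_id, 1)),
            round2=rounds.get((item_id, 2)),
            proposed_round2=proposed,
            adjudication=adjudications.get(item_id),
            allowlist_label=FinalLabel(row["printed_decision"]) if item_id in allowlist else None,
        )
        provenance[item_id] = (item, FinalLabel(row["printed_decision"]))
        footnotes_by_item[item_id] = footnotes

    # criteria --------------------------------------------------------------
    ind_df = _read_tsv(path, "independent_pim.tsv")
    independent = {}
    for _, row in ind_df.iterrows():
        cid = row["criterion_id"]
        crit = CriterionIndependentPIM(
            criterion_id=cid,
            atc_group=row["atc_group"],
            target=row["target"].strip(),
            target_kind=row["target_kind"],
            final_status=row["final_status"],
            route=row["route"].strip() or None,
            practice_statement=row["practice_statement"].strip(),
            footnotes=footnotes_by_item.get(cid, frozenset()),
        )
        if cid in independent:
            raise KBLoadError(f"duplicate criterion id {cid}")
        independent[cid] = crit

    dis_df = _read_tsv(path, "disease_pim.tsv")
    disease = {}
    for _, row in dis_df.iterrows():
        cid = row["criterion_id"]
        if cid in disease:
            raise KBLoadError(f"duplicate criterion id {cid}")
        disease[cid] = CriterionDiseasePIM(
            criterion_id=cid,
            section=row["section"],
            condition_code=row["condition_code"],
            drug_targets=_split(row["drug_targets"]),
            exceptions=_split(row["exceptions"]),
            qualifier_notes=row["qualifier_notes"],
        )

    ppo_df = _read_tsv(path, "ppo.tsv")
    ppo = {}
    for _, row in ppo_df.iterrows():
        cid = row["criterion_id"]
        if cid in ppo:
            raise KBLoadError(f"duplicate criterion id {cid}")
        ppo[cid] = CriterionPPO(
            criterion_id=cid,
            domain=row["domain"],
            trigger=Predicate.parse(row["trigger"]),
            indicated_therapy=_split(row["indicated"]),
            exception=Predicate.parse(row["exception"]),
            final_status=row["final_status"],
            notes=row["notes"],
        )

    kb = KnowledgeBase(independent, disease, ppo, lexicon, vocabulary, provenance, allowlist)
    _link_check(kb)
    return kb


def _link_check(kb: KnowledgeBase) -> None:
    """Hard linking errors: dangling drug/class/condition references."""
    problems = []
    for crit in kb.independent.values():
        if crit.target_kind == "CLASS":
            if crit.target not in kb.lexicon.all_classes:
                problems.append(f"{crit.criterion_id}: unknown class {crit.target!r}")
        elif kb.lexicon.normalize_drug(crit.target).status == "UNMATCHED":
            problems.append(f"{crit.criterion_id}: unknown drug {crit.target!r}")
    for crit in kb.disease.values():
        if crit.condition_code not in kb.conditions:
            problems.append(f"{crit.criterion_id}: unknown condition {crit.condition_code!r}")
        for t in crit.drug_targets:
            if not kb.lexicon.resolves(t):
                problems.append(f"{crit.criterion_id}: unresolvable target {t!r}")
        for e in crit.drug_exceptions:
            if kb.lexicon.normalize_drug(e).status == "UNMATCHED":
                problems.append(f"{crit.criterion_id}: unresolvable exception {e!r}")
        for r in crit.route_exceptions:
            if r not in ROUTE_TAGS:
                problems.append(f"{crit.criterion_id}: unknown route tag {r!r}")
    for crit in kb.ppo.values():
        for t in crit.indicated_therapy:
            if not kb.lexicon.resolves(t):
                problems.append(f"{crit.criterion_id}: unresolvable therapy {t!r}")
        for pred in (crit.trigger, crit.exception):
            for atom in pred.atoms():
                if atom.kind == "cond" and atom.key not in kb.conditions:
                    problems.append(f"{crit.criterion_id}: unknown condition {atom.key!r}")
                elif atom.kind == "meas" and atom.key not in MEASUREMENT_REGISTRY:
                    problems.append(f"{crit.criterion_id}: unknown measurement {atom.key!r}")
                elif atom.kind == "vacc" and atom.key not in VACCINATION_REGISTRY:
                    problems.append(f"{crit.criterion_id}: unknown vaccination {atom.key!r}")
                elif atom.kind == "med" and not kb.lexicon.resolves(atom.key):
                    problems.append(f"{crit.criterion_id}: unresolvable med atom {atom.key!r}")
    if problems:
        raise LinkingError("; ".join(problems))


def kb_counts(kb: KnowledgeBase) -> dict:
    """Census of the knowledge base by family and final status."""
    independent_pim = sum(1 for c in kb.independent.values() if c.final_status == "PIM")
    independent_not = sum(1 for c in kb.independent.values() if c.final_status == "NOT_PIM")
    ppo = sum(1 for c in kb.ppo.values() if c.final_status == "PPO")
    not_ppo = sum(1 for c in kb.ppo.values() if c.final_status == "NOT_PPO")
    return {
        "independent_pim": independent_pim,
        "independent_not_pim": independent_not,
        "disease_criteria": len(kb.disease),
        "ppo": ppo,
        "not_ppo": not_ppo,
        "candidates_total": len(kb.independent) + len(kb.disease) + len(kb.ppo),
    }


def lint_kb(kb: KnowledgeBase) -> list:
    """Soft invariant checks; returns a list of violation strings (empty on
    the shipped fixtures).  Linking errors are raised at load time; this
    covers cross-file consistency that should fail a release gate."""
    violations = []
    for crit in kb.independent.values():
        if crit.final_status == "PIM" and not crit.practice_statement:
            violations.append(f"{crit.criterion_id}: PIM without practice statement reference")
        if crit.criterion_id not in kb.provenance:
            violations.append(f"{crit.criterion_id}: no provenance")
    for crit in kb.ppo.values():
        if crit.criterion_id not in kb.provenance:
            violations.append(f"{crit.criterion_id}: no provenance")
    not_ppo = [c.criterion_id for c in kb.ppo.values() if c.final_status == "NOT_PPO"]
    if len(not_ppo) != 1:
        violations.append(f"expected exactly one NOT_PPO criterion, found {not_ppo}")
    for item_id in kb.provenance:
        if item_id not in kb.independent and item_id not in kb.ppo:
            violations.append(f"provenance item {item_id} has no criterion")
    for item_id in kb.allowlist:
        if item_id not in kb.provenance:
            violations.append(f"allowlist entry {item_id} has no provenance")
    return violations


def query(
    kb: KnowledgeBase,
    category: Optional[str] = None,
    atc_group: Optional[str] = None,
    condition: Optional[str] = None,
    drug: Optional[str] = None,
) -> list:
    """Criteria matching every given facet.

    The drug facet matches independent criteria whose target the drug is
    or whose target class the drug belongs to, disease criteria listing
    it (directly or via class), and omission criteria naming it as
    indicated therapy.  Unknown facet values yield an empty result.
    """
    results = []
    norm = kb.lexicon.normalize_drug(drug) if drug else None
    drug_classes = norm.classes if norm and norm.status != "UNMATCHED" else frozenset()
    cond_code = kb.conditions.resolve(condition) if condition else None

    def drug_matches(target: str) -> bool:
        if norm is None or norm.status == "UNMATCHED":
            return False
        return (
            target == norm.canonical
            or target in drug_classes
            or target in norm.components
        )

    for crit in kb.criteria():
        if category and getattr(Category, category, None) is not _category_of(crit):
            continue
        if atc_group:
            if not isinstance(crit, CriterionIndependentPIM) or crit.atc_group != atc_group:
                continue
        if cond_code is not None or condition:
            code = getattr(crit, "condition_code", None)
            trigger_conds = (
                {a.key for a in crit.trigger.atoms() if a.kind == "cond"}
                if isinstance(crit, CriterionPPO)
                else set()
            )
            if cond_code is None or (code != cond_code and cond_code not in trigger_conds):
                continue
        if drug:
            if isinstance(crit, CriterionIndependentPIM):
                if not drug_matches(crit.target):
                    continue
            elif isinstance(crit, CriterionDiseasePIM):
                if not any(drug_matches(t) for t in crit.drug_targets):
                    continue
            else:
                if not any(drug_matches(t) for t in crit.indicated_therapy):
                    continue
        results.append(crit)
    return results


def _category_of(crit) -> Category:
    if isinstance(crit, CriterionIndependentPIM):
        return Category.INDEPENDENT_PIM
    if isinstance(crit, CriterionDiseasePIM):
        return Category.DISEASE_PIM
    return Category.PPO
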