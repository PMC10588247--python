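"""Delphi consensus machinery.

Implements the two-round expert-panel decision process used to build the
criteria lists: per-item Likert summaries (mean with 95% CI), the
confidence-interval consensus rule, percent-agreement thresholds,
majority-vote adjudication for residual undecided items, and the
round-stability statistics (Kendall's W with tie correction, coefficient
of variation).

Likert orientation is fixed throughout: 1 = "definitely PIM" (or
"definitely should be started" for omission statements) and 5 =
"definitely not".  An item reaches positive consensus when the upper
bound of the 95% CI of its mean rating lies strictly below 3.0, negative
consensus when the lower bound lies strictly above 3.0, and is otherwise
undecided and re-asked in the next round.  Items still undecided after
the final round are resolved by a strict-majority vote of a six-member
geriatrician panel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .errors import (
    DomainError,
    InsufficientDataError,
    InvalidSummaryError,
    UnresolvedItemError,
)

__all__ = [
    "ConsensusDecision",
    "FinalLabel",
    "LikertRating",
    "RoundSummary",
    "AdjudicationRecord",
    "DelphiItem",
    "DecisionPath",
    "DelphiTally",
    "StabilityReport",
    "classify_item",
    "summarize_ratings",
    "min_agree",
    "agreement_consensus",
    "adjudicate",
    "run_delphi",
    "kendalls_w",
    "round_cv",
    "stability_report",
    "check_kb_consistency",
    "ConsistencyReport",
]

CONSENSUS_THRESHOLD = 3.0
ADJUDICATION_PANEL_SIZE = 6
AGREEMENT_FRACTION = 0.80
CV_ACCEPTABLE_LIMIT = 0.25


class ConsensusDecision(str, enum.Enum):
    CONSENSUS_POSITIVE = "CONSENSUS_POSITIVE"
    CONSENSUS_NEGATIVE = "CONSENSUS_NEGATIVE"
    UNDECIDED = "UNDECIDED"


class FinalLabel(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class LikertRating:
    """A single expert rating of one item on the 1-5 scale."""

    item_id: str
    rater_id: str
    score: int

    def __post_init__(self):
        if self.score not in (1, 2, 3, 4, 5):
            raise DomainError(f"Likert score must be 1..5, got {self.score!r}")


@dataclass(frozen=True)
class RoundSummary:
    """Per-item, per-round mean rating with its 95% confidence interval."""

    item_id: str
    round: int
    mean: float
    ci_low: float
    ci_high: float
    n_raters: Optional[int] = None

    def validate(self) -> "RoundSummary":
        vals = (self.mean, self.ci_low, self.ci_high)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidSummaryError(f"{self.item_id}: non-finite summary {vals}")
        if self.ci_low > self.ci_high:
            raise InvalidSummaryError(
                f"{self.item_id}: inverted interval [{self.ci_low}, {self.ci_high}]"
            )
        return self


def classify_item(summary: RoundSummary, threshold: float = CONSENSUS_THRESHOLD) -> ConsensusDecision:
    """Apply the CI consensus rule to one round summary.

    Positive consensus iff the CI upper bound is strictly below the
    threshold; negative consensus iff the lower bound is strictly above
    it; undecided otherwise (bounds on both sides, or touching the
    threshold exactly).
    """
    summary.validate()
    if summary.ci_high < threshold:
        return ConsensusDecision.CONSENSUS_POSITIVE
    if summary.ci_low > threshold:
        return ConsensusDecision.CONSENSUS_NEGATIVE
    return ConsensusDecision.UNDECIDED


def summarize_ratings(
    ratings: Sequence,
    item_id: str = "",
    round: int = 1,
    ci_method: str = "t",
) -> RoundSummary:
    """Mean and two-sided 95% CI for one item's ratings.

    ``ratings`` may be integers or :class:`LikertRating` objects.  The
    default interval is the t-interval on n-1 degrees of freedom; a
    normal (z) interval is available via ``ci_method="normal"``.  Zero
    variance collapses the interval onto the mean.
    """
    scores = np.asarray(
        [r.score if isinstance(r, LikertRating) else r for r in ratings], dtype=float
    )
    if scores.size < 2:
        raise InsufficientDataError("need at least 2 ratings to summarize")
    n = scores.size
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        half = 0.0
    else:
        sem = sd / math.sqrt(n)
        if ci_method == "t":
            q = float(_stats.t.ppf(0.975, n - 1))
        elif ci_method == "normal":
            q = float(_stats.norm.ppf(0.975))
        else:
            raise DomainError(f"unknown ci_method {ci_method!r}")
        half = q * sem
    return RoundSummary(item_id, round, mean, mean - half, mean + half, n_raters=n)


def min_agree(panel_size: int, fraction: float = AGREEMENT_FRACTION) -> int:
    """Smallest number of panellists whose agreement meets the fraction."""
    if panel_size <= 0:
        raise DomainError("panel_size must be positive")
    if not (0 < fraction <= 1):
        raise DomainError("fraction must be in (0, 1]")
    return math.ceil(fraction * panel_size - 1e-12)


def agreement_consensus(n_agree: int, panel_size: int, fraction: float = AGREEMENT_FRACTION) -> bool:
    """Percent-agreement rule used for the disease-specific lists."""
    if not (0 <= n_agree <= panel_size):
        raise DomainError(f"n_agree must be in [0, {panel_size}], got {n_agree}")
    return n_agree >= min_agree(panel_size, fraction)


@dataclass(frozen=True)
class AdjudicationRecord:
    """Majority-vote resolution of an item left undecided after the rounds.

    Either an explicit vote tally or a recorded outcome (when the source
    reports only the decision) must be present; if both are given they
    must agree.
    """

    item_id: str
    panel_size: int = ADJUDICATION_PANEL_SIZE
    votes_positive: Optional[int] = None
    outcome: Optional[FinalLabel] = None

    def resolve(self) -> FinalLabel:
        if self.votes_positive is not None:
            label = adjudicate(self)
            if self.outcome is not None and label is not self.outcome:
                raise DomainError(
                    f"{self.item_id}: vote tally {self.votes_positive}/{self.panel_size} "
                    f"contradicts recorded outcome {self.outcome.value}"
                )
            return label
        if self.outcome is not None:
            return self.outcome
        raise UnresolvedItemError([self.item_id])


def adjudicate(vote: AdjudicationRecord) -> FinalLabel:
    """Strict majority (> 50%) of the adjudication panel; ties are negative."""
    if vote.panel_size <= 0:
        raise DomainError("panel_size must be positive")
    if vote.votes_positive is None or not (0 <= vote.votes_positive <= vote.panel_size):
        raise DomainError(
            f"votes_positive must be in [0, {vote.panel_size}], got {vote.votes_positive}"
        )
    if vote.votes_positive / vote.panel_size > 0.5:
        return FinalLabel.POSITIVE
    return FinalLabel.NEGATIVE


@dataclass(frozen=True)
class DelphiItem:
    """Everything known about one candidate item entering the pipeline."""

    item_id: str
    round1: Optional[RoundSummary] = None
    round2: Optional[RoundSummary] = None
    proposed_round2: bool = False
    adjudication: Optional[AdjudicationRecord] = None
    allowlist_label: Optional[FinalLabel] = None


@dataclass(frozen=True)
class DecisionPath:
    """The decision trajectory of one item through the pipeline."""

    item_id: str
    round1: Optional[ConsensusDecision]
    round2: Optional[ConsensusDecision]
    adjudicated: bool
    adjudication_votes: Optional[int]
    final_label: FinalLabel
    allowlisted: bool = False


@dataclass
class DelphiTally:
    positive: int = 0
    negative: int = 0
    round1_positive: int = 0
    round1_negative: int = 0
    undecided_after_r1: int = 0
    assessed_r2: int = 0
    round2_positive: int = 0
    adjudicated: int = 0
    allowlisted: int = 0


def run_delphi(
    items: Iterable[DelphiItem], threshold: float = CONSENSUS_THRESHOLD
) -> tuple[list[DecisionPath], DelphiTally]:
    """Run every item through the round-1 / round-2 / adjudication pipeline.

    Items proposed after round 1 enter at round 2.  An item undecided
    after its last available round must carry an adjudication record;
    otherwise it must be on the known-anomaly allowlist (its published
    label is carried and flagged) or an :class:`UnresolvedItemError` is
    raised naming it.
    """
    paths: list[DecisionPath] = []
    tally = DelphiTally()
    unresolved: list[str] = []

    for item in items:
        d1: Optional[ConsensusDecision] = None
        d2: Optional[ConsensusDecision] = None
        adjudicated = False
        votes = None
        allowlisted = False
        final: Optional[FinalLabel] = None

        if item.round1 is None and not item.proposed_round2:
            raise DomainError(f"{item.item_id}: no round-1 summary and not flagged as proposed")

        if item.round1 is not None:
            d1 = classify_item(item.round1, threshold)
            if d1 is ConsensusDecision.CONSENSUS_POSITIVE:
                tally.round1_positive += 1
                final = FinalLabel.POSITIVE
            elif d1 is ConsensusDecision.CONSENSUS_NEGATIVE:
                tally.round1_negative += 1
                final = FinalLabel.NEGATIVE
            else:
                tally.undecided_after_r1 += 1

        if final is None:
            if item.round2 is not None:
                tally.assessed_r2 += 1
                d2 = classify_item(item.round2, threshold)
                if d2 is ConsensusDecision.CONSENSUS_POSITIVE:
                    tally.round2_positive += 1
                    final = FinalLabel.POSITIVE
                elif d2 is ConsensusDecision.CONSENSUS_NEGATIVE:
                    final = FinalLabel.NEGATIVE

            if final is None:
                if item.adjudication is not None:
                    adjudicated = True
                    votes = item.adjudication.votes_positive
                    tally.adjudicated += 1
                    final = item.adjudication.resolve()
                elif item.allowlist_label is not None:
                    allowlisted = True
                    tally.allowlisted += 1
                    final = item.allowlist_label
                else:
                    unresolved.append(item.item_id)
                    continue

        if final is FinalLabel.POSITIVE:
            tally.positive += 1
        else:
            tally.negative += 1
        paths.append(
            DecisionPath(item.item_id, d1, d2, adjudicated, votes, final, allowlisted)
        )

    if unresolved:
        raise UnresolvedItemError(unresolved)
    return paths, tally


# ---------------------------------------------------------------------------
# Round-stability statistics


def kendalls_w(ratings) -> float:
    """Kendall's coefficient of concordance W over a raters x items matrix.

    Ranks are assigned within each rater with midranks for ties and the
    standard tie-correction term is subtracted from the denominator:

        W = 12 S / (m^2 (n^3 - n) - m sum_i T_i)

    where S is the sum of squared deviations of the item rank sums from
    their mean and T_i = sum over tie groups of (t^3 - t) for rater i.
    A matrix in which every rater ties all items carries no ordering
    information; it is returned as perfect (trivial) concordance, W = 1.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DomainError("need at least 2 raters and 2 items")
    m, n = X.shape
    ranks = np.apply_along_axis(_stats.rankdata, 1, X)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for i in range(m):
        _, counts = np.unique(X[i], return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom == 0:
        return 1.0
    w = 12.0 * s / denom
    # clamp tiny negative round-off
    return float(min(max(w, 0.0), 1.0))


def round_cv(ratings) -> float:
    """Mean per-item coefficient of variation (sample SD over mean)."""
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("need at least 2 raters")
    means = X.mean(axis=0)
    if np.any(means <= 0):
        raise DomainError("all item means must be positive for a CV")
    cvs = X.std(axis=0, ddof=1) / means
    return float(cvs.mean())


@dataclass(frozen=True)
class StabilityReport:
    round: int
    kendalls_w: float
    cv: float

    @property
    def cv_acceptable(self) -> bool:
        return self.cv <= CV_ACCEPTABLE_LIMIT


def stability_report(ratings, round: int = 1) -> StabilityReport:
    return StabilityReport(round, kendalls_w(ratings), round_cv(ratings))


# ---------------------------------------------------------------------------
# Knowledge-base consistency


@dataclass
class ConsistencyReport:
    matches: list = field(default_factory=list)
    allowlisted: list = field(default_factory=list)  # (item_id, derived, printed, reason)
    mismatches: list = field(default_factory=list)  # (item_id, derived, printed)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def _derive_strict(item: DelphiItem, threshold: float) -> str:
    """Label the strict pipeline derives for one item, 'UNRESOLVED' when it
    cannot decide (undecided after the last round with no adjudication)."""
    stripped = DelphiItem(
        item.item_id,
        item.round1,
        item.round2,
        item.proposed_round2,
        item.adjudication,
        allowlist_label=None,
    )
    try:
        paths, _ = run_delphi([stripped], threshold)
    except UnresolvedItemError:
        return "UNRESOLVED"
    return paths[0].final_label.value


def check_kb_consistency(kb, threshold: float = CONSENSUS_THRESHOLD) -> ConsistencyReport:
    """Recompute every item's decision path from its round provenance and
    compare with the published final label.

    Discrepancies on the shipped known-anomaly allowlist are reported as
    allowlisted (the report stays ``ok``); anything else is a mismatch.
    """
    report = ConsistencyReport()
    for item_id, (item, printed) in sorted(kb.provenance.items()):
        derived = _derive_strict(item, threshold)
        if derived == printed.value:
            report.matches.append(item_id)
        elif item_id in kb.allowlist:
            report.allowlisted.append((item_id, derived, printed.value, kb.allowlist[item_id]))
        else:
            report.mismatches.append((item_id, derived, printed.value))
    return report
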