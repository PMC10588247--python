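"""Exception hierarchy for the malpip package."""


class MalpipError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MalpipError, ValueError):
    """An argument is outside the domain an operation is defined on."""


class InvalidSummaryError(DomainError):
    """A round summary carries a non-finite or inverted confidence interval."""


class InsufficientDataError(DomainError):
    """Too few ratings to summarize (fewer than two)."""


class UnresolvedItemError(MalpipError):
    """An item is still undecided after the last Delphi round and no
    adjudication record is available to resolve it."""

    def __init__(self, item_ids):
        self.item_ids = list(item_ids)
        super().__init__(
            "unresolved item(s) after final round with no adjudication: "
            + ", ".join(self.item_ids)
        )


class KBLoadError(MalpipError):
    """A knowledge-base fixture file is missing or unparseable."""


class LinkingError(KBLoadError):
    """A criterion references a drug, class or condition that does not
    resolve against the shipped lexicon / condition vocabulary."""


class UnknownDrugError(MalpipError, KeyError):
    """Lookup of a canonical drug name that is not in the lexicon."""
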