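"""Medication-name normalization and drug-class expansion.

The lexicon maps free-text medication names onto canonical drugs and the
pharmacological classes the criteria are written against.  Matching is
deterministic: case, surrounding whitespace, unicode-dash and separator
variants, and common salt/ester suffixes are normalized away, but no
fuzzy matching is ever applied silently — a misspelling returns
``UNMATCHED`` (an optional assist can *suggest* near-misses).
Combination products resolve to their components, which are screened
individually.
"""

from __future__ import annotations

import difflib
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Optional

from .errors import DomainError, UnknownDrugError

__all__ = ["LexiconEntry", "NormalizationResult", "Lexicon"]

# salt / ester suffix tokens stripped (right to left) when the full string
# fails to match; deterministic alternative to fuzzy matching
_SALT_SUFFIXES = {
    "sodium", "potassium", "calcium", "hydrochloride", "hcl", "tartrate",
    "succinate", "sulfate", "sulphate", "maleate", "acetate", "valerate",
    "besylate", "mesylate", "phosphate", "citrate", "bromide", "tosylate",
    "carbonate", "dihydrate", "monohydrate", "etexilate", "undecanoate",
}

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")


def _canon_text(name: str) -> str:
    s = unicodedata.normalize("NFKC", name).translate(_DASHES)
    s = s.casefold().strip()
    s = s.replace("/", "-")
    s = re.sub(r"[()\[\],;:]", " ", s)
    s = re.sub(r"\s*-\s*", "-", s)
    s = re.sub(r"\s+", " ", s)
    return s.strip(" .-")


@dataclass(frozen=True)
class LexiconEntry:
    canonical_name: str
    synonyms: frozenset = frozenset()
    class_memberships: frozenset = frozenset()
    combination_components: tuple = ()
    default_route: Optional[str] = None

    @property
    def is_combination(self) -> bool:
        return len(self.combination_components) >= 2


@dataclass(frozen=True)
class NormalizationResult:
    input_string: str
    status: str  # MATCHED | COMBINATION | UNMATCHED
    canonical: Optional[str] = None
    classes: frozenset = frozenset()
    components: tuple = ()
    suggestions: tuple = ()


class Lexicon:
    """Canonical drugs, synonyms, combinations and class memberships."""

    def __init__(self, entries: list[LexiconEntry]):
        self.entries: dict[str, LexiconEntry] = {}
        self._index: dict[str, str] = {}
        for e in entries:
            if e.canonical_name in self.entries:
                raise DomainError(f"duplicate canonical name {e.canonical_name!r}")
            self.entries[e.canonical_name] = e
        for e in entries:
            for alias in {e.canonical_name, *e.synonyms}:
                key = _canon_text(alias)
                owner = self._index.setdefault(key, e.canonical_name)
                if owner != e.canonical_name:
                    raise DomainError(
                        f"alias {alias!r} maps to both {owner!r} and {e.canonical_name!r}"
                    )
        for e in entries:
            if e.combination_components and len(e.combination_components) < 2:
                raise DomainError(f"{e.canonical_name}: combination needs >= 2 components")
            for comp in e.combination_components:
                if comp not in self.entries:
                    raise DomainError(f"{e.canonical_name}: unknown component {comp!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.entries

    @property
    def all_classes(self) -> frozenset:
        out = set()
        for e in self.entries.values():
            out |= e.class_memberships
        return frozenset(out)

    def _lookup(self, key: str) -> Optional[str]:
        hit = self._index.get(key)
        if hit is not None:
            return hit
        # deterministic salt/ester suffix stripping
        tokens = key.split(" ")
        while len(tokens) > 1 and tokens[-1] in _SALT_SUFFIXES:
            tokens.pop()
            hit = self._index.get(" ".join(tokens))
            if hit is not None:
                return hit
        return None

    def normalize_drug(self, name: str, fuzzy_suggest: bool = False) -> NormalizationResult:
        """Resolve a free-text medication name.

        Returns MATCHED for plain drugs, COMBINATION for combination
        products (with components), UNMATCHED otherwise.  With
        ``fuzzy_suggest`` close lexicon names are offered as suggestions
        on the UNMATCHED result; they are never auto-applied.
        """
        if not isinstance(name, str) or not name.strip():
            raise DomainError("medication name must be a non-empty string")
        key = _canon_text(name)
        canonical = self._lookup(key)
        if canonical is None:
            suggestions = ()
            if fuzzy_suggest:
                suggestions = tuple(
                    difflib.get_close_matches(key, self._index.keys(), n=3, cutoff=0.85)
                )
            return NormalizationResult(name, "UNMATCHED", suggestions=suggestions)
        entry = self.entries[canonical]
        classes = self.expand_classes(canonical)
        if entry.is_combination:
            return NormalizationResult(
                name, "COMBINATION", canonical, classes, entry.combination_components
            )
        return NormalizationResult(name, "MATCHED", canonical, classes)

    def expand_classes(self, canonical: str) -> frozenset:
        """All class memberships of a drug, including (for combination
        products) the classes of every component.  Idempotent."""
        entry = self.entries.get(canonical)
        if entry is None:
            raise UnknownDrugError(canonical)
        classes = set(entry.class_memberships)
        for comp in entry.combination_components:
            classes |= self.entries[comp].class_memberships
        return frozenset(classes)

    def default_route(self, canonical: str) -> Optional[str]:
        entry = self.entries.get(canonical)
        if entry is None:
            raise UnknownDrugError(canonical)
        return entry.default_route

    def members_of(self, class_name: str) -> list[str]:
        """Canonical names of the drugs carrying a class, sorted."""
        return sorted(
            name for name, e in self.entries.items() if class_name in e.class_memberships
        )

    def resolves(self, target: str) -> bool:
        """True if a criterion target resolves as a drug name or class."""
        return target in self.all_classes or self._lookup(_canon_text(target)) is not None
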