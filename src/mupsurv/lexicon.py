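"""Marker-of-ultra-processing (MUP) lexicon and ingredient-list scanning.

A MUP is an ingredient — a cosmetic additive or a non-culinary industrial
ingredient — whose presence in an ingredient list flags a food product as
ultra-processed (NOVA group 4).  The lexicon groups 57 such markers into
nine categories (flavour, flavour enhancer, colouring agent, sweetener,
processing aid, varieties of sugar, modified oil, protein source, fibre).
Free-text ingredient lists are normalized into a token stream and searched
for each marker's terms under whole-term matching: a single-word term must
match a whole token, a multi-word term a contiguous token run, so "sugar"
never fires inside "sugar snap peas"' neighbours nor inside longer words.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MarkerDef",
    "MupLexicon",
    "IngredientText",
    "LexiconError",
    "default_lexicon_path",
    "load_lexicon",
    "normalize_text",
    "scan_ingredients",
    "is_upf",
]

#: Markers whose presence is definitionally equivalent to their category.
CATEGORY_IDENTICAL_MARKERS = ("flavour", "colour", "hydrogenated oil", "fibre")

_PUNCT_RE = re.compile(r"[^a-z0-9]+")
_ENUM_RE = re.compile(r"^\d+[a-z]?$")


class LexiconError(ValueError):
    """Raised when a lexicon file is malformed or violates an invariant."""


@dataclass(frozen=True)
class MarkerDef:
    """One marker: its name, category and normalized search-term patterns."""

    name: str
    category: str
    search_terms: tuple[tuple[str, ...], ...]  # each term = token tuple
    identical_to_category: bool = False
    verified: bool = False

    def __post_init__(self) -> None:
        if not self.search_terms:
            raise LexiconError(f"marker {self.name!r} has no search terms")


@dataclass(frozen=True)
class MupLexicon:
    """The full marker taxonomy used for ingredient scanning."""

    categories: tuple[str, ...]
    markers: tuple[MarkerDef, ...]

    @property
    def category_of(self) -> dict[str, str]:
        return {m.name: m.category for m in self.markers}

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def markers_in(self, category: str) -> tuple[MarkerDef, ...]:
        return tuple(m for m in self.markers if m.category == category)

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise LexiconError("duplicate category names")
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LexiconError(f"marker(s) defined more than once: {sorted(dupes)}")
        for m in self.markers:
            if m.category not in self.categories:
                raise LexiconError(
                    f"marker {m.name!r} assigned to unknown category {m.category!r}"
                )


@dataclass(frozen=True)
class IngredientText:
    """Free-text ingredient list plus its normalized token stream."""

    raw: str
    tokens: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", normalize_text(self.raw))


def normalize_text(raw: str) -> tuple[str, ...]:
    """Normalize free ingredient text into a token tuple.

    Lower-cases, strips accents, collapses hyphens and all punctuation to
    whitespace, and re-joins split E-number codes so that ``"E 620"``,
    ``"e620"`` and ``"E620"`` all yield the single token ``"e620"``.
    Normalization is idempotent.
    """
    folded = unicodedata.normalize("NFKD", raw)
    folded = "".join(c for c in folded if not unicodedata.combining(c))
    pieces = _PUNCT_RE.sub(" ", folded.lower()).split()
    tokens: list[str] = []
    i = 0
    while i < len(pieces):
        # "e" immediately followed by a numeric code is an E-number spelling
        if pieces[i] == "e" and i + 1 < len(pieces) and _ENUM_RE.match(pieces[i + 1]):
            tokens.append("e" + pieces[i + 1])
            i += 2
        else:
            tokens.append(pieces[i])
            i += 1
    return tuple(tokens)


def _contains_run(tokens: tuple[str, ...], term: tuple[str, ...]) -> bool:
    """Whole-term match: `term` occurs as a contiguous token run."""
    k = len(term)
    if k == 0 or k > len(tokens):
        return False
    if k == 1:
        return term[0] in tokens
    return any(tokens[i : i + k] == term for i in range(len(tokens) - k + 1))


def scan_ingredients(
    text: IngredientText | str, lexicon: MupLexicon
) -> set[str]:
    """Return the set of lexicon markers present in one ingredient list.

    A marker is present iff at least one of its search terms occurs in the
    normalized text as a whole term.  Empty text yields the empty set.
    """
    if isinstance(text, str):
        text = IngredientText(text)
    tokens = text.tokens
    found: set[str] = set()
    for marker in lexicon.markers:
        if any(_contains_run(tokens, term) for term in marker.search_terms):
            found.add(marker.name)
    return found


def is_upf(markers_present: Iterable[str]) -> bool:
    """A food item is ultra-processed iff it contains at least one MUP."""
    return len(set(markers_present)) > 0


def default_lexicon_path() -> Path:
    return Path(str(resources.files("mupsurv").joinpath("data/mup_lexicon.yaml")))


def load_lexicon(path: str | Path | None = None) -> MupLexicon:
    """Load and validate a lexicon file (YAML: categories → markers → terms).

    The shipped default holds the 57-marker / 9-category taxonomy.  Rejects
    duplicate marker names, markers listed under two categories, empty term
    sets and unknown structure, naming the offending entry.
    """
    if path is None:
        path = default_lexicon_path()
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - passthrough detail
            raise LexiconError(f"cannot parse lexicon file {path}: {exc}") from exc
    if not isinstance(doc, Mapping) or "categories" not in doc:
        raise LexiconError(f"lexicon file {path} lacks a top-level 'categories' list")

    categories: list[str] = []
    markers: list[MarkerDef] = []
    for cat in doc["categories"]:
        try:
            cname = cat["name"]
            entries = cat["markers"]
        except (TypeError, KeyError) as exc:
            raise LexiconError(f"malformed category entry {cat!r}") from exc
        categories.append(cname)
        for entry in entries:
            try:
                mname = entry["name"]
                raw_terms = entry["search_terms"]
            except (TypeError, KeyError) as exc:
                raise LexiconError(
                    f"malformed marker entry {entry!r} in category {cname!r}"
                ) from exc
            terms = tuple(
                normalize_text(t) for t in raw_terms if normalize_text(t)
            )
            if not terms:
                raise LexiconError(f"marker {mname!r} has no usable search terms")
            markers.append(
                MarkerDef(
                    name=mname,
                    category=cname,
                    search_terms=terms,
                    identical_to_category=bool(entry.get("identical_to_category", False)),
                    verified=bool(entry.get("verified", False)),
                )
            )
    return MupLexicon(categories=tuple(categories), markers=tuple(markers))
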