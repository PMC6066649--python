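"""Category-level grammars over the two-category tile alphabet.

Grammars are defined purely on the A/B category sequence; tile identities
and separator markers never influence membership.  Each grammar exposes a
total membership predicate (:meth:`Grammar.accepts`), a generator for each
admissible repeat count *N*, and a marker-placement convention used when
building stimuli.  A small open registry maps stable string names (``ABN``,
``ABnA``, ``Mirror``, ``Copy``, ``AEdgeStar``, ``AEdgePlus``, ``BFirst``)
to :class:`Grammar` instances so that candidate strategy grammars can be
added without touching the core.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

A = "A"
B = "B"
CATEGORIES = (A, B)

#: Marker character used in the textual serialization ("ABB|ABB").
MARKER_CHAR = "|"

ENUMERATION_BOUND = 14


class UnknownGrammarError(KeyError):
    """Raised when a grammar name is not present in the registry."""


class InvalidRepeatCountError(ValueError):
    """Raised when a repeat count lies outside a grammar's admissible range."""


class IntractableEnumerationError(ValueError):
    """Raised when exhaustive enumeration is requested beyond the length bound."""


@dataclass(frozen=True)
class CategoryString:
    """An ordered A/B category sequence with optional separator markers.

    ``marker_slots`` are 0-based gap positions strictly inside the string
    (slot ``k`` sits between ``symbols[k-1]`` and ``symbols[k]``).  Markers
    are presentation metadata only.
    """

    symbols: str
    marker_slots: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.symbols) <= set(CATEGORIES):
            raise ValueError(f"symbols must be drawn from {CATEGORIES}: {self.symbols!r}")
        slots = tuple(self.marker_slots)
        if slots != tuple(sorted(set(slots))):
            raise ValueError("marker_slots must be sorted and unique")
        for slot in slots:
            if not 0 < slot < len(self.symbols):
                raise ValueError(
                    f"marker slot {slot} not strictly inside string of length {len(self.symbols)}"
                )
        object.__setattr__(self, "marker_slots", slots)

    def __len__(self) -> int:
        return len(self.symbols)

    def to_text(self) -> str:
        """Serialize as e.g. ``"ABB|ABB"`` with markers at their slots."""
        out = []
        slots = set(self.marker_slots)
        for i, ch in enumerate(self.symbols):
            if i in slots:
                out.append(MARKER_CHAR)
            out.append(ch)
        return "".join(out)

    @classmethod
    def from_text(cls, text: str) -> "CategoryString":
        symbols = []
        slots = []
        for ch in text:
            if ch == MARKER_CHAR:
                slots.append(len(symbols))
            elif ch in (" ",):
                continue
            else:
                symbols.append(ch)
        return cls("".join(symbols), tuple(slots))


@dataclass(frozen=True)
class LanguageSample:
    """Exact accept set of a grammar over all category strings up to a bound."""

    strings: frozenset[str]
    bound: int

    def __contains__(self, s: str | CategoryString) -> bool:
        if isinstance(s, CategoryString):
            s = s.symbols
        return s in self.strings


def _as_symbols(s: CategoryString | str) -> str:
    return s.symbols if isinstance(s, CategoryString) else s


@dataclass(frozen=True)
class Grammar:
    """A named grammar: membership predicate + generator + marker convention."""

    name: str
    level: str  # regular | context-free | mildly-context-sensitive | heuristic
    predicate: Callable[[str], bool]
    generator: Callable[[int, np.random.Generator], str]
    n_range: range = field(default_factory=lambda: range(1, 9))
    marker_rule: Callable[[int], tuple[int, ...]] = lambda length: ()

    def accepts(self, s: CategoryString | str) -> bool:
        """Membership by category pattern only; empty strings are rejected."""
        symbols = _as_symbols(s)
        if not symbols:
            return False
        return bool(self.predicate(symbols))

    def generate(self, n: int, rng: np.random.Generator) -> CategoryString:
        if n not in self.n_range:
            raise InvalidRepeatCountError(
                f"repeat count {n} outside admissible range "
                f"[{self.n_range.start}, {self.n_range.stop - 1}] for {self.name}"
            )
        symbols = self.generator(n, rng)
        out = CategoryString(symbols, self.marker_rule(len(symbols)))
        assert self.accepts(out), "generator produced a non-member"
        return out

    def marker_slots(self, length: int) -> tuple[int, ...]:
        return self.marker_rule(length)


_REGISTRY: dict[str, Grammar] = {}


def register(grammar: Grammar, *, overwrite: bool = False) -> Grammar:
    if grammar.name in _REGISTRY and not overwrite:
        raise ValueError(f"grammar {grammar.name!r} already registered")
    _REGISTRY[grammar.name] = grammar
    return grammar


def unregister(name: str) -> None:
    _REGISTRY.pop(name, None)


def get_grammar(name: str | Grammar) -> Grammar:
    if isinstance(name, Grammar):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownGrammarError(
            f"unregistered grammar {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def registered_names() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def accepts(grammar: str | Grammar, s: CategoryString | str) -> bool:
    return get_grammar(grammar).accepts(s)


def generate(grammar: str | Grammar, n: int, rng: np.random.Generator) -> CategoryString:
    return get_grammar(grammar).generate(n, rng)


def enumerate_language(grammar: str | Grammar, max_len: int) -> LanguageSample:
    """Exact accept set by exhaustive generation over {A,B}^<=max_len."""
    if max_len > ENUMERATION_BOUND:
        raise IntractableEnumerationError(
            f"max_len {max_len} exceeds tractability bound {ENUMERATION_BOUND}"
        )
    g = get_grammar(grammar)
    accepted = []
    for length in range(1, max_len + 1):
        for tup in itertools.product(CATEGORIES, repeat=length):
            s = "".join(tup)
            if g.accepts(s):
                accepted.append(s)
    return LanguageSample(frozenset(accepted), max_len)


# --- generator helpers -------------------------------------------------------

def _random_half(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(CATEGORIES), size=n))


def _midpoint_marker(length: int) -> tuple[int, ...]:
    if length < 2:
        return ()
    return (length // 2,)


def _edge_markers(length: int) -> tuple[int, ...]:
    # one marker after the initial A and one before the final A
    if length < 3:
        return _midpoint_marker(length)
    return (1, length - 1)


# --- grammar definitions -----------------------------------------------------

#: Training grammar A B^N (warm-up sessions only).
ABN = register(
    Grammar(
        name="ABN",
        level="regular",
        predicate=lambda s: len(s) >= 2 and s[0] == A and set(s[1:]) == {B},
        generator=lambda n, rng: A + B * n,
        marker_rule=lambda length: (1,) if length >= 2 else (),
    )
)

#: A B^N A — regular, one long-distance dependency between the edge As.
ABnA = register(
    Grammar(
        name="ABnA",
        level="regular",
        predicate=lambda s: (
            len(s) >= 3 and s[0] == A and s[-1] == A and set(s[1:-1]) == {B}
        ),
        generator=lambda n, rng: A + B * n + A,
        marker_rule=_edge_markers,
    )
)

#: W W^R — context-free, nested dependencies (even-length palindromes).
Mirror = register(
    Grammar(
        name="Mirror",
        level="context-free",
        predicate=lambda s: len(s) % 2 == 0 and len(s) >= 2 and s == s[::-1],
        generator=lambda n, rng: (lambda w: w + w[::-1])(_random_half(n, rng)),
        marker_rule=_midpoint_marker,
    )
)

#: W W — mildly context-sensitive, crossed dependencies.
Copy = register(
    Grammar(
        name="Copy",
        level="mildly-context-sensitive",
        predicate=lambda s: (
            len(s) % 2 == 0 and len(s) >= 2 and s[: len(s) // 2] == s[len(s) // 2 :]
        ),
        generator=lambda n, rng: (lambda w: w + w)(_random_half(n, rng)),
        marker_rule=_midpoint_marker,
    )
)

#: A (possibly empty middle) A — heuristic edge checker.
AEdgeStar = register(
    Grammar(
        name="AEdgeStar",
        level="heuristic",
        predicate=lambda s: len(s) >= 2 and s[0] == A and s[-1] == A,
        generator=lambda n, rng: A + _random_half(n, rng) + A,
        marker_rule=_midpoint_marker,
    )
)

#: A (non-empty middle) A.
AEdgePlus = register(
    Grammar(
        name="AEdgePlus",
        level="heuristic",
        predicate=lambda s: len(s) >= 3 and s[0] == A and s[-1] == A,
        generator=lambda n, rng: A + _random_half(n, rng) + A,
        marker_rule=_midpoint_marker,
    )
)

# Name-literal placeholder: accept iff the first symbol is a B.  The formal
# definition used in the original alternative-grammar suite is not published;
# the predicate is a single swappable callable so it can be replaced via
# register(..., overwrite=True).
BFirst = register(
    Grammar(
        name="BFirst",
        level="heuristic",
        predicate=lambda s: s[0] == B,
        generator=lambda n, rng: B + _random_half(n, rng),
        marker_rule=_midpoint_marker,
    )
)

#: Default candidate suite used for consistency coding.
DEFAULT_CANDIDATES = ("ABnA", "Mirror", "Copy", "AEdgeStar", "AEdgePlus", "BFirst")

#: The three session target grammars.
TARGET_GRAMMARS = ("ABnA", "Mirror", "Copy")
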