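"""Balanced measurement designs: facets, nesting, and admissible effects.

A measurement design names the *object of measurement* (typically the test
taker) and the *facets* of the measurement procedure — stations, forms,
raters, sites — together with their crossing/nesting structure.  From the
design this module derives the admissible variance-component *effects*
(the terms of the random-effects score decomposition) and their degrees of
freedom under a balanced layout.

Design formulas use a compact infix grammar:

* ``x`` (or ``*``) crosses facets: ``p x t x r``;
* ``:`` nests the left identifier within the right: ``p:s x f x st`` reads
  "persons nested within sites; sites, forms and stations fully crossed";
* the first identifier is the object of measurement.

A fully crossed design with the object plus *k* facets yields ``2**(k+1)-1``
effects.  Under nesting, any effect containing a nested facet absorbs that
facet's nesting parents into its nesting-index part, and index subsets whose
mean squares would be confounded in balanced data collapse onto a single
effect (their closures coincide), so the expected-mean-square system stays
non-singular.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

from .errors import ConfigError, DesignError, ParseError

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
# a lone 'x', '*' or '×' acts as the crossing operator; identifiers may
# still contain the letter x ("box", "x1") because the split requires a
# non-word character (or string boundary) on both sides
_CROSS = re.compile(r"(?<![A-Za-z0-9_])[x×*](?![A-Za-z0-9_])")


@dataclass(frozen=True)
class Facet:
    """One source of score variance (or the object of measurement)."""

    name: str
    nested_within: tuple[str, ...] = ()
    is_object_of_measurement: bool = False


@dataclass(frozen=True)
class Effect:
    """One admissible variance component, in Brennan-style notation.

    ``primary`` holds the indices before the colon, ``nesting`` the indices
    after it (``pf:s`` has primary ``{p, f}`` and nesting ``{s}``).  The two
    sets are disjoint; ``facets`` is their union.  The residual is the
    unique maximal effect containing every facet of the design.
    """

    name: str
    primary: frozenset[str]
    nesting: frozenset[str]
    is_residual: bool = False

    @property
    def facets(self) -> frozenset[str]:
        return self.primary | self.nesting

    def contains(self, other: "Effect") -> bool:
        """True when ``other``'s index set is a subset of this effect's."""
        return other.facets <= self.facets

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class Design:
    """A parsed design: ordered facets plus the enumerated effect list."""

    facets: tuple[Facet, ...]
    effects: tuple[Effect, ...]
    formula_text: str

    # -- lookups ---------------------------------------------------------
    @property
    def facet_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.facets)

    def facet(self, name: str) -> Facet:
        for f in self.facets:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def object_facet(self) -> Facet:
        return next(f for f in self.facets if f.is_object_of_measurement)

    @property
    def object_effect(self) -> Effect:
        """The pure object-of-measurement effect (``p`` or ``p:s``)."""
        target = frozenset({self.object_facet.name}) | frozenset(
            self.object_facet.nested_within
        )
        for e in self.effects:
            if e.facets == target:
                return e
        raise DesignError("object effect missing from effect list")

    @property
    def residual_effect(self) -> Effect:
        return self.effects[-1]

    def effect_named(self, name: str) -> Effect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(f"no effect named {name!r} in design {self.formula_text!r}")

    def ancestors(self, name: str) -> tuple[str, ...]:
        return self.facet(name).nested_within

    def render(self) -> str:
        """Formula text that re-parses to an identical design."""
        ancestor_names = {a for f in self.facets for a in f.nested_within}
        terms = []
        for f in self.facets:
            if f.name in ancestor_names:
                continue  # appears inside another term's nesting chain
            terms.append(":".join((f.name,) + f.nested_within))
        return " x ".join(terms)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_design(formula: str) -> Design:
    """Parse a crossing/nesting formula into a :class:`Design`.

    The first identifier is the object of measurement.  Raises
    :class:`ParseError` for malformed tokens and :class:`DesignError` for
    duplicate facets or cyclic nesting.
    """
    if not formula or not formula.strip():
        raise ParseError("empty design formula")
    terms = [t.strip() for t in _CROSS.split(formula)]
    if any(not t for t in terms):
        raise ParseError(f"dangling crossing operator in formula {formula!r}")

    order: list[str] = []
    nested: dict[str, tuple[str, ...]] = {}
    heads: list[str] = []
    for term in terms:
        chain = [c.strip() for c in term.split(":")]
        for ident in chain:
            if not ident:
                raise ParseError(f"dangling ':' in term {term!r}")
            if not _IDENT.match(ident):
                raise ParseError(f"invalid identifier {ident!r} in formula {formula!r}")
        head = chain[0]
        if head in heads:
            raise DesignError(f"duplicate facet name {head!r}")
        heads.append(head)
        for i, ident in enumerate(chain):
            parents = tuple(chain[i + 1:])
            if ident in nested:
                if parents and nested[ident] and parents != nested[ident]:
                    raise DesignError(
                        f"conflicting nesting declared for facet {ident!r}"
                    )
                nested[ident] = nested[ident] or parents
            else:
                nested[ident] = parents
            if ident not in order:
                order.append(ident)

    # cycle check: a facet must not be reachable from itself through the
    # nesting relation (revisiting a shared ancestor is not a cycle)
    for name in order:
        seen = set()
        frontier = list(nested[name])
        while frontier:
            cur = frontier.pop()
            if cur == name:
                raise DesignError(f"cyclic nesting involving facet {cur!r}")
            if cur in seen:
                continue
            seen.add(cur)
            frontier.extend(nested.get(cur, ()))

    object_name = terms[0].split(":")[0].strip()
    facets = tuple(
        Facet(
            name=name,
            nested_within=_full_ancestry(name, nested),
            is_object_of_measurement=(name == object_name),
        )
        for name in order
    )
    design = Design(facets=facets, effects=(), formula_text=formula.strip())
    effects = tuple(enumerate_effects(design))
    return Design(facets=facets, effects=effects, formula_text=formula.strip())


def _full_ancestry(name: str, nested: dict[str, tuple[str, ...]]) -> tuple[str, ...]:
    out: list[str] = []
    cur = name
    while nested.get(cur):
        for parent in nested[cur]:
            if parent not in out:
                out.append(parent)
        cur = nested[cur][-1]
        if len(out) > len(nested):  # pragma: no cover - guarded by cycle check
            raise DesignError("cyclic nesting")
    return tuple(out)


# ---------------------------------------------------------------------------
# effect enumeration
# ---------------------------------------------------------------------------

def enumerate_effects(design: Design) -> list[Effect]:
    """Enumerate every admissible effect of a design.

    Each non-empty subset of facets is closed by absorbing the nesting
    ancestors of its members; closures that coincide are confounded in
    balanced data and collapse to one effect.  Within a closed set the
    nesting indices are the members that are ancestors of another member,
    the primary indices are the rest.
    """
    names = [f.name for f in design.facets]
    anc = {f.name: set(f.nested_within) for f in design.facets}
    closed: set[frozenset[str]] = set()
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            closure = set(subset)
            for member in subset:
                closure |= anc[member]
            closed.add(frozenset(closure))

    pos = {name: i for i, name in enumerate(names)}
    ordered = sorted(closed, key=lambda s: (len(s), tuple(sorted(pos[n] for n in s))))
    all_facets = frozenset(names)
    single_char = all(len(n) == 1 for n in names)
    sep = "" if single_char else "·"

    effects = []
    for facet_set in ordered:
        nesting = frozenset(
            g for g in facet_set if any(g in anc[m] for m in facet_set if m != g)
        )
        primary = facet_set - nesting
        label = sep.join(sorted(primary, key=pos.__getitem__))
        if nesting:
            label += ":" + sep.join(sorted(nesting, key=pos.__getitem__))
        effects.append(
            Effect(
                name=label,
                primary=primary,
                nesting=nesting,
                is_residual=(facet_set == all_facets),
            )
        )
    return effects


# ---------------------------------------------------------------------------
# sizes, degrees of freedom
# ---------------------------------------------------------------------------

def degrees_of_freedom(effect: Effect, sizes: dict[str, int]) -> int:
    """Balanced-design degrees of freedom for one effect.

    ``df = prod(n_f - 1)`` over primary indices times ``prod(n_f)`` over
    nesting indices.  Sizes of nested facets are counts *per parent
    combination* (balanced designs only).
    """
    df = 1
    for name in effect.primary:
        if name not in sizes:
            raise ConfigError(f"missing size for facet {name!r}")
        df *= sizes[name] - 1
    for name in effect.nesting:
        if name not in sizes:
            raise ConfigError(f"missing size for facet {name!r}")
        df *= sizes[name]
    return df


def n_levels(effect: Effect, sizes: dict[str, int]) -> int:
    """Number of distinct level combinations an effect indexes."""
    n = 1
    for name in effect.facets:
        if name not in sizes:
            raise ConfigError(f"missing size for facet {name!r}")
        n *= sizes[name]
    return n
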