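"""Quine-McCluskey minimization for Boolean and multi-valued rules.

Implicant patterns carry a single value or a full wildcard per position
(multi-valued positions never hold partial value subsets, which keeps the
implicant lattice finite).  Merging generalizes the classic pairwise rule:
m implicants identical except at one position whose values jointly exhaust
the alphabet collapse to a wildcard there.

Cover selection picks essential prime implicants first (sole coverers of
some minterm) and completes the cover by exact branch-and-bound set cover
(Petrick-style) up to ``EXACT_COVER_LIMIT`` candidate implicants, falling
back to a greedy completion with a warning beyond that -- minimal-DNF
search is NP-complete.  Ties among minimum covers are broken
deterministically: most total wildcards, then lexicographic pattern order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .core import DiscreteFunction

__all__ = [
    "Implicant",
    "CoverEntry",
    "CoverSet",
    "prime_implicants",
    "minimal_cover",
    "cover",
    "dnf_text",
    "simplified_table",
]

EXACT_COVER_LIMIT = 24

STAR = None  # wildcard marker inside patterns


@dataclass(frozen=True)
class Implicant:
    """A pattern asserting one output value.

    ``pattern`` has k positions, each a value in M or None (wildcard);
    ``output`` is the asserted result r of the assertion {r: C}.
    """

    pattern: tuple
    output: int

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def star_count(self) -> int:
        return sum(1 for p in self.pattern if p is STAR)

    @property
    def literal_count(self) -> int:
        return self.k - self.star_count

    def covers(self, x: Sequence[int]) -> bool:
        return all(p is STAR or p == v for p, v in zip(self.pattern, x))

    def minterms(self, m: int):
        """All inputs matched by this pattern."""
        axes = [range(m) if p is STAR else (p,) for p in self.pattern]
        return itertools.product(*axes)

    def sort_key(self):
        # house order: more literals first, then lexicographic with the
        # wildcard sorting before concrete values
        return (-self.literal_count,
                tuple(-1 if p is STAR else p for p in self.pattern))


def prime_implicants(f: DiscreteFunction, s: int) -> List[Implicant]:
    """All maximal implicants of the on-set {x | f(x) = s}.

    Level-by-level m-way merging starting from the minterms; an implicant
    that takes part in any merge is contained in the merged pattern and
    therefore not prime.
    """
    if not (0 <= s < f.m):
        raise ValueError(f"output value {s} outside alphabet")
    current = {x for x in f.inputs() if f(x) == s}
    primes = []
    while current:
        merged = set()
        nxt = set()
        buckets: Dict[tuple, dict] = {}
        for p in current:
            for i, v in enumerate(p):
                if v is STAR:
                    continue
                key = (i, p[:i] + (STAR,) + p[i + 1:])
                buckets.setdefault(key, {})[v] = p
        for (i, masked), found in buckets.items():
            if len(found) == f.m:
                nxt.add(masked)
                merged.update(found.values())
        primes.extend(p for p in current if p not in merged)
        current = nxt
    out = [Implicant(p, s) for p in set(primes)]
    out.sort(key=Implicant.sort_key)
    return out


@dataclass
class CoverEntry:
    """Deterministic minimal cover of one output value's on-set."""

    implicants: List[Implicant]
    essential: List[bool]

    def __iter__(self):
        return iter(self.implicants)

    def __len__(self):
        return len(self.implicants)


CoverSet = Dict[int, CoverEntry]


def _greedy_completion(remaining, candidates, m):
    chosen = []
    remaining = set(remaining)
    cands = list(candidates)
    while remaining:
        best = max(cands, key=lambda imp: (
            sum(1 for x in remaining if imp.covers(x)),
            imp.star_count,
            tuple(-(-1 if p is STAR else p) for p in imp.pattern)))
        chosen.append(best)
        cands.remove(best)
        remaining -= {x for x in remaining if best.covers(x)}
    return chosen


def _exact_completion(remaining, candidates, m):
    """Branch-and-bound minimum set cover with deterministic tie-breaks:
    fewest implicants, then most total wildcards, then lexicographic
    pattern order."""
    cover_of = {x: [i for i, imp in enumerate(candidates) if imp.covers(x)]
                for x in remaining}
    best: list = [None]  # (size, -stars, patterns_key, chosen)

    def key_of(chosen):
        stars = sum(candidates[i].star_count for i in chosen)
        pats = sorted(tuple(-1 if p is STAR else p
                            for p in candidates[i].pattern) for i in chosen)
        return (len(chosen), -stars, pats)

    def search(uncovered, chosen):
        if best[0] is not None and len(chosen) > best[0][0]:
            return
        if not uncovered:
            cand = key_of(chosen) + (list(chosen),)
            if best[0] is None or cand[:3] < best[0][:3]:
                best[0] = cand
            return
        # branch on the hardest minterm
        x = min(uncovered, key=lambda x: len(cover_of[x]))
        for i in cover_of[x]:
            if i in chosen:
                continue
            nxt = {y for y in uncovered if not candidates[i].covers(y)}
            search(nxt, chosen | {i})

    search(set(remaining), frozenset())
    return [candidates[i] for i in best[0][3]]


def minimal_cover(implicants: Iterable[Implicant],
                  onset: Iterable[tuple]) -> CoverEntry:
    """Essential implicants plus a deterministic minimal completion."""
    implicants = list(implicants)
    onset = [tuple(x) for x in onset]
    if not onset:
        return CoverEntry([], [])
    cover_of = {x: [imp for imp in implicants if imp.covers(x)]
                for x in onset}
    for x, imps in cover_of.items():
        if not imps:
            raise ValueError(f"minterm {x} not covered by any implicant")
    essential = []
    for x, imps in cover_of.items():
        if len(imps) == 1 and imps[0] not in essential:
            essential.append(imps[0])
    covered = set()
    for imp in essential:
        covered.update(x for x in onset if imp.covers(x))
    remaining = [x for x in onset if x not in covered]
    extra: List[Implicant] = []
    if remaining:
        candidates = [imp for imp in implicants if imp not in essential
                      and any(imp.covers(x) for x in remaining)]
        if len(candidates) > EXACT_COVER_LIMIT:
            warnings.warn(
                f"{len(candidates)} candidate implicants exceed the exact "
                f"cover limit ({EXACT_COVER_LIMIT}); using greedy completion",
                RuntimeWarning)
            extra = _greedy_completion(remaining, candidates, 0)
        else:
            extra = _exact_completion(remaining, candidates, 0)
    chosen = essential + extra
    flags = [imp in essential for imp in chosen]
    order = sorted(range(len(chosen)), key=lambda i: chosen[i].sort_key())
    return CoverEntry([chosen[i] for i in order], [flags[i] for i in order])


def cover(f: DiscreteFunction) -> CoverSet:
    """Deterministic minimal cover for every output value (Q_s)."""
    out: CoverSet = {}
    for s in range(f.m):
        onset = [x for x in f.inputs() if f(x) == s]
        if not onset:
            out[s] = CoverEntry([], [])
            continue
        out[s] = minimal_cover(prime_implicants(f, s), onset)
    return out


def _names(f: DiscreteFunction, names) -> list:
    if names is not None:
        names = list(names)
        if len(names) != f.k:
            raise ValueError("need exactly k names")
        return names
    if f.input_names is not None:
        return list(f.input_names)
    return [f"x{i}" for i in range(1, f.k + 1)]


def _clause_text(imp: Implicant, names) -> str:
    lits = []
    for name, p in zip(names, imp.pattern):
        if p is STAR:
            continue
        lits.append(name if p == 1 else "~" + name)
    return "*".join(lits)


def dnf_text(f: DiscreteFunction, names=None) -> str:
    """Printable minimal disjunctive normal form.

    Boolean rules: clauses joined by ``+``, literals by ``*``, negation by
    ``~``.  Multi-valued rules: a max of assertions ``{r: xi=v*...}``.
    """
    names = _names(f, names)
    covers = cover(f)
    if f.m == 2:
        entry = covers[1]
        if not entry.implicants:
            return "0"
        if len(entry.implicants) == 1 and entry.implicants[0].star_count == f.k:
            return "1"
        return " + ".join(_clause_text(imp, names) for imp in entry)
    assertions = []
    for s in range(f.m):
        for imp in covers[s]:
            if imp.star_count == imp.k:
                body = "*"
            else:
                body = "*".join(f"{n}={p}" for n, p in
                                zip(names, imp.pattern) if p is not STAR)
            assertions.append(f"{{{s}: {body}}}")
    return "max{" + ", ".join(assertions) + "}"


def structured_dnf(f: DiscreteFunction, names=None):
    """DNF as data: list of (output value, [(name, value), ...]) clauses."""
    names = _names(f, names)
    covers = cover(f)
    out = []
    for s in range(f.m):
        for imp in covers[s]:
            out.append((s, [(n, p) for n, p in zip(names, imp.pattern)
                            if p is not STAR]))
    return out


def simplified_table(f: DiscreteFunction):
    """Cover implicants as rows (pattern with None = NA wildcard, output),
    output values in descending order, clauses in house order."""
    covers = cover(f)
    rows = []
    for s in sorted(range(f.m), reverse=True):
        for imp in covers[s]:
            rows.append((imp.pattern, s))
    return rows
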