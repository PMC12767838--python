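"""Discrete update rules over the alphabet M = {0, ..., m-1}.

A gene's update rule ("logical paradigm") is stored as a complete mapping
table: arity ``k``, base ``m`` and a tuple of ``m**k`` output values.  Row
indexing is mixed-radix with the *first* variable as the most significant
digit::

    index(x) = sum_i  x_i * m**(k - i)      (i = 1..k)

Every module in this package relies on that convention.

Besides plain evaluation, this module detects and generates the canonical
rule classes of discrete regulatory modelling:

* nested canalization (a value of one input forces the output; peeling the
  forced region exposes the next layer),
* sign-definite / monotone rules (each input acts consistently as an
  activator or a repressor),
* dominant (weighted-majority) rules, via exact linear-feasibility
  witnesses.
"""

from __future__ import annotations

import itertools
import random as _random
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "DiscreteFunction",
    "CanalizationLayer",
    "NestedCanalization",
    "EdgeSign",
    "DominantForm",
    "evaluate",
    "nested_canalization",
    "edge_sign",
    "is_monotone",
    "detect_dominant",
    "random_function",
    "load_truth_table",
    "dump_truth_table",
]

# Scale used when rounding float LP solutions to exact integers.  The LP is
# posed with a separation margin of 1, so a relative rounding error of
# ~1e-6 after scaling by RATIONAL_SCALE can never flip an inequality.
RATIONAL_SCALE = 10 ** 6


@dataclass(frozen=True)
class DiscreteFunction:
    """A complete k-input, base-m mapping table.

    Parameters
    ----------
    k : int
        Number of inputs (arity).  ``k == 0`` is allowed and encodes a
        constant rule (table of length one).
    m : int
        Size of the value alphabet, ``m >= 2``.
    table : tuple of int
        ``m**k`` output values, indexed mixed-radix with variable 1 most
        significant.
    input_names : tuple of str, optional
        Display names for the k inputs.
    """

    k: int
    m: int
    table: tuple
    input_names: tuple = None

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("arity k must be non-negative")
        if self.m < 2:
            raise ValueError("base m must be at least 2")
        table = tuple(int(v) for v in self.table)
        if len(table) != self.m ** self.k:
            raise ValueError(
                f"table length {len(table)} != m**k = {self.m ** self.k}"
            )
        if any(not (0 <= v < self.m) for v in table):
            raise ValueError("table entries must lie in {0..m-1}")
        object.__setattr__(self, "table", table)
        if self.input_names is not None:
            names = tuple(str(n) for n in self.input_names)
            if len(names) != self.k:
                raise ValueError("need exactly k input names")
            object.__setattr__(self, "input_names", names)

    # -- indexing ---------------------------------------------------------
    def index(self, x: Sequence[int]) -> int:
        if len(x) != self.k:
            raise ValueError(f"expected {self.k} inputs, got {len(x)}")
        idx = 0
        for v in x:
            v = int(v)
            if not (0 <= v < self.m):
                raise ValueError(f"input value {v} outside 0..{self.m - 1}")
            idx = idx * self.m + v
        return idx

    def __call__(self, x: Sequence[int]) -> int:
        return self.table[self.index(x)]

    def inputs(self) -> Iterator[tuple]:
        """All m**k input vectors in table (index) order."""
        return itertools.product(range(self.m), repeat=self.k)

    # -- helpers ----------------------------------------------------------
    @classmethod
    def from_callable(cls, k: int, m: int, fn: Callable[[tuple], int],
                      input_names=None) -> "DiscreteFunction":
        table = tuple(int(fn(x)) for x in
                      itertools.product(range(m), repeat=k))
        return cls(k, m, table, input_names)

    def is_constant(self) -> bool:
        return len(set(self.table)) <= 1

    def restrict(self, assignment: Mapping[int, int]) -> "DiscreteFunction":
        """Partial evaluation: fix variables (1-based index -> value).

        Returns the rule on the remaining variables, in their original
        relative order.
        """
        for i in assignment:
            if not (1 <= i <= self.k):
                raise ValueError(f"variable index {i} out of range")
        free = [i for i in range(1, self.k + 1) if i not in assignment]

        def fn(y):
            x = [0] * self.k
            for i, v in assignment.items():
                x[i - 1] = v
            for i, v in zip(free, y):
                x[i - 1] = v
            return self(x)

        names = None
        if self.input_names is not None:
            names = tuple(self.input_names[i - 1] for i in free)
        return DiscreteFunction.from_callable(len(free), self.m, fn, names)

    def permute(self, order: Sequence[int]) -> "DiscreteFunction":
        """Reorder inputs: ``order[j]`` is the old 1-based index of new
        position j+1."""
        if sorted(order) != list(range(1, self.k + 1)):
            raise ValueError("order must be a permutation of 1..k")

        def fn(y):
            x = [0] * self.k
            for newpos, old in enumerate(order):
                x[old - 1] = y[newpos]
            return self(x)

        names = None
        if self.input_names is not None:
            names = tuple(self.input_names[i - 1] for i in order)
        return DiscreteFunction.from_callable(self.k, self.m, fn, names)


def evaluate(f: DiscreteFunction, x: Sequence[int]) -> int:
    """Table lookup under the mixed-radix convention (x1 most significant)."""
    return f(x)


# ---------------------------------------------------------------------------
# Nested canalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanalizationLayer:
    """One layer of a nested-canalization chain.

    ``value_map`` sends each canalizing value of variable ``variable``
    (1-based) to its canalized output value; its keys are S_in, its value
    set is S_out, and |S_out| <= |S_in| holds by construction.
    """

    variable: int
    value_map: Mapping[int, int]
    depth: int

    @property
    def canalizing_values(self) -> tuple:
        return tuple(sorted(self.value_map))

    @property
    def canalized_values(self) -> tuple:
        return tuple(sorted(set(self.value_map.values())))


@dataclass
class NestedCanalization:
    """Result of greedy canalization peeling.

    ``layers`` is the ordered chain (possibly empty).  ``residual`` is what
    remains after all layers are peeled: either ``("constant", v)``,
    ``("table", {input-tuple: value})`` for a non-canalizing remainder, or
    ``("empty", None)`` when the layers exhaust the whole domain.
    Truthiness, length and iteration all refer to the layer chain.
    """

    layers: list
    residual: tuple
    k: int = 0
    m: int = 2

    def __len__(self):
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def __bool__(self):
        return bool(self.layers)

    @property
    def depth(self) -> int:
        return len(self.layers)

    def reconstruct(self) -> DiscreteFunction:
        """Replay the layer case-analysis over the residual table.

        Exact inverse of the peeling: the round trip reproduces the source
        rule.
        """
        kind, payload = self.residual

        def fn(x):
            for layer in self.layers:
                v = x[layer.variable - 1]
                if v in layer.value_map:
                    return layer.value_map[v]
            if kind == "constant":
                return payload
            if kind == "table":
                return payload[tuple(x)]
            raise ValueError("input escaped an exhaustive layer chain")

        return DiscreteFunction.from_callable(self.k, self.m, fn)


def nested_canalization(f: DiscreteFunction) -> NestedCanalization:
    """Greedy layer peeling of canalizing structure.

    At each layer the canalizing value set of every unused variable is the
    maximal set of values that force the output on the current residual
    domain.  The layer variable is the one with the largest such set, ties
    broken by lowest index.  When *every* value of a variable is forcing
    (the residual depends on that variable alone), the largest value is
    dropped so that S_in stays a proper subset of M; the dropped branch is
    peeled at the next layer or ends up in a constant residual.  For m = 2
    this reduces to the classical nested-canalizing chain with singleton
    canalizing/canalized values.
    """
    active = [x for x in f.inputs()]
    free = list(range(1, f.k + 1))
    layers = []
    depth = 0
    while True:
        outs = {f(x) for x in active}
        if len(outs) <= 1:
            residual = ("constant", outs.pop()) if outs else ("empty", None)
            return NestedCanalization(layers, residual, f.k, f.m)
        best = None
        for v in free:
            vmap = {}
            for a in range(f.m):
                slice_outs = {f(x) for x in active if x[v - 1] == a}
                if len(slice_outs) == 1:
                    vmap[a] = slice_outs.pop()
            if len(vmap) == f.m:
                # keep S_in a proper subset: release the largest value
                del vmap[max(vmap)]
            if vmap and (best is None or len(vmap) > len(best[1])):
                best = (v, vmap)
        if best is None:
            residual = ("table", {tuple(x): f(x) for x in active})
            return NestedCanalization(layers, residual, f.k, f.m)
        v, vmap = best
        depth += 1
        layers.append(CanalizationLayer(v, dict(vmap), depth))
        active = [x for x in active if x[v - 1] not in vmap]
        free.remove(v)


# ---------------------------------------------------------------------------
# Edge signs / monotonicity
# ---------------------------------------------------------------------------

class EdgeSign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    HYBRID = "hybrid"
    NULL = "null"

    @property
    def symbol(self) -> str:
        return {"positive": "+", "negative": "-",
                "hybrid": "?", "null": "0"}[self.value]


def edge_sign(f: DiscreteFunction, i: int) -> EdgeSign:
    """Sign of input i (1-based): positive if raising x_i never lowers the
    output (and raises it somewhere), negative for the mirror case, null if
    x_i never matters, hybrid otherwise."""
    if not (1 <= i <= f.k):
        raise ValueError(f"variable index {i} out of range 1..{f.k}")
    up = down = False
    for ctx in itertools.product(range(f.m), repeat=f.k - 1):
        x = list(ctx[: i - 1]) + [0] + list(ctx[i - 1:])
        for a, b in itertools.combinations(range(f.m), 2):
            x[i - 1] = a
            fa = f(x)
            x[i - 1] = b
            fb = f(x)
            if fa < fb:
                up = True
            elif fa > fb:
                down = True
    if not up and not down:
        return EdgeSign.NULL
    if up and down:
        return EdgeSign.HYBRID
    return EdgeSign.POSITIVE if up else EdgeSign.NEGATIVE


def is_monotone(f: DiscreteFunction, direction: str = "increasing") -> bool:
    """True iff every input acts consistently in the given direction
    (constant-in-a-variable inputs count vacuously)."""
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    bad = EdgeSign.NEGATIVE if direction == "increasing" else EdgeSign.POSITIVE
    for i in range(1, f.k + 1):
        s = edge_sign(f, i)
        if s is bad or s is EdgeSign.HYBRID:
            return False
    return True


# ---------------------------------------------------------------------------
# Dominant (weighted-majority) rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominantForm:
    """Weighted state-count witness: output = argmax_s sum_{x_i=s} w_i + theta_s.

    Weights are integers (exact arithmetic); a valid form has a *strict*
    argmax on every input.
    """

    weights: tuple
    baselines: tuple

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def m(self) -> int:
        return len(self.baselines)

    def scores(self, x: Sequence[int]) -> list:
        sc = list(self.baselines)
        for i, v in enumerate(x):
            sc[v] += self.weights[i]
        return sc

    def __call__(self, x: Sequence[int]) -> int:
        sc = self.scores(x)
        top = max(sc)
        if sc.count(top) != 1:
            raise ValueError(f"tied argmax at input {tuple(x)}")
        return sc.index(top)


def detect_dominant(f: DiscreteFunction):
    """Exact witness search for the weighted-majority class.

    Poses one linear feasibility problem: for every input the winning
    state's score must exceed each loser's by at least 1.  The float LP
    solution (HiGHS) is scaled to integers and re-verified exactly against
    the whole table; returns the witness or None when infeasible.
    """
    k, m = f.k, f.m
    nvar = k + m  # w_1..w_k, theta_0..theta_{m-1}
    rows, rhs = [], []
    for x in f.inputs():
        winner = f(x)
        for s in range(m):
            if s == winner:
                continue
            row = [0.0] * nvar
            for i, v in enumerate(x):
                if v == s:
                    row[i] += 1.0
                if v == winner:
                    row[i] -= 1.0
            row[k + s] += 1.0
            row[k + winner] -= 1.0
            rows.append(row)
            rhs.append(-1.0)
    if not rows:  # k == 0 or m == 1 corner; constant rule is trivially dominant
        return DominantForm((), tuple(1 if s == f.table[0] else 0
                                      for s in range(m)))
    res = linprog(c=[0.0] * nvar, A_ub=np.array(rows), b_ub=np.array(rhs),
                  bounds=[(-1e6, 1e6)] * nvar, method="highs")
    if not res.success:
        return None
    sol = [int(round(v * RATIONAL_SCALE)) for v in res.x]
    form = DominantForm(tuple(sol[:k]), tuple(sol[k:]))
    for x in f.inputs():
        sc = form.scores(x)
        top = max(sc)
        if sc.count(top) != 1 or sc.index(top) != f(x):
            return None  # rounding destroyed the witness (margin makes this
            # practically impossible); report as not detected
    return form


# ---------------------------------------------------------------------------
# Random rule generation
# ---------------------------------------------------------------------------

def random_function(k: int, m: int, kind: str = "uniform", *, seed: int,
                    layers: int = 1, canalizing_values: int = 1,
                    weight_range: int = 5) -> DiscreteFunction:
    """Draw a random rule from one of the paradigm classes.

    kind:
        ``uniform``     -- every table entry i.i.d. uniform on M.
        ``canalizing``  -- ``layers`` nested layers, each with
                           ``canalizing_values`` forcing values (must be
                           <= m-1 so every layer leaves a residual);
                           the residual subtable is filled uniformly.
        ``threshold``   -- integer weights in [-weight_range, weight_range]
                           \\ {0}, cut points at midpoints of realized sums.
        ``dominant``    -- random real weights/baselines, strict argmax.

    The seed is mandatory; identical parameters and seed give identical
    tables.
    """
    if k < 1 and kind != "uniform":
        raise ValueError("structured kinds need k >= 1")
    rng = _random.Random(seed)
    if kind == "uniform":
        table = tuple(rng.randrange(m) for _ in range(m ** k))
        return DiscreteFunction(k, m, table)

    if kind == "canalizing":
        if layers > k:
            raise ValueError(f"cannot nest {layers} layers in {k} variables")
        if not (1 <= canalizing_values <= m - 1):
            raise ValueError("canalizing_values must be in 1..m-1")
        chain = rng.sample(range(1, k + 1), layers)
        vmaps = []
        for _ in chain:
            s_in = rng.sample(range(m), canalizing_values)
            vmaps.append({a: rng.randrange(m) for a in s_in})

        def fn(x):
            for v, vmap in zip(chain, vmaps):
                if x[v - 1] in vmap:
                    return vmap[x[v - 1]]
            return rng.randrange(m)

        return DiscreteFunction.from_callable(k, m, fn)

    if kind == "threshold":
        w = [rng.choice([c for c in range(-weight_range, weight_range + 1)
                         if c != 0]) for _ in range(k)]
        sums = sorted({sum(wi * xi for wi, xi in zip(w, x))
                       for x in itertools.product(range(m), repeat=k)})
        mids = [(a + b) / 2 for a, b in zip(sums, sums[1:])]
        # pad below the minimum so m-1 distinct cut points always exist
        lo = sums[0]
        while len(mids) < m - 1:
            lo -= 1
            mids.append(lo - 0.5)
        cuts = sorted(rng.sample(mids, m - 1))

        def fn(x):
            z = sum(wi * xi for wi, xi in zip(w, x))
            return sum(1 for t in cuts if z > t)

        return DiscreteFunction.from_callable(k, m, fn)

    if kind == "dominant":
        w = [rng.uniform(-1, 1) for _ in range(k)]
        theta = [rng.uniform(-1, 1) for _ in range(m)]

        def fn(x):
            sc = list(theta)
            for i, v in enumerate(x):
                sc[v] += w[i]
            return sc.index(max(sc))

        return DiscreteFunction.from_callable(k, m, fn)

    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Single-rule text format
# ---------------------------------------------------------------------------

def load_truth_table(text: str) -> DiscreteFunction:
    """Parse the truth-table text format.

    Header line ``k m``, then m**k rows.  Rows are either
    ``x1 x2 ... xk : f`` (coordinates validated against index order) or a
    bare output value per line.
    """
    lines = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError("empty truth-table text")
    head = lines[0].split()
    if len(head) != 2:
        raise ValueError("header must be 'k m'")
    k, m = int(head[0]), int(head[1])
    body = lines[1:]
    if len(body) != m ** k:
        raise ValueError(f"expected {m ** k} rows, got {len(body)}")
    table = []
    for rownum, (ln, x) in enumerate(
            zip(body, itertools.product(range(m), repeat=k))):
        if ":" in ln:
            coords, out = ln.split(":")
            got = tuple(int(t) for t in coords.split())
            if got != x:
                raise ValueError(
                    f"row {rownum}: coordinates {got} out of index order, "
                    f"expected {x}")
            table.append(int(out))
        else:
            table.append(int(ln))
    return DiscreteFunction(k, m, tuple(table))


def dump_truth_table(f: DiscreteFunction, coordinates: bool = True) -> str:
    lines = [f"{f.k} {f.m}"]
    for x in f.inputs():
        if coordinates:
            lines.append(" ".join(map(str, x)) + " : " + str(f(x)))
        else:
            lines.append(str(f(x)))
    return "\n".join(lines) + "\n"
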