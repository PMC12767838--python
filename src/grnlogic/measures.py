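"""Order parameters and algebraic conversions of discrete rules.

Sensitivity
    S = m^-k * sum_x sum_i sum_{j != x_i} [f(x) != f(x^(i,j))] / (m-1),
    the expected number of single-input perturbations that change the
    output.  Computed exactly (Fractions) over all m**k inputs.

Effectiveness
    Derived from the deterministic minimal prime-implicant covers Q_s.
    For each state x, contributions are averaged over the cover implicants
    of Q_{f(x)} that cover x:

        E_input = k - m^-k * sum_x avg_{q in C(x)} star_count(q)
        E_i     = m^-k * sum_x avg_{q in C(x)} [position i of q not *]

    so that E_input = sum_i E_i exactly and each E_i lies in [0, 1].
    Redundancy of input i is R_i = 1 - E_i.

Complexity
    C = sum_s |Q_s|, the total number of cover implicants.

Polynomial form
    Boolean rules have a unique real multilinear interpolating polynomial
    (Moebius transform over subcubes).  Multi-valued rules (m prime) have a
    unique mod-m algebraic normal form with per-variable exponents up to
    m-1, summed with the generalized XOR (addition mod m).

Threshold form
    Linear feasibility over weights, optional interaction monomials up to
    a requested order, and m-1 strictly increasing cut points; solved by
    LP with a separation margin of 1 and verified exactly after integer
    rationalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from . import minimize
from .core import RATIONAL_SCALE, DiscreteFunction

__all__ = [
    "EffectivenessReport",
    "PolynomialForm",
    "ThresholdForm",
    "UNDETERMINED",
    "sensitivity",
    "effectiveness",
    "complexity",
    "to_polynomial",
    "threshold_form",
    "boolean_to_multivalued",
]


class _Undetermined:
    """Sentinel: the feasibility solver failed (distinct from infeasible)."""

    def __repr__(self):
        return "UNDETERMINED"

    def __bool__(self):
        return False


UNDETERMINED = _Undetermined()


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

def sensitivity(f: DiscreteFunction) -> Fraction:
    total = 0
    for x in f.inputs():
        x = list(x)
        fx = f(x)
        for i in range(f.k):
            orig = x[i]
            for j in range(f.m):
                if j == orig:
                    continue
                x[i] = j
                if f(x) != fx:
                    total += 1
            x[i] = orig
    return Fraction(total, (f.m - 1) * f.m ** f.k)


def activity(f: DiscreteFunction, i: int) -> Fraction:
    """Per-variable term of the sensitivity sum: the probability (uniform
    inputs, uniform redraw of x_i) that perturbing input i flips the
    output."""
    if not (1 <= i <= f.k):
        raise ValueError(f"variable index {i} out of range")
    total = 0
    for x in f.inputs():
        x = list(x)
        fx = f(x)
        orig = x[i - 1]
        for j in range(f.m):
            if j != orig:
                x[i - 1] = j
                if f(x) != fx:
                    total += 1
        x[i - 1] = orig
    return Fraction(total, (f.m - 1) * f.m ** f.k)


# ---------------------------------------------------------------------------
# Effectiveness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectivenessReport:
    edge: tuple  # Fractions, one per input
    input_effectiveness: Fraction

    @property
    def redundancy(self) -> tuple:
        return tuple(1 - e for e in self.edge)

    def rounded(self, digits: int = 4) -> tuple:
        return tuple(round(float(e), digits) for e in self.edge)


def effectiveness(f: DiscreteFunction,
                  covers: Optional[minimize.CoverSet] = None
                  ) -> EffectivenessReport:
    if covers is None:
        covers = minimize.cover(f)
    n = f.m ** f.k
    edge = [Fraction(0)] * f.k
    star_sum = Fraction(0)
    for x in f.inputs():
        cx = [imp for imp in covers[f(x)] if imp.covers(x)]
        if not cx:
            raise ValueError(f"cover incomplete at {x}")
        star_sum += Fraction(sum(imp.star_count for imp in cx), len(cx))
        for i in range(f.k):
            hits = sum(1 for imp in cx if imp.pattern[i] is not None)
            edge[i] += Fraction(hits, len(cx))
    edge = tuple(e / n for e in edge)
    e_input = f.k - star_sum / n
    assert e_input == sum(edge)
    return EffectivenessReport(edge, e_input)


def complexity(f: DiscreteFunction,
               covers: Optional[minimize.CoverSet] = None) -> int:
    if covers is None:
        covers = minimize.cover(f)
    return sum(len(entry) for entry in covers.values())


# ---------------------------------------------------------------------------
# Polynomial form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolynomialForm:
    """Interpolating polynomial of a rule.

    ``kind`` is ``"multilinear"`` (Boolean, integer coefficients, ordinary
    arithmetic) or ``"mod-m"`` (coefficients in Z_m, evaluation and
    summation mod m).  ``coeffs`` maps exponent tuples (length k, entries
    in 0..m-1) to nonzero coefficients.
    """

    k: int
    m: int
    kind: str
    coeffs: Mapping[tuple, int]

    @property
    def highest_order(self) -> int:
        if not self.coeffs:
            return 0
        return max(sum(1 for e in exp if e) for exp in self.coeffs)

    def monomials(self) -> Dict[frozenset, int]:
        """Boolean view: {frozenset of 1-based variable indices: coefficient}."""
        if self.kind != "multilinear":
            raise ValueError("monomials() applies to the Boolean branch")
        return {frozenset(i + 1 for i, e in enumerate(exp) if e): c
                for exp, c in self.coeffs.items()}

    def __call__(self, x: Sequence[int]) -> int:
        total = 0
        for exp, c in self.coeffs.items():
            term = c
            for xi, e in zip(x, exp):
                if e:
                    term *= xi ** e
            total += term
        return total % self.m if self.kind == "mod-m" else total


def _mobius_boolean(f: DiscreteFunction) -> Dict[tuple, int]:
    coef = list(f.table)  # index bits follow the mixed-radix convention
    k = f.k
    for i in range(k):  # subtract the subfunction without variable i+1
        stride = 2 ** (k - 1 - i)
        for idx in range(2 ** k):
            if (idx // stride) % 2 == 1:
                coef[idx] -= coef[idx - stride]
    out = {}
    for idx, c in enumerate(coef):
        if c:
            exp = tuple((idx >> (k - 1 - i)) & 1 for i in range(k))
            out[exp] = c
    return out


def _inv_vandermonde_mod(m: int) -> list:
    """Inverse mod m of V[a, e] = a**e (m x m), m prime."""
    mat = [[pow(a, e, m) for e in range(m)] for a in range(m)]
    inv = [[1 if i == j else 0 for j in range(m)] for i in range(m)]
    for col in range(m):
        piv = next(r for r in range(col, m) if mat[r][col] % m)
        mat[col], mat[piv] = mat[piv], mat[col]
        inv[col], inv[piv] = inv[piv], inv[col]
        s = pow(mat[col][col], -1, m)
        mat[col] = [v * s % m for v in mat[col]]
        inv[col] = [v * s % m for v in inv[col]]
        for r in range(m):
            if r != col and mat[r][col]:
                fct = mat[r][col]
                mat[r] = [(v - fct * w) % m for v, w in zip(mat[r], mat[col])]
                inv[r] = [(v - fct * w) % m for v, w in zip(inv[r], inv[col])]
    return inv


def _is_prime(n: int) -> bool:
    return n >= 2 and all(n % d for d in range(2, int(n ** 0.5) + 1))


def _anf_mod_m(f: DiscreteFunction) -> Dict[tuple, int]:
    m, k = f.m, f.k
    if not _is_prime(m):
        raise ValueError(
            f"mod-m polynomial interpolation needs a prime base, got m={m}")
    inv = _inv_vandermonde_mod(m)
    coef = np.array(f.table, dtype=np.int64).reshape((m,) * k)
    invm = np.array(inv, dtype=np.int64)
    for axis in range(k):
        coef = np.tensordot(invm, np.moveaxis(coef, axis, 0), axes=(1, 0))
        coef = np.moveaxis(coef, 0, axis) % m
    out = {}
    for exp in itertools.product(range(m), repeat=k):
        c = int(coef[exp])
        if c:
            out[exp] = c
    return out


def to_polynomial(f: DiscreteFunction) -> PolynomialForm:
    """Unique interpolating polynomial of the rule (see module docstring)."""
    if f.m == 2:
        return PolynomialForm(f.k, 2, "multilinear", _mobius_boolean(f))
    return PolynomialForm(f.k, f.m, "mod-m", _anf_mod_m(f))


# ---------------------------------------------------------------------------
# Threshold form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdForm:
    """Step-function representation f(x) = Theta_m(sum-of-terms + offset).

    ``weights`` are the k first-order weights, ``interactions`` maps
    frozensets of 1-based indices (size >= 2) to weights, ``thresholds``
    are the m-1 strictly increasing cut points of the step function
    Theta(z) = #{t_j < z}.  All values are exact Fractions; evaluation
    reproduces the source table exactly.
    """

    weights: tuple
    offset: Fraction
    thresholds: tuple
    interactions: Mapping[frozenset, Fraction]
    order: int

    def score(self, x: Sequence[int]) -> Fraction:
        z = self.offset
        for w, xi in zip(self.weights, x):
            z += w * xi
        for idxs, w in self.interactions.items():
            term = w
            for i in idxs:
                term *= x[i - 1]
            z += term
        return z

    def __call__(self, x: Sequence[int]) -> int:
        z = self.score(x)
        return sum(1 for t in self.thresholds if z > t)


def threshold_form(f: DiscreteFunction, max_order: Optional[int] = None):
    """Search orders 1..max_order for a satisfiable threshold form.

    Returns the first satisfiable ThresholdForm (lowest order), None when
    every order up to max_order is infeasible, or UNDETERMINED on solver
    failure.  A form always exists at order k (the interpolating polynomial
    itself is a valid score), so max_order = k never returns None.
    """
    if max_order is None:
        max_order = max(f.k, 1)
    if not (1 <= max_order <= max(f.k, 1)):
        raise ValueError("max_order must be in 1..k")
    for order in range(1, max_order + 1):
        result = _threshold_at_order(f, order)
        if result is UNDETERMINED or result is not None:
            return result
    return None


def _threshold_at_order(f: DiscreteFunction, order: int):
    k, m = f.k, f.m
    subsets = [frozenset(c) for size in range(1, order + 1)
               for c in itertools.combinations(range(1, k + 1), size)]
    nsub = len(subsets)
    nvar = nsub + 1 + (m - 1)  # term weights, offset, cut points
    rows, rhs = [], []

    def score_row(x):
        row = [0.0] * nvar
        for j, idxs in enumerate(subsets):
            prod = 1
            for i in idxs:
                prod *= x[i - 1]
            row[j] = float(prod)
        row[nsub] = 1.0  # offset
        return row

    for x in f.inputs():
        s = f(x)
        base = score_row(x)
        if s >= 1:  # z >= t_s + 1
            row = [-v for v in base]
            row[nsub + 1 + (s - 1)] += 1.0
            rows.append(row)
            rhs.append(-1.0)
        if s <= m - 2:  # z <= t_{s+1}
            row = list(base)
            row[nsub + 1 + s] -= 1.0
            rows.append(row)
            rhs.append(0.0)
    for j in range(m - 2):  # t_j + 1 <= t_{j+1}
        row = [0.0] * nvar
        row[nsub + 1 + j] = 1.0
        row[nsub + 1 + j + 1] = -1.0
        rows.append(row)
        rhs.append(-1.0)
    res = linprog(c=[0.0] * nvar, A_ub=np.array(rows), b_ub=np.array(rhs),
                  bounds=[(-1e7, 1e7)] * nvar, method="highs")
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        return UNDETERMINED
    sol = [Fraction(int(round(v * RATIONAL_SCALE)), RATIONAL_SCALE)
           for v in res.x]
    weights = [Fraction(0)] * k
    interactions = {}
    for j, idxs in enumerate(subsets):
        if len(idxs) == 1:
            weights[next(iter(idxs)) - 1] = sol[j]
        elif sol[j]:
            interactions[idxs] = sol[j]
    form = ThresholdForm(tuple(weights), sol[nsub],
                         tuple(sol[nsub + 1:]), interactions, order)
    for x in f.inputs():
        if form(x) != f(x):
            return UNDETERMINED  # rationalization failed (margin makes this
            # practically impossible)
    return form


# ---------------------------------------------------------------------------
# Boolean -> multi-valued embedding
# ---------------------------------------------------------------------------

def boolean_to_multivalued(f: DiscreteFunction, m_target: int,
                           value_map: Optional[Mapping[int, int]] = None,
                           binarize: str = "floor") -> DiscreteFunction:
    """Embed a Boolean rule into a larger alphabet.

    ``value_map`` sends the Boolean levels {0, 1} to target levels
    (default {0: 0, 1: m_target - 1}).  Intermediate input levels are
    binarized to the nearer mapped corner; exact midpoints go to the
    0-corner under ``binarize="floor"`` and to the 1-corner under
    ``"ceil"``.  The result agrees with f on mapped Boolean corners.
    """
    if f.m != 2:
        raise ValueError("source rule must be Boolean")
    if m_target <= 2:
        raise ValueError("m_target must exceed 2")
    if binarize not in ("floor", "ceil"):
        raise ValueError("binarize must be 'floor' or 'ceil'")
    vmap = dict(value_map) if value_map is not None else {0: 0,
                                                          1: m_target - 1}
    if set(vmap) != {0, 1}:
        raise ValueError("value_map must map exactly {0, 1}")
    lo, hi = vmap[0], vmap[1]
    if not all(0 <= v < m_target for v in (lo, hi)):
        raise ValueError("mapped corner values outside target alphabet")

    def to_bit(v: int) -> int:
        d0, d1 = abs(v - lo), abs(v - hi)
        if d0 == d1:
            return 0 if binarize == "floor" else 1
        return 0 if d0 < d1 else 1

    def fn(x):
        return vmap[f([to_bit(v) for v in x])]

    return DiscreteFunction.from_callable(f.k, m_target, fn, f.input_names)
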