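"""Logical-network model, file formats, random generation and rule census.

A :class:`LogicNetwork` holds named nodes, each with an ordered regulator
list and a :class:`~grnlogic.core.DiscreteFunction` whose arity equals the
regulator count; the alphabet base ``m`` is shared network-wide.  Nodes
that are referenced as regulators but never defined are *external inputs*:
they carry no rule and hold their state during simulation.

Supported formats
-----------------
* expression files -- one rule per line, ``NAME = expr`` with AND/OR/NOT
  written as words (any case) or ``& | !``, plus parentheses;
* per-node truth-table files;
* threshold-model edge lists -- rows ``input  output  type`` with type 1
  for activation and 2 for repression;
* edge-list TSV export with signs, and a JSON serialization.
"""

from __future__ import annotations

import json
import math
import random as _random
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import measures, minimize
from .core import DiscreteFunction, EdgeSign, edge_sign, nested_canalization, \
    random_function

__all__ = [
    "LogicNetwork",
    "NodeCensusRow",
    "ParseError",
    "parse_expressions",
    "parse_truth_tables",
    "parse_threshold_model",
    "export_edges",
    "edges_tsv",
    "generate_kauffman",
    "census",
]

ARITY_CAP = 16


class ParseError(ValueError):
    pass


class LogicNetwork:
    """Named nodes with per-node regulator lists and update rules.

    ``functions[name]`` is None exactly for external-input nodes (zero
    regulators, no rule).  Out-edges are derived from in-edges on demand
    and therefore always their transpose.
    """

    def __init__(self, names: Sequence[str],
                 regulators: Dict[str, Sequence[str]],
                 functions: Dict[str, Optional[DiscreteFunction]],
                 m: int = 2, metadata: Optional[dict] = None):
        self.names = list(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate node names")
        self.regulators = {n: list(regulators.get(n, [])) for n in self.names}
        self.functions = {n: functions.get(n) for n in self.names}
        self.m = m
        self.metadata = dict(metadata or {})
        self._validate()

    def _validate(self):
        known = set(self.names)
        for n in self.names:
            regs = self.regulators[n]
            missing = [r for r in regs if r not in known]
            if missing:
                raise ValueError(f"node {n}: unresolved regulators {missing}")
            f = self.functions[n]
            if f is None:
                if regs:
                    raise ValueError(
                        f"node {n}: has regulators but no rule")
            else:
                if f.k != len(regs):
                    raise ValueError(
                        f"node {n}: rule arity {f.k} != {len(regs)} regulators")
                if f.m != self.m:
                    raise ValueError(f"node {n}: rule base {f.m} != {self.m}")

    # -- topology ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.names)

    def is_input(self, name: str) -> bool:
        return self.functions[name] is None

    @property
    def input_nodes(self) -> list:
        return [n for n in self.names if self.is_input(n)]

    def out_edges(self) -> Dict[str, list]:
        out = {n: [] for n in self.names}
        for tgt in self.names:
            for src in self.regulators[tgt]:
                out[src].append(tgt)
        return out

    def edges(self) -> list:
        return [(src, tgt) for tgt in self.names
                for src in self.regulators[tgt]]

    def copy(self) -> "LogicNetwork":
        return LogicNetwork(self.names, self.regulators, self.functions,
                            self.m, self.metadata)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "m": self.m,
            "metadata": self.metadata,
            "nodes": [
                {"name": n,
                 "regulators": self.regulators[n],
                 "table": (list(self.functions[n].table)
                           if self.functions[n] is not None else None)}
                for n in self.names
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LogicNetwork":
        doc = json.loads(text)
        names, regulators, functions = [], {}, {}
        for node in doc["nodes"]:
            n = node["name"]
            names.append(n)
            regulators[n] = node["regulators"]
            if node["table"] is None:
                functions[n] = None
            else:
                functions[n] = DiscreteFunction(
                    len(node["regulators"]), doc["m"], tuple(node["table"]))
        return cls(names, regulators, functions, doc["m"],
                   doc.get("metadata"))


# ---------------------------------------------------------------------------
# Expression parser
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|&{1,2}|\|{1,2}|!|[A-Za-z0-9_.\-]+)")


def _tokenize(expr: str, lineno: int) -> list:
    tokens, pos = [], 0
    while pos < len(expr):
        mobj = _TOKEN.match(expr, pos)
        if not mobj:
            raise ParseError(f"line {lineno}: cannot tokenize near "
                             f"{expr[pos:pos + 10]!r}")
        tok = mobj.group(1)
        low = tok.lower()
        if low == "and" or tok in ("&", "&&"):
            tokens.append(("AND", tok))
        elif low == "or" or tok in ("|", "||"):
            tokens.append(("OR", tok))
        elif low == "not" or tok == "!":
            tokens.append(("NOT", tok))
        elif tok == "(":
            tokens.append(("LP", tok))
        elif tok == ")":
            tokens.append(("RP", tok))
        elif low in ("0", "1", "true", "false"):
            tokens.append(("CONST", 1 if low in ("1", "true") else 0))
        else:
            tokens.append(("NAME", tok))
        pos = mobj.end()
    return tokens


class _ExprParser:
    """Recursive descent, precedence NOT > AND > OR."""

    def __init__(self, tokens, lineno):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _take(self, kind=None):
        tok = self._peek()
        if tok is None or (kind is not None and tok[0] != kind):
            raise ParseError(f"line {self.lineno}: unexpected "
                             f"{'end of line' if tok is None else tok[1]!r}")
        self.pos += 1
        return tok

    def parse(self):
        node = self._or()
        if self._peek() is not None:
            raise ParseError(f"line {self.lineno}: trailing tokens after "
                             f"expression")
        return node

    def _or(self):
        node = self._and()
        while self._peek() and self._peek()[0] == "OR":
            self._take()
            node = ("or", node, self._and())
        return node

    def _and(self):
        node = self._unary()
        while self._peek() and self._peek()[0] == "AND":
            self._take()
            node = ("and", node, self._unary())
        return node

    def _unary(self):
        tok = self._peek()
        if tok is None:
            raise ParseError(f"line {self.lineno}: unexpected end of line")
        if tok[0] == "NOT":
            self._take()
            return ("not", self._unary())
        if tok[0] == "LP":
            self._take()
            node = self._or()
            self._take("RP")
            return node
        if tok[0] == "CONST":
            self._take()
            return ("const", tok[1])
        if tok[0] == "NAME":
            self._take()
            return ("var", tok[1])
        raise ParseError(f"line {self.lineno}: unexpected {tok[1]!r}")


def _ast_vars(node, acc):
    kind = node[0]
    if kind == "var":
        if node[1] not in acc:
            acc.append(node[1])
    elif kind == "not":
        _ast_vars(node[1], acc)
    elif kind in ("and", "or"):
        _ast_vars(node[1], acc)
        _ast_vars(node[2], acc)


def _ast_eval(node, env):
    kind = node[0]
    if kind == "var":
        return env[node[1]]
    if kind == "const":
        return node[1]
    if kind == "not":
        return 1 - _ast_eval(node[1], env)
    a = _ast_eval(node[1], env)
    b = _ast_eval(node[2], env)
    return (a & b) if kind == "and" else (a | b)


def parse_expressions(text: str, arity_cap: int = ARITY_CAP) -> LogicNetwork:
    """Build a Boolean network from ``NAME = expr`` lines.

    Regulator order is the order of first appearance in the expression;
    the truth table is built by exhaustive evaluation.  Genes referenced
    but never defined become external-input nodes.  Variables that never
    change the output (e.g. ``B = X or not X``) are still recorded as
    regulators.
    """
    defined: Dict[str, tuple] = {}
    order: List[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected 'NAME = expression'")
        name, expr = line.split("=", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z0-9_.\-]+", name):
            raise ParseError(f"line {lineno}: bad gene name {name!r}")
        if name in defined:
            raise ParseError(f"line {lineno}: duplicate definition of {name}")
        ast = _ExprParser(_tokenize(expr, lineno), lineno).parse()
        regs: List[str] = []
        _ast_vars(ast, regs)
        if len(regs) > arity_cap:
            raise ParseError(
                f"line {lineno}: {name} has {len(regs)} regulators, "
                f"exceeding the arity cap of {arity_cap} "
                f"(table would need 2**{len(regs)} rows)")
        defined[name] = (regs, ast)
        order.append(name)

    names = list(order)
    referenced = [r for name in order for r in defined[name][0]]
    for r in referenced:
        if r not in defined and r not in names:
            names.append(r)  # external input
    regulators, functions = {}, {}
    for n in names:
        if n in defined:
            regs, ast = defined[n]
            regulators[n] = regs
            functions[n] = DiscreteFunction.from_callable(
                len(regs), 2,
                lambda x, regs=regs, ast=ast:
                    _ast_eval(ast, dict(zip(regs, x))),
                tuple(regs))
        else:
            regulators[n] = []
            functions[n] = None
    return LogicNetwork(names, regulators, functions, 2)


# ---------------------------------------------------------------------------
# Truth-table parser
# ---------------------------------------------------------------------------

def parse_truth_tables(text: str, m: int = 2) -> LogicNetwork:
    """Build a network from per-node truth-table blocks.

    Each block starts with ``NAME <- REG1 REG2 ...`` (no regulators for a
    constant node) followed by the m**k table rows in the single-rule text
    format: either ``x1 ... xk : f`` rows (validated against index order)
    or bare output values.  Blank lines and ``#`` comments separate blocks.
    """
    lines = [ln.split("#", 1)[0].rstrip() for ln in text.splitlines()]
    blocks: List[Tuple[int, str, List[str], List[str]]] = []
    current = None
    for lineno, ln in enumerate(lines, start=1):
        s = ln.strip()
        if not s:
            continue
        if "<-" in s:
            name, rest = s.split("<-", 1)
            current = (lineno, name.strip(), rest.split(), [])
            blocks.append(current)
        else:
            if current is None:
                raise ParseError(
                    f"line {lineno}: table row before any 'NAME <- ...' header")
            current[3].append(s)

    names, regulators, functions = [], {}, {}
    for lineno, name, regs, rows in blocks:
        if name in functions:
            raise ParseError(f"line {lineno}: duplicate definition of {name}")
        k = len(regs)
        expected = m ** k
        if len(rows) != expected:
            raise ParseError(
                f"line {lineno}: node {name} needs {expected} table rows, "
                f"got {len(rows)}")
        import itertools as _it
        table = []
        for row, x in zip(rows, _it.product(range(m), repeat=k)):
            if ":" in row:
                coords, out = row.split(":")
                got = tuple(int(t) for t in coords.split())
                if got != x:
                    raise ParseError(
                        f"node {name}: row coordinates {got} out of index "
                        f"order, expected {x}")
                table.append(int(out))
            else:
                table.append(int(row))
        names.append(name)
        regulators[name] = regs
        functions[name] = DiscreteFunction(k, m, tuple(table), tuple(regs))
    for _, name, regs, _rows in blocks:
        for r in regs:
            if r not in functions and r not in names:
                names.append(r)
                regulators[r] = []
                functions[r] = None
    return LogicNetwork(names, regulators, functions, m)


# ---------------------------------------------------------------------------
# Threshold-model parser
# ---------------------------------------------------------------------------

def parse_threshold_model(rows, tie: str = "zero") -> LogicNetwork:
    """Build a Boolean network from (input, output, type) edges.

    Type 1 is activation, type 2 repression.  A node switches on when
    active activators outnumber active repressors.  Ties follow the
    ``tie`` mode: ``"zero"`` (default) forces output 0; ``"retain"`` keeps
    the node's current state, realized by adding the node itself as an
    explicit input of its own table.
    """
    if tie not in ("zero", "retain"):
        raise ValueError("tie must be 'zero' or 'retain'")
    if isinstance(rows, str):
        parsed = []
        for lineno, ln in enumerate(rows.splitlines(), start=1):
            s = ln.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) != 3:
                raise ParseError(
                    f"line {lineno}: expected 'input output type'")
            parsed.append((parts[0], parts[1], int(parts[2])))
        rows = parsed
    incoming: Dict[str, List[Tuple[str, int]]] = {}
    seen: List[str] = []
    for src, tgt, typ in rows:
        if typ not in (1, 2):
            raise ParseError(f"unknown edge type {typ} on {src} -> {tgt} "
                             f"(1 = activation, 2 = repression)")
        incoming.setdefault(tgt, []).append((src, typ))
        for n in (src, tgt):
            if n not in seen:
                seen.append(n)

    names, regulators, functions = [], {}, {}
    for n in seen:
        names.append(n)
        if n not in incoming:
            regulators[n] = []
            functions[n] = None
            continue
        regs = []
        signs = []
        for src, typ in incoming[n]:
            if src in regs:
                raise ParseError(f"duplicate edge {src} -> {n}")
            regs.append(src)
            signs.append(1 if typ == 1 else -1)
        self_pos = None
        if tie == "retain":
            if n in regs:
                self_pos = regs.index(n)
            else:
                regs = regs + [n]
                signs = signs + [0]
                self_pos = len(regs) - 1

        def fn(x, signs=signs, self_pos=self_pos):
            total = sum(s * v for s, v in zip(signs, x))
            if total > 0:
                return 1
            if total < 0:
                return 0
            return x[self_pos] if self_pos is not None else 0

        regulators[n] = regs
        functions[n] = DiscreteFunction.from_callable(
            len(regs), 2, fn, tuple(regs))
    net = LogicNetwork(names, regulators, functions, 2)
    net.metadata["tie_rule"] = tie
    return net


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_edges(net: LogicNetwork) -> list:
    """One row (source, target, sign symbol) per resolved edge; signs come
    from the target rule (+, -, ? hybrid, 0 no influence)."""
    rows = []
    for tgt in net.names:
        f = net.functions[tgt]
        for pos, src in enumerate(net.regulators[tgt], start=1):
            rows.append((src, tgt, edge_sign(f, pos).symbol))
    return rows


def edges_tsv(net: LogicNetwork) -> str:
    lines = ["source\ttarget\tsign"]
    lines += [f"{s}\t{t}\t{sign}" for s, t, sign in export_edges(net)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Random Kauffman-style generation
# ---------------------------------------------------------------------------

def generate_kauffman(N: int, K: int, m: int = 2,
                      paradigm: str = "uniform", *, seed: int,
                      allow_self: bool = False,
                      **paradigm_params) -> LogicNetwork:
    """Random network: every node wired to K distinct regulators drawn
    uniformly (self-edges excluded by default), rules drawn from the
    requested paradigm class via :func:`grnlogic.core.random_function`."""
    if N < 1:
        raise ValueError("N must be positive")
    if not (1 <= K < N):
        raise ValueError(f"need 1 <= K < N, got K={K}, N={N}")
    rng = _random.Random(seed)
    width = len(str(N))
    names = [f"g{str(i).zfill(width)}" for i in range(1, N + 1)]
    regulators, functions = {}, {}
    for name in names:
        pool = names if allow_self else [x for x in names if x != name]
        regs = rng.sample(pool, K)
        regulators[name] = regs
        functions[name] = random_function(
            K, m, paradigm, seed=rng.randrange(2 ** 31), **paradigm_params)
    return LogicNetwork(names, regulators, functions, m)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeCensusRow:
    name: str
    canalizing: Optional[bool]
    signed: Optional[bool]
    threshold: Optional[bool]
    dominant: Optional[bool]
    sensitivity: Optional[Fraction]
    input_effectiveness: Optional[Fraction]
    complexity: Optional[int]


def census(net: LogicNetwork, check_threshold: bool = True,
           check_dominant: bool = True) -> list:
    """Per-node paradigm classification plus the three order parameters.

    ``signed`` means every input acts sign-definitely (no hybrid edge);
    ``threshold`` tests order-1 (linear) realizability; both witness
    searches can be skipped for speed on large rules.  External-input
    nodes report None throughout.
    """
    from .core import detect_dominant
    from .measures import UNDETERMINED, threshold_form

    rows = []
    for name in net.names:
        f = net.functions[name]
        if f is None:
            rows.append(NodeCensusRow(name, None, None, None, None,
                                      None, None, None))
            continue
        covers = minimize.cover(f)
        signs = [edge_sign(f, i) for i in range(1, f.k + 1)]
        signed = all(s is not EdgeSign.HYBRID for s in signs)
        thresh = None
        if check_threshold:
            form = threshold_form(f, max_order=1) if f.k else None
            thresh = (None if form is UNDETERMINED
                      else form is not None) if f.k else True
        dom = None
        if check_dominant:
            dom = detect_dominant(f) is not None
        rows.append(NodeCensusRow(
            name,
            bool(nested_canalization(f)) or f.is_constant(),
            signed,
            thresh,
            dom,
            measures.sensitivity(f),
            measures.effectiveness(f, covers).input_effectiveness,
            measures.complexity(f, covers)))
    return rows
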