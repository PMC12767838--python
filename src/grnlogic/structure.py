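"""Static architecture analysis of logical networks.

The reduction pipeline mirrors how regulatory signal actually propagates:

* *clamping* fixes nodes whose rule is constant or whose regulators are
  all fixed, substituting their value downstream (arity shrinks);
* *pruning* removes terminal nodes (regulate nothing non-static) and, in
  later rounds, relay nodes whose targets were all removed; what remains
  are the relevant components;
* *FFL decoupling* substitutes an intermediary's rule into its target
  (f_S(P, I) -> f_S(P, f_I(P))), removing intermediaries that only relay
  information already carried by their predecessors; iterating clamp /
  prune / decouple to a fixed point yields the dynamic core components.

Feedback-loop enumeration decomposes the graph into strongly connected
components and runs Johnson's simple-cycle algorithm inside each true SCC
(no heuristics; a configurable cap guards against cycle explosions).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from . import measures
from .core import DiscreteFunction, EdgeSign, edge_sign
from .network import LogicNetwork

__all__ = [
    "ComponentReport",
    "LoopReport",
    "clamp_static",
    "prune_relevant",
    "decouple_ffl",
    "core_components",
    "feedback_loops",
]

LABELS = ("static", "terminal", "relay", "external-input", "core",
          "peripheral")

MAX_FFL_PREDECESSORS = 6
DEFAULT_CYCLE_CAP = 10 ** 6


@dataclass
class ComponentReport:
    """Node classification and the reduced network it leaves behind."""

    labels: Dict[str, str]
    reduced: LogicNetwork
    static_values: Dict[str, int] = field(default_factory=dict)

    @property
    def counts(self) -> Dict[str, int]:
        out = {lab: 0 for lab in LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def nodes(self, label: str) -> list:
        return [n for n, lab in self.labels.items() if lab == label]


# ---------------------------------------------------------------------------
# Clamping
# ---------------------------------------------------------------------------

def clamp_static(net: LogicNetwork):
    """Fix every node whose value is forced, substitute downstream.

    A node is static when its rule is constant or when all of its
    regulators are already static (its rule then evaluates to a constant).
    External inputs are never static -- their value is undetermined.
    Returns ``(reduced network, {static node: value})``; in the reduced
    network static regulators are substituted into downstream tables,
    shrinking their arity.
    """
    static: Dict[str, int] = {}
    current: Dict[str, Tuple[list, Optional[DiscreteFunction]]] = {
        n: (list(net.regulators[n]), net.functions[n]) for n in net.names}
    changed = True
    while changed:
        changed = False
        for n in net.names:
            if n in static:
                continue
            regs, f = current[n]
            if f is None:
                continue
            fixed = {i + 1: static[r] for i, r in enumerate(regs)
                     if r in static}
            if fixed:
                f = f.restrict(fixed)
                regs = [r for r in regs if r not in static]
                current[n] = (regs, f)
            if f.is_constant():
                static[n] = f.table[0]
                changed = True
    names = [n for n in net.names if n not in static]
    regulators = {n: current[n][0] for n in names}
    functions = {n: current[n][1] for n in names}
    reduced = LogicNetwork(names, regulators, functions, net.m, net.metadata)
    return reduced, static


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _prune_rounds(net: LogicNetwork):
    """Iteratively strip nodes with no surviving targets.

    Returns (removed-in-round-1, removed-later, survivors).  External
    inputs are never removed here; they are classified separately.
    """
    alive = set(n for n in net.names)
    terminal: List[str] = []
    relay: List[str] = []
    first = True
    while True:
        out = {n: [] for n in alive}
        for tgt in alive:
            for src in net.regulators[tgt]:
                if src in alive:
                    out[src].append(tgt)
        doomed = [n for n in alive
                  if not net.is_input(n) and not out[n]]
        if not doomed:
            break
        (terminal if first else relay).extend(doomed)
        alive -= set(doomed)
        first = False
    return terminal, relay, [n for n in net.names if n in alive]


def _drop_dead_inputs(net: LogicNetwork) -> LogicNetwork:
    """Remove external inputs that regulate nothing that survived."""
    out = net.out_edges()
    keep = [n for n in net.names if not net.is_input(n) or out[n]]
    return LogicNetwork(keep, {n: net.regulators[n] for n in keep},
                        {n: net.functions[n] for n in keep},
                        net.m, net.metadata)


def prune_relevant(net: LogicNetwork) -> ComponentReport:
    """Relevant components: the network minus static, terminal and relay
    nodes.

    Clamps first, then removes nodes round by round: nodes with no
    non-static targets fall in round 1 (terminal), nodes stranded by those
    removals fall later (relay).  Edges pointing only at removed nodes
    disappear with their sources.  Idempotent: rerunning on the reduced
    network changes nothing.
    """
    clamped, static = clamp_static(net)
    terminal, relay, survivors = _prune_rounds(clamped)
    labels = {}
    for n, _v in static.items():
        labels[n] = "static"
    for n in terminal:
        labels[n] = "terminal"
    for n in relay:
        labels[n] = "relay"
    keep = set(survivors)
    names = [n for n in clamped.names if n in keep]
    reduced = LogicNetwork(
        names, {n: clamped.regulators[n] for n in names},
        {n: clamped.functions[n] for n in names}, net.m, net.metadata)
    reduced = _drop_dead_inputs(reduced)
    for n in net.names:
        if n not in labels:
            labels[n] = ("external-input" if net.is_input(n)
                         else "core")
    # inputs dropped from the reduced net keep their external-input label
    return ComponentReport(labels, reduced, static)


# ---------------------------------------------------------------------------
# FFL decoupling
# ---------------------------------------------------------------------------

def decouple_ffl(net: LogicNetwork, P: Sequence[str], I: str, S: str):
    """Substitute intermediary I's rule into target S (Eq. f_S(P, f_I(P))).

    Preconditions: I's regulators lie inside P, S is regulated by a subset
    of P plus I, and I is not its own regulator.  Returns the reduced rule
    f'_S of arity |P| (S's dependence on I is eliminated by construction),
    or None when the preconditions fail.
    """
    P = list(P)
    if I not in net.names or S not in net.names or I == S or I in P:
        return None
    f_I, f_S = net.functions.get(I), net.functions.get(S)
    if f_I is None or f_S is None:
        return None
    regs_I, regs_S = net.regulators[I], net.regulators[S]
    if I in regs_I or I not in regs_S:
        return None
    if not set(regs_I) <= set(P):
        return None
    if not set(regs_S) <= set(P) | {I}:
        return None

    def fn(x):
        env = dict(zip(P, x))
        env[I] = f_I([env[r] for r in regs_I])
        return f_S([env[r] for r in regs_S])

    return DiscreteFunction.from_callable(len(P), net.m, fn, tuple(P))


def _drop_null_regulators(net: LogicNetwork, name: str) -> bool:
    """Remove influence-free regulators of one node; True if changed."""
    f = net.functions[name]
    if f is None or f.k == 0:
        return False
    null = [i for i in range(1, f.k + 1)
            if edge_sign(f, i) is EdgeSign.NULL]
    if not null:
        return False
    keep = [i for i in range(1, f.k + 1) if i not in null]
    # fixing null variables at 0 is value-free: the output ignores them
    net.functions[name] = f.restrict({i: 0 for i in null})
    net.regulators[name] = [net.regulators[name][i - 1] for i in keep]
    return True


def core_components(net: LogicNetwork) -> ComponentReport:
    """Dynamic core components: iterate clamping, pruning and FFL
    decoupling to a fixed point.

    Nodes removed by the first clamp/prune pass keep their static /
    terminal / relay labels; anything removed once decoupling starts
    rewiring the network is peripheral.  The survivors are the core.
    """
    labels: Dict[str, str] = {}
    static_values: Dict[str, int] = {}
    current = net.copy()
    first_pass = True
    for _round in range(10 * max(1, net.n)):  # decoupling always terminates
        # on real motifs; the bound guards pathological rewiring cycles
        clamped, static = clamp_static(current)
        static_values.update(static)
        for n in static:
            labels.setdefault(n, "static" if first_pass else "peripheral")
        rep = prune_relevant(clamped)
        for n in clamped.names:
            lab = rep.labels[n]
            if lab in ("terminal", "relay"):
                labels.setdefault(n, lab if first_pass else "peripheral")
        current = rep.reduced
        first_pass = False

        changed = False
        for I in list(current.names):
            if current.is_input(I):
                continue
            P = current.regulators[I]
            if not P or len(P) > MAX_FFL_PREDECESSORS or I in P:
                continue
            for S in current.out_edges()[I]:
                # a genuine feed-forward motif: the target is distinct from
                # the predecessors (no feedback through S) and shares at
                # least one direct predecessor edge with I
                if S == I or S in P:
                    continue
                if not set(current.regulators[S]) & set(P):
                    continue
                reduced_rule = decouple_ffl(current, P, I, S)
                if reduced_rule is None:
                    continue
                current.functions[S] = reduced_rule
                current.regulators[S] = list(P)
                _drop_null_regulators(current, S)
                changed = True
        if not changed:
            break
    else:
        warnings.warn("core-component iteration cap reached", RuntimeWarning)
    for n in net.names:
        if n not in labels:
            if net.is_input(n):
                labels[n] = "external-input"
            elif n in current.names:
                labels[n] = "core"
            else:
                labels[n] = "peripheral"
    # inputs may have been dropped inside the loop; rebuild cleanly
    current = _drop_dead_inputs(current)
    return ComponentReport(labels, current, static_values)


# ---------------------------------------------------------------------------
# Feedback loops
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeAttributes:
    sign: str
    activity: Fraction
    effectiveness: Fraction
    support: int


@dataclass
class LoopReport:
    """Simple cycles grouped by strongly connected component.

    ``cycles`` maps the loop name ``SCC<i>.<j>`` to the node sequence
    (rotation-normalized, smallest node first).  ``edge_signs`` and
    ``edge_attributes`` are filled according to the analysis mode.
    """

    cycles: Dict[str, tuple]
    length_histogram: Dict[int, int]
    mode: str
    truncated: bool = False
    edge_signs: Optional[Dict[str, tuple]] = None
    edge_attributes: Optional[Dict[tuple, EdgeAttributes]] = None


def _edge_sign_symbol(net: LogicNetwork, src: str, tgt: str) -> str:
    pos = net.regulators[tgt].index(src) + 1
    return edge_sign(net.functions[tgt], pos).symbol


def feedback_loops(net: LogicNetwork, mode: str = "loop",
                   max_cycles: int = DEFAULT_CYCLE_CAP) -> LoopReport:
    """Enumerate all feedback loops (simple directed cycles).

    mode:
        ``loop``      -- cycles and the length histogram;
        ``length``    -- same payload (the histogram is always computed);
        ``loopsign``  -- adds per-cycle edge sign symbols;
        ``edgeattr``  -- adds per-edge sign, activity (flip-influence
                         probability under uniform contexts), edge
                         effectiveness and support (number of loops through
                         the edge).
    """
    if mode not in ("loop", "length", "loopsign", "edgeattr"):
        raise ValueError(f"unknown mode {mode!r}")
    g = nx.DiGraph()
    g.add_nodes_from(net.names)
    g.add_edges_from(net.edges())
    sccs = sorted((sorted(c) for c in nx.strongly_connected_components(g)),
                  key=lambda c: c[0])
    cycles: Dict[str, tuple] = {}
    truncated = False
    scc_index = 0
    for comp in sccs:
        sub = g.subgraph(comp)
        if len(comp) == 1 and not sub.has_edge(comp[0], comp[0]):
            continue  # not a true SCC: no closed signal transfer
        scc_index += 1
        found = []
        for cyc in nx.simple_cycles(sub):
            pivot = cyc.index(min(cyc))
            found.append(tuple(cyc[pivot:] + cyc[:pivot]))
            if len(cycles) + len(found) >= max_cycles:
                warnings.warn(
                    f"cycle cap {max_cycles} reached; loop report truncated",
                    RuntimeWarning)
                truncated = True
                break
        found.sort(key=lambda c: (len(c), c))
        for j, cyc in enumerate(found, start=1):
            cycles[f"SCC{scc_index}.{j}"] = cyc
        if truncated:
            break
    hist: Dict[int, int] = {}
    for cyc in cycles.values():
        hist[len(cyc)] = hist.get(len(cyc), 0) + 1
    report = LoopReport(cycles, hist, mode, truncated)
    if mode in ("loopsign", "edgeattr"):
        report.edge_signs = {
            name: tuple(_edge_sign_symbol(net, cyc[i], cyc[(i + 1) % len(cyc)])
                        for i in range(len(cyc)))
            for name, cyc in cycles.items()}
    if mode == "edgeattr":
        support: Dict[tuple, int] = {}
        for cyc in cycles.values():
            for i in range(len(cyc)):
                e = (cyc[i], cyc[(i + 1) % len(cyc)])
                support[e] = support.get(e, 0) + 1
        attrs = {}
        eff_cache: Dict[str, tuple] = {}
        for (src, tgt), sup in support.items():
            f = net.functions[tgt]
            pos = net.regulators[tgt].index(src) + 1
            if tgt not in eff_cache:
                eff_cache[tgt] = measures.effectiveness(f).edge
            attrs[(src, tgt)] = EdgeAttributes(
                sign=edge_sign(f, pos).symbol,
                activity=measures.activity(f, pos),
                effectiveness=eff_cache[tgt][pos - 1],
                support=sup)
        report.edge_attributes = attrs
    return report
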