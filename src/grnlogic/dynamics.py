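"""State-space simulation of logical networks.

States are tuples of values in M, one per node in network name order.
External-input nodes hold their value under every update rule.

* synchronous / asynchronous stepping (plus a fast asynchronous mode that
  only draws among nodes whose update would change something);
* attractor sampling from random restarts with cycle extraction;
* Derrida damage spreading -- co-evolution of a trajectory and a
  perturbed twin, reporting the final normalized Hamming distance
  D = (1/n) sum_i [s_i != s'_i]; under asynchronous update both twins
  follow the *same* node-choice schedule so that update noise is not
  conflated with damage;
* percolation of stable components on square, hexagonal and triangular
  lattices (periodic horizontal, open vertical boundaries; spanning is
  tested top to bottom);
* preference analysis of a target node's states from the distribution of
  its regulators across sampled attractor states.
"""

from __future__ import annotations

import math
import random as _random
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .core import DiscreteFunction
from .network import LogicNetwork

__all__ = [
    "step",
    "random_state",
    "sample_attractors",
    "AttractorSample",
    "derrida_damage",
    "DamageResult",
    "lattice_network",
    "percolation",
    "PercolationResult",
    "preference_analysis",
    "PreferenceReport",
]

UPDATE_RULES = ("sync", "async-random", "async-fast")


def _node_update(net: LogicNetwork, state: tuple, idx: Dict[str, int],
                 name: str) -> int:
    f = net.functions[name]
    if f is None:
        return state[idx[name]]
    return f([state[idx[r]] for r in net.regulators[name]])


def _index(net: LogicNetwork) -> Dict[str, int]:
    return {n: i for i, n in enumerate(net.names)}


def step(net: LogicNetwork, state: Sequence[int], rule: str = "sync",
         rng: Optional[_random.Random] = None) -> tuple:
    """One update of the system state.

    ``sync`` updates every node simultaneously; ``async-random`` updates a
    single uniformly chosen (non-input) node; ``async-fast`` chooses
    uniformly among nodes whose update would change their value and is a
    no-op at a fixed point.  Asynchronous modes require a seeded
    ``random.Random``.
    """
    if rule not in UPDATE_RULES:
        raise ValueError(f"unknown update rule {rule!r}")
    state = tuple(state)
    idx = _index(net)
    if rule == "sync":
        return tuple(_node_update(net, state, idx, n) for n in net.names)
    if rng is None:
        raise ValueError("asynchronous update needs a seeded generator")
    movable = [n for n in net.names if not net.is_input(n)]
    if rule == "async-random":
        n = rng.choice(movable)
        new = list(state)
        new[idx[n]] = _node_update(net, state, idx, n)
        return tuple(new)
    updatable = [n for n in movable
                 if _node_update(net, state, idx, n) != state[idx[n]]]
    if not updatable:
        return state
    n = rng.choice(updatable)
    new = list(state)
    new[idx[n]] = _node_update(net, state, idx, n)
    return tuple(new)


def random_state(net: LogicNetwork, rng: _random.Random) -> tuple:
    return tuple(rng.randrange(net.m) for _ in net.names)


# ---------------------------------------------------------------------------
# Attractor sampling
# ---------------------------------------------------------------------------

@dataclass
class AttractorSample:
    """Distinct attractors found by random restarts (synchronous update).

    Each attractor is a tuple of states; fixed points have length one,
    cycles are rotation-normalized so the lexicographically smallest state
    comes first.  ``basin_hits`` counts restarts per attractor;
    ``unresolved`` counts trajectories that exhausted the horizon.
    """

    attractors: List[tuple]
    basin_hits: List[int]
    unresolved: int = 0

    @property
    def fixed_points(self) -> list:
        return [a[0] for a in self.attractors if len(a) == 1]

    @property
    def cycles(self) -> list:
        return [a for a in self.attractors if len(a) > 1]


def _canonical_cycle(states: Sequence[tuple]) -> tuple:
    pivot = states.index(min(states))
    return tuple(states[pivot:]) + tuple(states[:pivot])


def sample_attractors(net: LogicNetwork, samples: int, horizon: int = 1000,
                      *, seed: int) -> AttractorSample:
    """Synchronous trajectories from ``samples`` random initial states;
    a revisited state closes the trajectory and yields its attractor."""
    rng = _random.Random(seed)
    found: Dict[tuple, int] = {}
    unresolved = 0
    for _ in range(samples):
        state = random_state(net, rng)
        seen = {state: 0}
        path = [state]
        closed = None
        for t in range(1, horizon + 1):
            state = step(net, state, "sync")
            if state in seen:
                closed = _canonical_cycle(path[seen[state]:])
                break
            seen[state] = t
            path.append(state)
        if closed is None:
            unresolved += 1
        else:
            found[closed] = found.get(closed, 0) + 1
    attractors = sorted(found)
    return AttractorSample(attractors, [found[a] for a in attractors],
                          unresolved)


# ---------------------------------------------------------------------------
# Derrida damage spreading
# ---------------------------------------------------------------------------

@dataclass
class DamageResult:
    """Final normalized distances from perturbation replicates."""

    distances: List[float]
    init_fraction: float
    rule: str
    horizon: int
    replicates: int
    seed: int

    @property
    def mean(self) -> float:
        return sum(self.distances) / len(self.distances)


def _hamming(a: tuple, b: tuple) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def derrida_damage(net: LogicNetwork, init_fraction: float = 0.1,
                   replicates: int = 100, horizon: int = 500,
                   rule: str = "sync", *, seed: int) -> DamageResult:
    """Damage spreading: perturb ceil(init_fraction * n) distinct nodes of
    a random state (multi-valued flips redraw uniformly among the other
    values), co-evolve original and twin for ``horizon`` steps, and record
    the final normalized Hamming distance per replicate.

    Asynchronous runs draw one shared node-choice schedule per replicate,
    applied to both twins.
    """
    if not (0 < init_fraction <= 1):
        raise ValueError("init_fraction must be in (0, 1]")
    if rule not in ("sync", "async"):
        raise ValueError("damage rule must be 'sync' or 'async'")
    n = net.n
    flips = math.ceil(init_fraction * n)
    rng = _random.Random(seed)
    idx = _index(net)
    movable = [nm for nm in net.names if not net.is_input(nm)]
    distances = []
    for _ in range(replicates):
        s = random_state(net, rng)
        twin = list(s)
        for pos in rng.sample(range(n), flips):
            others = [v for v in range(net.m) if v != twin[pos]]
            twin[pos] = rng.choice(others)
        twin = tuple(twin)
        if rule == "sync":
            for _t in range(horizon):
                s = step(net, s, "sync")
                twin = step(net, twin, "sync")
        else:
            schedule = [rng.choice(movable) for _t in range(horizon)]
            for nm in schedule:
                new_s = list(s)
                new_s[idx[nm]] = _node_update(net, s, idx, nm)
                s = tuple(new_s)
                new_t = list(twin)
                new_t[idx[nm]] = _node_update(net, twin, idx, nm)
                twin = tuple(new_t)
        distances.append(_hamming(s, twin) / n)
    return DamageResult(distances, init_fraction, rule, horizon,
                        replicates, seed)


# ---------------------------------------------------------------------------
# Lattice percolation
# ---------------------------------------------------------------------------

LATTICES = ("square", "hexagonal", "triangular")


def _lattice_neighbors(kind: str, L: int, r: int, c: int) -> list:
    """Neighbor coordinates: periodic horizontally, open vertically."""
    east, west = (r, (c + 1) % L), (r, (c - 1) % L)
    if kind == "square":
        cand = [(r - 1, c), (r + 1, c), east, west]
    elif kind == "triangular":
        cand = [(r - 1, c), (r + 1, c), east, west,
                (r - 1, (c + 1) % L), (r + 1, (c - 1) % L)]
    elif kind == "hexagonal":
        # brick-wall honeycomb: 2 horizontal neighbors plus one vertical,
        # alternating up/down with sublattice parity
        vert = (r - 1, c) if (r + c) % 2 == 0 else (r + 1, c)
        cand = [east, west, vert]
    else:
        raise ValueError(f"unknown lattice kind {kind!r}")
    return [(rr, cc) for rr, cc in cand if 0 <= rr < L]


def _node_name(r: int, c: int) -> str:
    return f"n{r}_{c}"


def lattice_network(kind: str, L: int, m: int = 2,
                    paradigm: str = "uniform", *, seed: int,
                    rule_factory: Optional[Callable] = None,
                    **paradigm_params) -> LogicNetwork:
    """L x L lattice with local-neighbor inputs.

    ``rule_factory(r, c, neighbors, rng)`` may override rule construction
    and must return ``(regulator names, DiscreteFunction)``; by default
    each node draws a rule of the requested paradigm over its neighbors.
    """
    from .core import random_function
    if L < 2:
        raise ValueError("lattice side must be at least 2")
    rng = _random.Random(seed)
    names, regulators, functions = [], {}, {}
    for r in range(L):
        for c in range(L):
            name = _node_name(r, c)
            names.append(name)
            nbrs = [_node_name(rr, cc)
                    for rr, cc in _lattice_neighbors(kind, L, r, c)]
            if rule_factory is not None:
                regs, f = rule_factory(r, c, nbrs, rng)
            else:
                regs = nbrs
                f = random_function(len(regs), m, paradigm,
                                    seed=rng.randrange(2 ** 31),
                                    **paradigm_params)
            regulators[name] = regs
            functions[name] = f
    net = LogicNetwork(names, regulators, functions, m)
    net.metadata.update({"lattice": kind, "side": L})
    return net


@dataclass
class PercolationResult:
    spanning: bool
    cluster_sizes: List[int]
    stable_nodes: int
    lattice: str
    side: int


def percolation(kind: str, L: int, m: int = 2, paradigm: str = "uniform",
                transient: int = 200, window: int = 20, *, seed: int,
                rule_factory: Optional[Callable] = None,
                **paradigm_params) -> PercolationResult:
    """Stable-component percolation on a lattice-embedded system.

    Evolve a random state synchronously for ``transient`` steps, mark
    nodes whose value never changes during ``window`` further steps as
    stable, cluster stable nodes by lattice adjacency, and test whether
    some cluster touches both the top and bottom boundary rows.
    """
    net = lattice_network(kind, L, m, paradigm, seed=seed,
                          rule_factory=rule_factory, **paradigm_params)
    rng = _random.Random(seed + 1)
    state = random_state(net, rng)
    for _ in range(transient):
        state = step(net, state, "sync")
    idx = _index(net)
    stable = {n: True for n in net.names}
    ref = state
    for _ in range(window):
        state = step(net, state, "sync")
        for n in net.names:
            if state[idx[n]] != ref[idx[n]]:
                stable[n] = False
    stable_set = {n for n, ok in stable.items() if ok}

    # cluster by (undirected) lattice adjacency
    parent = {n: n for n in stable_set}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for r in range(L):
        for c in range(L):
            a = _node_name(r, c)
            if a not in stable_set:
                continue
            for rr, cc in _lattice_neighbors(kind, L, r, c):
                b = _node_name(rr, cc)
                if b in stable_set:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[ra] = rb
    clusters: Dict[str, set] = {}
    for n in stable_set:
        clusters.setdefault(find(n), set()).add(n)
    spanning = False
    for members in clusters.values():
        rows = {int(n[1:].split("_")[0]) for n in members}
        if 0 in rows and (L - 1) in rows:
            spanning = True
            break
    sizes = sorted((len(c) for c in clusters.values()), reverse=True)
    return PercolationResult(spanning, sizes, len(stable_set), kind, L)


# ---------------------------------------------------------------------------
# Preference analysis (multi-valued interaction matrices)
# ---------------------------------------------------------------------------

@dataclass
class PreferenceReport:
    """How regulator value distributions score the target's states.

    ``conditional[p]`` is the m x m row-normalized matrix
    D_p[v][j] = P(regulator p = j | target = v) over sampled attractor
    states (weighted by basin hits).  The score matrix is
    sum_p D_p W; per-state scores are its diagonal, the preferred state
    its argmax, and ``transitions`` lists (u, v) pairs where row u of the
    score matrix peaks at v != u (a preferred move u -> v).
    """

    target: str
    regulators: List[str]
    conditional: Dict[str, list]
    score_matrix: list
    state_scores: list
    preferred_state: Optional[int]
    transitions: List[tuple]
    states_sampled: int


def preference_analysis(net: LogicNetwork, target: str, samples: int = 200,
                        horizon: int = 500, *, seed: int,
                        weights: Optional[Sequence[Sequence[float]]] = None
                        ) -> PreferenceReport:
    if target not in net.names:
        raise ValueError(f"unknown target node {target!r}")
    m = net.m
    W = ([[1.0 if i == j else 0.0 for j in range(m)] for i in range(m)]
         if weights is None else [list(map(float, row)) for row in weights])
    regs = net.regulators[target]
    idx = _index(net)
    sample = sample_attractors(net, samples, horizon, seed=seed)
    pool: List[Tuple[tuple, int]] = []
    for att, hits in zip(sample.attractors, sample.basin_hits):
        for state in att:
            pool.append((state, hits))
    if not pool:
        warnings.warn("no stable states found; preference report is empty",
                      RuntimeWarning)
        zero = [[0.0] * m for _ in range(m)]
        return PreferenceReport(target, list(regs), {}, zero, [0.0] * m,
                                None, [], 0)
    counts = {p: [[0.0] * m for _ in range(m)] for p in regs}
    for state, w in pool:
        tv = state[idx[target]]
        for p in regs:
            counts[p][tv][state[idx[p]]] += w
    conditional = {}
    for p in regs:
        mat = []
        for v in range(m):
            total = sum(counts[p][v])
            mat.append([c / total for c in counts[p][v]] if total
                       else [0.0] * m)
        conditional[p] = mat
    score = [[0.0] * m for _ in range(m)]
    for p in regs:
        D = conditional[p]
        for v in range(m):
            for j in range(m):
                for s in range(m):
                    score[v][s] += D[v][j] * W[j][s]
    state_scores = [score[v][v] for v in range(m)]
    preferred = None
    if any(abs(x) > 0 for row in score for x in row):
        preferred = max(range(m), key=lambda v: state_scores[v])
    transitions = []
    for u in range(m):
        if all(x == 0 for x in score[u]):
            continue
        v = max(range(m), key=lambda j: score[u][j])
        if v != u:
            transitions.append((u, v))
    return PreferenceReport(target, list(regs), conditional, score,
                            state_scores, preferred, transitions,
                            sum(w for _, w in pool))
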