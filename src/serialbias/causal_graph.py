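"""Causal graphs for trial-history analyses of reproduction experiments.

In a magnitude-reproduction experiment the stimulus presented on trial t
(``s[t]``) can influence the reproduction error on the same trial (central
tendency, *CT*) and on the next trial (lag-1 serial dependence, *SD1*),
while errors also carry over from one trial to the next.  When the stimulus
sequence is a random walk, consecutive stimuli are themselves dependent,
which opens indirect paths between a regressor of interest and the error it
is regressed on.  A simple regression slope then mixes the direct effect
with whatever flows along those open paths.

This module encodes that structure as a directed acyclic graph and answers
the two questions a regression specification needs:

* which conditioning sets *d-separate* a cause from an effect, and
* whether a candidate adjustment set satisfies the *single-door criterion*,
  in which case the partial regression coefficient of the cause (in a
  regression of the effect on the cause plus the adjustment set) identifies
  the direct effect, i.e. the coefficient attached to that single edge.

d-separation is decided by a reachability ("Bayes-ball") traversal; the
graphs involved are tiny, so no sophistication is needed beyond
correctness, which the test suite checks against an exhaustive
path-enumeration oracle.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable

__all__ = [
    "Dag",
    "build_experiment_graph",
    "window_graph",
    "descendants",
    "is_d_separated",
    "single_door_valid",
]

Edge = tuple[str, str]


class Dag:
    """An immutable directed acyclic graph over string-labeled nodes.

    Parameters
    ----------
    nodes : iterable of str
        Variable labels, e.g. ``"s[t]"`` or ``"e[t-1]"``.
    edges : iterable of (str, str)
        Directed edges ``(cause, effect)``.  Both endpoints must be nodes,
        and the edge set must be acyclic.
    """

    __slots__ = ("_nodes", "_edges", "_children", "_parents")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge]):
        self._nodes = frozenset(nodes)
        self._edges = frozenset((str(u), str(v)) for u, v in edges)
        for u, v in self._edges:
            if u not in self._nodes or v not in self._nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")
        children: dict[str, set[str]] = {n: set() for n in self._nodes}
        parents: dict[str, set[str]] = {n: set() for n in self._nodes}
        for u, v in self._edges:
            children[u].add(v)
            parents[v].add(u)
        self._children = children
        self._parents = parents
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm: a DAG can be fully peeled off by in-degree zero.
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        queue = deque(n for n, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            n = queue.popleft()
            seen += 1
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self._nodes):
            raise ValueError("graph contains a directed cycle")

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes

    @property
    def edges(self) -> frozenset[Edge]:
        return self._edges

    def parents(self, node: str) -> frozenset[str]:
        self._require(node)
        return frozenset(self._parents[node])

    def children(self, node: str) -> frozenset[str]:
        self._require(node)
        return frozenset(self._children[node])

    def has_edge(self, cause: str, effect: str) -> bool:
        return (cause, effect) in self._edges

    def remove_edge(self, cause: str, effect: str) -> "Dag":
        """Return a copy of the graph without the edge ``cause -> effect``."""
        if not self.has_edge(cause, effect):
            raise ValueError(f"edge {cause!r} -> {effect!r} not in graph")
        return Dag(self._nodes, self._edges - {(cause, effect)})

    def _require(self, node: str) -> None:
        if node not in self._nodes:
            raise ValueError(f"unknown node {node!r}")

    # -- text serialization (one "cause -> effect" per line) ---------------

    def to_edgelist(self) -> str:
        """Serialize to text: one ``cause -> effect`` line per edge.

        Isolated nodes are written as bare labels so that round-tripping
        preserves the node set.
        """
        lines = [f"{u} -> {v}" for u, v in sorted(self._edges)]
        linked = {n for e in self._edges for n in e}
        lines.extend(sorted(self._nodes - linked))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edgelist(cls, text: str) -> "Dag":
        nodes: set[str] = set()
        edges: set[Edge] = set()
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "->" in line:
                u, _, v = line.partition("->")
                u, v = u.strip(), v.strip()
                if not u or not v:
                    raise ValueError(f"malformed edge line: {raw!r}")
                nodes.update((u, v))
                edges.add((u, v))
            else:
                nodes.add(line)
        return cls(nodes, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dag({len(self._nodes)} nodes, {len(self._edges)} edges)"


def _trial_edges(n_trials: int, autocorrelated: bool, s, e) -> list[Edge]:
    """Edge families shared by the chain and window constructors.

    ``s`` and ``e`` map a trial index to its node label.
    """
    edges: list[Edge] = []
    for k in range(1, n_trials + 1):
        edges.append((s(k), e(k)))            # central tendency
        if k < n_trials:
            edges.append((s(k), e(k + 1)))    # lag-1 serial dependence
            edges.append((e(k), e(k + 1)))    # error carryover
            if autocorrelated:
                edges.append((s(k), s(k + 1)))  # random-walk stimulus chain
    return edges


def build_experiment_graph(n_trials: int, autocorrelated: bool) -> Dag:
    """Causal graph of an ``n_trials``-trial reproduction experiment.

    Nodes are ``s1..sN`` (stimuli) and ``e1..eN`` (reproduction errors).
    Every stimulus affects its own trial's error (the CT edges) and the next
    trial's error (the SD1 edges), and errors carry over between consecutive
    trials.  When ``autocorrelated`` is true the stimuli form a chain
    ``s[k] -> s[k+1]``, modelling the random-walk design; in the shuffled
    (no-autocorrelation) condition those edges are absent.

    Parameters
    ----------
    n_trials : int
        Number of trials; must be at least 2.
    autocorrelated : bool
        Whether consecutive stimuli are causally linked.

    Returns
    -------
    Dag
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    s = lambda k: f"s{k}"
    e = lambda k: f"e{k}"
    nodes = [s(k) for k in range(1, n_trials + 1)] + [e(k) for k in range(1, n_trials + 1)]
    return Dag(nodes, _trial_edges(n_trials, autocorrelated, s, e))


def _offset_label(kind: str, offset: int) -> str:
    return f"{kind}[t]" if offset == 0 else f"{kind}[t-{offset}]"


def window_graph(autocorrelated: bool, n_back: int = 2) -> Dag:
    """Sliding-window view of the experiment graph around the current trial.

    Nodes are labeled relative to the current trial: ``s[t]``, ``s[t-1]``,
    ..., ``e[t]``, ``e[t-1]``, ...  All paths relevant to lag-1
    identification live within two trials back, so the default window covers
    trials t-2 .. t; the lag-2 conditional-independence check needs t-2 as
    well.

    Parameters
    ----------
    autocorrelated : bool
        Whether the stimulus-chain edges are present.
    n_back : int
        How many earlier trials to include (window size ``n_back + 1``).
    """
    if n_back < 1:
        raise ValueError("n_back must be >= 1")
    n = n_back + 1
    # trial index k = 1 is the oldest trial in the window; offset = n - k.
    s = lambda k: _offset_label("s", n - k)
    e = lambda k: _offset_label("e", n - k)
    nodes = [s(k) for k in range(1, n + 1)] + [e(k) for k in range(1, n + 1)]
    return Dag(nodes, _trial_edges(n, autocorrelated, s, e))


def descendants(dag: Dag, node: str) -> frozenset[str]:
    """All nodes reachable from ``node`` along directed paths (excluding it)."""
    if node not in dag.nodes:
        raise ValueError(f"unknown node {node!r}")
    out: set[str] = set()
    stack = [node]
    while stack:
        for c in dag.children(stack.pop()):
            if c not in out:
                out.add(c)
                stack.append(c)
    out.discard(node)
    return frozenset(out)


def _ancestors_of_set(dag: Dag, nodes: frozenset[str]) -> set[str]:
    anc = set(nodes)
    stack = list(nodes)
    while stack:
        for p in dag.parents(stack.pop()):
            if p not in anc:
                anc.add(p)
                stack.append(p)
    return anc


def is_d_separated(dag: Dag, x: str, y: str, z: Iterable[str]) -> bool:
    """Decide whether ``z`` blocks every path between ``x`` and ``y``.

    A path is blocked if it contains a chain or fork node inside ``z``, or a
    collider none of whose descendants (itself included) lies in ``z``.
    ``x`` and ``y`` are d-separated given ``z`` when every path between them
    is blocked; under the causal Markov assumption this implies conditional
    independence of the corresponding variables.

    Implemented as the standard two-phase reachability traversal: first
    collect the ancestors of ``z`` (which determine collider activation),
    then walk trails from ``x`` keeping track of the direction of travel.

    Parameters
    ----------
    dag : Dag
    x, y : str
        Distinct query nodes, neither in ``z``.
    z : iterable of str
        Conditioning set.

    Returns
    -------
    bool
        True iff every path between ``x`` and ``y`` is blocked given ``z``.
    """
    zset = frozenset(z)
    for n in (x, y, *zset):
        if n not in dag.nodes:
            raise ValueError(f"unknown node {n!r}")
    if x == y or x in zset or y in zset:
        raise ValueError("x, y and z must be disjoint")

    anc_z = _ancestors_of_set(dag, zset)

    # Trail states are (node, direction): "up" means the trail arrived at the
    # node from one of its children (or is the start node), "down" means it
    # arrived from a parent.
    to_visit: list[tuple[str, str]] = [(x, "up")]
    visited: set[tuple[str, str]] = set()
    while to_visit:
        state = to_visit.pop()
        if state in visited:
            continue
        visited.add(state)
        node, direction = state
        if node == y:
            return False
        if direction == "up" and node not in zset:
            for p in dag.parents(node):
                to_visit.append((p, "up"))
            for c in dag.children(node):
                to_visit.append((c, "down"))
        elif direction == "down":
            if node not in zset:
                for c in dag.children(node):
                    to_visit.append((c, "down"))
            if node in anc_z:  # collider (or ancestor of z) opens upward travel
                for p in dag.parents(node):
                    to_visit.append((p, "up"))
    return True


def single_door_valid(dag: Dag, cause: str, effect: str, z: Iterable[str]) -> bool:
    """Single-door criterion for identifying the direct effect of one edge.

    The coefficient on the edge ``cause -> effect`` equals the partial
    regression coefficient of ``cause`` in a linear regression of ``effect``
    on ``{cause} | z`` whenever

    1. ``z`` contains no descendant of ``effect``, and
    2. ``z`` d-separates ``cause`` from ``effect`` in the graph with the
       ``cause -> effect`` edge removed.

    Parameters
    ----------
    dag : Dag
        Graph containing the edge of interest.
    cause, effect : str
        Endpoints of the edge whose coefficient is to be identified.
    z : iterable of str
        Candidate adjustment set.

    Returns
    -------
    bool
    """
    if not dag.has_edge(cause, effect):
        raise ValueError(f"edge {cause!r} -> {effect!r} not in graph")
    zset = frozenset(z)
    if zset & (descendants(dag, effect) | {effect}):
        return False
    return is_d_separated(dag.remove_edge(cause, effect), cause, effect, zset)
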