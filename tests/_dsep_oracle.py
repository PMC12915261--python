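"""Test-only reference for d-separation: exhaustive path enumeration.

Independent of the package's reachability traversal — every undirected
simple path between the query nodes is listed and checked against the
blocking rules directly.
"""

from collections import defaultdict

from serialbias.causal_graph import Dag, descendants


def all_undirected_paths(dag: Dag, x: str, y: str) -> list[list[str]]:
    nbrs = defaultdict(set)
    for u, v in dag.edges:
        nbrs[u].add(v)
        nbrs[v].add(u)
    paths: list[list[str]] = []

    def dfs(node: str, path: list[str]) -> None:
        if node == y:
            paths.append(list(path))
            return
        for nxt in sorted(nbrs[node]):
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(x, [x])
    return paths


def path_is_blocked(dag: Dag, path: list[str], z: frozenset[str]) -> bool:
    edges = dag.edges
    for i in range(1, len(path) - 1):
        prev, v, nxt = path[i - 1], path[i], path[i + 1]
        collider = (prev, v) in edges and (nxt, v) in edges
        if collider:
            if not (({v} | descendants(dag, v)) & z):
                return True
        elif v in z:
            return True
    return False


def dsep_by_paths(dag: Dag, x: str, y: str, z) -> bool:
    """True iff every undirected path between x and y is blocked by z."""
    zset = frozenset(z)
    return all(
        path_is_blocked(dag, path, zset) for path in all_undirected_paths(dag, x, y)
    )


def random_dag(rng, n_nodes: int, p_edge: float = 0.35) -> Dag:
    """A random DAG: random topological order, each forward edge with p_edge."""
    labels = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = [
        (labels[order[i]], labels[order[j]])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return Dag(labels, edges)


def random_query(rng, dag: Dag):
    nodes = sorted(dag.nodes)
    x, y = rng.choice(len(nodes), size=2, replace=False)
    x, y = nodes[x], nodes[y]
    z = frozenset(n for n in nodes if n not in (x, y) and rng.random() < 0.4)
    return x, y, z
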