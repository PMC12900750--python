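"""Network-topology hub identification.

Two independent topological criteria are combined:

* **subgraph centrality** — the diagonal of the matrix exponential of the
  adjacency matrix, SC(i) = sum_k (A^k)_ii / k!, which weights the closed
  walks through a node by inverse factorial length; computed exactly via
  the symmetric eigendecomposition SC(i) = sum_j V_ij^2 exp(lambda_j);
* **MCODE** module membership — vertices are weighted by the
  core-clustering coefficient (k of the highest k-core of the closed
  neighborhood times that core's density), complexes are grown greedily
  from high-weight seeds with a vertex-weight-percentage admission
  threshold, then post-processed (2-core filter, optional haircut/fluff).

Consensus hubs are the top-k centrality nodes that also sit inside an
MCODE module.  All tie-breaks are lexicographic on the node id, so the
whole procedure is deterministic and invariant to input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


def read_edge_list(path: str | Path, dialect: str = "tsv2col") -> nx.Graph:
    """Load an undirected simple graph from a 2-column TSV or a SIF file.

    Duplicate edges are merged and self-loops dropped.  SIF lines are
    ``source <relation> target1 [target2 ...]``.
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if dialect == "tsv2col":
                if len(parts) != 2:
                    if lineno == 1:  # tolerate a header row
                        continue
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                src, targets = parts[0], parts[1:]
            else:
                if len(parts) == 1:
                    g.add_node(parts[0])
                    continue
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs source, relation, target(s)")
                src, targets = parts[0], parts[2:]
            g.add_node(src)
            for t in targets:
                if t == src:
                    continue  # self-loop dropped
                g.add_edge(src, t)
    return g


@dataclass
class McodeModule:
    """One MCODE complex: its members, density*size score, and seed."""

    members: tuple[str, ...]
    score: float
    seed_node: str


def subgraph_centrality(graph: nx.Graph) -> pd.DataFrame:
    """Exact subgraph centrality, ranked descending (ties lexicographic).

    Returns a DataFrame indexed by node with columns ``sc`` and ``rank``
    (1 = most central).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes(), key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    lam, v = np.linalg.eigh(a)
    sc = (v**2) @ np.exp(lam)
    df = pd.DataFrame({"sc": sc}, index=pd.Index(nodes, name="node"))
    df["_key"] = df.index.map(str)
    df = df.sort_values(["sc", "_key"], ascending=[False, True], kind="mergesort").drop(columns="_key")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_k_nodes(ranking: pd.DataFrame, k: int = 25) -> list[str]:
    """The k most central nodes (boundary ties already broken in ranking)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        import warnings

        warnings.warn(f"k={k} exceeds node count {len(ranking)}; returning all nodes")
        k = len(ranking)
    return list(ranking.index[:k])


def _core_clustering_weight(graph: nx.Graph, v) -> float:
    """k of the highest k-core of N[v], times that core's density."""
    if graph.degree(v) == 0:
        return 0.0
    closed = graph.subgraph(list(graph.adj[v]) + [v])
    core_num = nx.core_number(closed)
    kmax = max(core_num.values())
    core_nodes = [u for u, c in core_num.items() if c >= kmax]
    core = closed.subgraph(core_nodes)
    nn = core.number_of_nodes()
    density = 2.0 * core.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
    return kmax * density


def mcode_vertex_weights(graph: nx.Graph) -> pd.Series:
    """Core-clustering-coefficient vertex weights for every node."""
    nodes = sorted(graph.nodes(), key=str)
    return pd.Series(
        [_core_clustering_weight(graph, v) for v in nodes],
        index=pd.Index(nodes, name="node"),
        name="weight",
    )


def _haircut(sub: nx.Graph) -> nx.Graph:
    """Iteratively strip degree-1 vertices (keeps the module's 2-core)."""
    sub = sub.copy()
    while True:
        ones = [v for v in sub if sub.degree(v) <= 1 and sub.number_of_nodes() > 1]
        if not ones:
            return sub
        sub.remove_nodes_from(ones)


def mcode_find_modules(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
) -> list[McodeModule]:
    """Greedy MCODE complex detection.

    Seeds are taken in descending vertex-weight order (ties lexicographic);
    a neighbor joins the growing complex when its weight exceeds
    ``(1 - vwp) * seed_weight``.  Each vertex belongs to at most one
    module.  Complexes lacking a 2-core are discarded; ``haircut`` strips
    singly-connected members; ``fluff`` adds boundary neighbors whose
    closed-neighborhood density exceeds ``fluff_density``.  Modules are
    scored density * size and returned best first.
    """
    if not (0 <= vwp < 1):
        raise ValueError("vwp must be in [0, 1)")
    weights = mcode_vertex_weights(graph)
    order = sorted(weights.index, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    modules: list[McodeModule] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in sorted(graph.adj[v], key=str):
                if u in visited or u in members:
                    continue
                if weights[u] > threshold:
                    members.add(u)
                    frontier.append(u)
        visited |= members
        sub = graph.subgraph(members)
        core_num = nx.core_number(sub) if sub.number_of_nodes() else {}
        if not core_num or max(core_num.values()) < 2:
            continue  # no 2-core: not a complex
        if haircut:
            sub = _haircut(sub)
        if fluff:
            extra = set()
            for v in list(sub.nodes()):
                for u in sorted(graph.adj[v], key=str):
                    if u in sub or u in extra:
                        continue
                    closed = graph.subgraph(list(graph.adj[u]) + [u])
                    nn = closed.number_of_nodes()
                    dens = 2.0 * closed.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
                    if dens > fluff_density:
                        extra.add(u)
            sub = graph.subgraph(set(sub.nodes()) | extra)
        nn = sub.number_of_nodes()
        density = 2.0 * sub.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
        modules.append(
            McodeModule(members=tuple(sorted(sub.nodes(), key=str)), score=density * nn, seed_node=seed)
        )
    modules.sort(key=lambda m: (-m.score, tuple(map(str, m.members))))
    return modules


def consensus_hubs(
    topk: list[str],
    modules: list[McodeModule],
    ranking: pd.DataFrame | None = None,
) -> list[str]:
    """Top-centrality nodes that are also MCODE module members.

    Ordered by descending centrality when a ranking is supplied, else by
    the order of ``topk``.
    """
    in_modules: set = set()
    for m in modules:
        in_modules |= set(m.members)
    hubs = [v for v in topk if v in in_modules]
    if ranking is not None:
        hubs.sort(key=lambda v: (ranking.loc[v, "rank"]))
    return hubs


def write_network_outputs(
    out_dir: str | Path,
    ranking: pd.DataFrame,
    modules: list[McodeModule],
    hubs: list[str],
) -> None:
    """centrality.tsv, modules.tsv, hubs.txt under out_dir."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    ranking.to_csv(d / "centrality.tsv", sep="\t")
    rows = [
        {"module_id": i + 1, "score": m.score, "members": ",".join(m.members)}
        for i, m in enumerate(modules)
    ]
    pd.DataFrame(rows, columns=["module_id", "score", "members"]).to_csv(
        d / "modules.tsv", sep="\t", index=False
    )
    (d / "hubs.txt").write_text("\n".join(hubs) + ("\n" if hubs else ""))
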