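"""Haplotype networks: mutation distances and the minimum spanning network.

Nodes are haplotypes carrying their panel frequency and per-population
composition; edges connect haplotypes by their minimum number of mutation
steps.  The network is the minimum spanning network (MSN): a minimum
spanning tree augmented with every alternative edge of equal cost — an
edge (u, v, w) is retained exactly when w does not exceed the smallest
weight at which u and v first become connected in a Kruskal sweep (their
minimax path distance), plus an optional epsilon.  For distinct pairwise
distances and epsilon 0 the MSN is exactly the MST.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class HapNetwork:
    gene_id: str
    graph: nx.Graph
    distance_definition: str = "mutation steps (gap run = 1 step)"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return [(a, b, d["steps"]) for a, b, d in self.graph.edges(data=True)]

    def total_weight(self) -> float:
        return sum(d["steps"] for _, _, d in self.graph.edges(data=True))


def _gap_aware_steps(a: str, b: str) -> int:
    """Mutation steps between two aligned sequences.

    Substitutions count one step per position; a maximal run of contiguous
    gap columns counts as a single step (one indel event).
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    steps = 0
    in_gap = False
    for ca, cb in zip(a.upper(), b.upper()):
        gap = ca == "-" or cb == "-"
        if gap:
            if not in_gap:
                steps += 1
            in_gap = True
            continue
        in_gap = False
        if ca != cb:
            steps += 1
    return steps


def _align_pair(a: str, b: str) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def mutation_distance_matrix(
    sequences: dict[str, str], gap_mode: str = "run"
) -> pd.DataFrame:
    """Symmetric integer matrix of pairwise mutation steps.

    Equal-length sequences are compared positionally; unequal lengths are
    first put through a pairwise global (end-gapped) alignment, needed only
    when an indel haplotype is present.  ``gap_mode`` "run" counts a gap
    run as one step, "position" counts every gap column.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    ids = list(sequences)
    n = len(ids)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[ids[i]], sequences[ids[j]]
            if len(a) != len(b):
                a, b = _align_pair(a, b)
            if gap_mode == "run":
                d = _gap_aware_steps(a, b)
            elif gap_mode == "position":
                d = sum(1 for x, y in zip(a.upper(), b.upper()) if x != y)
            else:
                raise ValueError(f"unknown gap_mode {gap_mode!r}")
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def _minimax_distances(dist: pd.DataFrame) -> pd.DataFrame:
    """Largest edge weight on the MST path between every node pair."""
    g = nx.Graph()
    ids = list(dist.index)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            g.add_edge(a, b, weight=float(dist.loc[a, b]))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        # DFS from a tracking the running max edge weight
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, running = stack.pop()
            for nbr in mst.neighbors(node):
                if nbr in seen:
                    continue
                seen.add(nbr)
                m = max(running, mst[node][nbr]["weight"])
                out.loc[a, nbr] = out.loc[nbr, a] = m
                stack.append((nbr, m))
    return out


def minimum_spanning_network(
    dist: pd.DataFrame,
    node_frequencies: dict[str, float] | None = None,
    population_counts: dict[str, dict[str, int]] | None = None,
    epsilon: float = 0.0,
    gene_id: str = "",
) -> HapNetwork:
    """Minimum spanning network over a haplotype distance matrix.

    Retains every edge whose weight is within ``epsilon`` of the weight at
    which its endpoints' components first merge in ascending-weight (Kruskal)
    order, so all equal-cost alternative links survive.  The result always
    contains at least one minimum spanning tree and is connected.
    """
    if not dist.index.equals(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if dist.isna().any().any():
        raise ValueError("NaN distance in matrix")
    if not np.allclose(dist.values, dist.values.T):
        raise ValueError("distance matrix must be symmetric")
    ids = list(dist.index)
    g = nx.Graph(gene_id=gene_id)
    for h in ids:
        g.add_node(
            h,
            frequency=float((node_frequencies or {}).get(h, 0.0)),
            **{
                f"count_{pop}": int(c)
                for pop, c in ((population_counts or {}).get(h, {})).items()
            },
        )
    if len(ids) > 1:
        minimax = _minimax_distances(dist)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                w = float(dist.loc[a, b])
                if w <= minimax.loc[a, b] + epsilon:
                    g.add_edge(a, b, steps=int(w) if w == int(w) else w)
    if not nx.is_connected(g):
        raise ValueError("minimum spanning network is not connected")
    return HapNetwork(gene_id=gene_id, graph=g)


def hap_network(table, panel, epsilon: float = 0.0,
                gap_mode: str = "run") -> HapNetwork:
    """Build the gcHap network for one locus from a GcHapTable and panel."""
    dist = mutation_distance_matrix(table.hap_sequences, gap_mode=gap_mode)
    counts = table.carrier_counts()
    total = sum(counts.values())
    freqs = {h: c / total for h, c in counts.items()}
    pop_of = dict(zip(panel.frame["variety_id"], panel.frame["population"]))
    pop_counts: dict[str, dict[str, int]] = {h: Counter() for h in table.hap_ids}
    for variety, hap in table.assignments.items():
        pop_counts[hap][pop_of.get(variety, "unknown")] += 1
    return minimum_spanning_network(
        dist, node_frequencies=freqs,
        population_counts={h: dict(c) for h, c in pop_counts.items()},
        epsilon=epsilon, gene_id=table.gene_id,
    )


def export_network(network: HapNetwork, path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML or an edge-list TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "edgelist":
        rows = [
            {"hap_a": a, "hap_b": b, "steps": d["steps"]}
            for a, b, d in network.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["hap_a", "hap_b", "steps"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network export format {fmt!r}")
    return path


def brute_force_mst_weight(dist: pd.DataFrame) -> float:
    """Exhaustive minimum spanning tree weight (test oracle, n <= ~8).

    Enumerates all spanning trees via Prüfer sequences.
    """
    import itertools

    ids = list(dist.index)
    n = len(ids)
    if n == 1:
        return 0.0
    if n == 2:
        return float(dist.iloc[0, 1])
    best = math.inf
    for pruefer in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for node in pruefer:
            degree[node] += 1
        seq = list(pruefer)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        weight = 0.0
        deg = degree[:]
        import heapq

        heap = leaves[:]
        heapq.heapify(heap)
        for node in seq:
            leaf = heapq.heappop(heap)
            weight += float(dist.iloc[leaf, node])
            deg[node] -= 1
            if deg[node] == 1:
                heapq.heappush(heap, node)
        u, v = heapq.heappop(heap), heapq.heappop(heap)
        weight += float(dist.iloc[u, v])
        best = min(best, weight)
    return best
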