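"""Median-joining haplotype networks over HVRI motifs.

The construction follows the classic median-joining scheme: start from
the epsilon-relaxed minimum spanning network (MSN) of the observed
haplotypes under weighted mutational distance, propose median
(consensus) vectors for triplets of linked nodes, keep the cheapest
proposals (within ``epsilon`` of the minimum connection cost), prune
median vectors that the spanning structure no longer needs, and repeat
to a fixed point.  Median vectors are possible unsampled intermediates
(e.g. extinct or unsampled ancestral haplotypes); observed nodes carry
their sample frequencies, medians frequency zero.

Sites are treated as binary presence/absence of a variant relative to
the reference, which matches position-only motifs; an explicit allele
is retained on a median position only when every carrier agrees on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import (
    DEFAULT_WINDOW,
    HaplotypeMotif,
    VariantSite,
    format_motif,
    motif_distance,
    parse_motif,
)

OBSERVED = "observed"
MEDIAN = "median"

_MAX_ROUNDS = 64


@dataclass
class HaploNetwork:
    """A haplotype network: motif nodes, mutation-labelled weighted edges."""

    graph: nx.Graph
    epsilon: float = 0.0
    weights: dict[int, float] | None = None
    window: tuple[int, int] = DEFAULT_WINDOW

    def observed_nodes(self) -> list[HaplotypeMotif]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == OBSERVED]

    def frequency(self, node: HaplotypeMotif) -> int:
        return self.graph.nodes[node]["frequency"]

    @property
    def n_samples(self) -> int:
        return sum(d["frequency"] for _, d in self.graph.nodes(data=True))

    def validate(self) -> None:
        if self.graph.number_of_nodes() and not nx.is_connected(self.graph):
            raise AssertionError("network is not connected")
        for n, d in self.graph.nodes(data=True):
            if d["kind"] == MEDIAN and d["frequency"] != 0:
                raise AssertionError(f"median node {n} has nonzero frequency")
        for u, v, d in self.graph.edges(data=True):
            expect = motif_distance(u, v, self.weights)
            if abs(d["weight"] - expect) > 1e-9:
                raise AssertionError(f"edge {u}-{v} weight {d['weight']} != {expect}")
            if frozenset(d["positions"]) != _diff_positions(u, v):
                raise AssertionError(f"edge {u}-{v} mislabelled")


def _diff_positions(a: HaplotypeMotif, b: HaplotypeMotif) -> frozenset[int]:
    out = set(a.positions ^ b.positions)
    for pos in a.positions & b.positions:
        aa, ba = a.allele_at(pos), b.allele_at(pos)
        if aa is not None and ba is not None and aa != ba:
            out.add(pos)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Minimum spanning network (union of MSTs, epsilon-relaxed)
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def _pairwise(nodes: Sequence[HaplotypeMotif], weights) -> dict[tuple[int, int], float]:
    return {
        (i, j): motif_distance(nodes[i], nodes[j], weights)
        for i, j in combinations(range(len(nodes)), 2)
    }


def _minimax(nodes: Sequence[HaplotypeMotif], dist) -> dict[tuple[int, int], float]:
    """Minimax path weight between all pairs: the Kruskal merge level.

    Computed from an MST: the minimax distance between two nodes is the
    largest edge on their unique MST path.
    """
    n = len(nodes)
    edges = sorted(dist.items(), key=lambda kv: kv[1])
    uf = _UnionFind(range(n))
    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    for (i, j), w in edges:
        if uf.union(i, j):
            tree.add_edge(i, j, weight=w)
    out: dict[tuple[int, int], float] = {}
    for src in range(n):
        # DFS carrying the max edge weight seen so far
        stack = [(src, -1.0)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nb in tree.neighbors(node):
                if nb in seen:
                    continue
                seen.add(nb)
                m2 = max(mx, tree[node][nb]["weight"])
                key = (src, nb) if src < nb else (nb, src)
                out[key] = m2
                stack.append((nb, m2))
    return out


def _msn_edges(nodes: Sequence[HaplotypeMotif], weights, epsilon: float) -> set[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge is feasible iff its weight is within ``epsilon`` of the
    minimax (Kruskal merge) level of its endpoints; at ``epsilon=0``
    this is exactly the union of all minimum spanning trees.
    """
    if len(nodes) < 2:
        return set()
    dist = _pairwise(nodes, weights)
    minimax = _minimax(nodes, dist)
    return {ij for ij, w in dist.items() if w <= minimax[ij] + epsilon + 1e-12}


def minimum_spanning_network(
    haplotypes: Mapping[HaplotypeMotif, int],
    weights: Mapping[int, float] | None = None,
    epsilon: float = 0.0,
) -> HaploNetwork:
    """The epsilon-relaxed MSN of the observed haplotypes (no medians)."""
    nodes = sorted(haplotypes, key=lambda m: m.sort_key())
    return _assemble(nodes, haplotypes, weights, epsilon)


# ---------------------------------------------------------------------------
# Median joining
# ---------------------------------------------------------------------------

def _median(u: HaplotypeMotif, v: HaplotypeMotif, w: HaplotypeMotif) -> HaplotypeMotif:
    """Per-position majority consensus of three motifs.

    A position is present iff carried by at least two of the three; it
    keeps an explicit allele only when every carrier states the same
    one, otherwise it is stored allele-unknown.
    """
    sites = []
    for pos in sorted(u.positions | v.positions | w.positions):
        carriers = [m for m in (u, v, w) if pos in m.positions]
        if len(carriers) < 2:
            continue
        alleles = {m.allele_at(pos) for m in carriers}
        allele = alleles.pop() if len(alleles) == 1 else None
        sites.append(VariantSite(pos, allele))
    return HaplotypeMotif(tuple(sites), u.window)


def build_mj_network(
    haplotypes: Mapping[HaplotypeMotif, int],
    weights: Mapping[int, float] | None = None,
    epsilon: float = 0.0,
    mask_length_variants: bool = False,
) -> HaploNetwork:
    """Median-joining network of a haplotype frequency table.

    Parameters
    ----------
    haplotypes
        Motif -> sample count.  All motifs must share a window.
    weights
        Per-position mutation weights (default 1 everywhere).  The
        conventional scheme up-weights coding-region SNPs relative to
        hypervariable positions.
    epsilon
        Reduction threshold: how far above the minimum connection cost
        a link or median proposal may lie and still be kept.  0 gives
        the sparsest (most reduced) network.
    mask_length_variants
        Drop sites in the 16182-16193 poly-C region first, the usual
        convention for network analyses of HVRI data.
    """
    if not haplotypes:
        raise ValueError("empty haplotype table")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    windows = {m.window for m in haplotypes}
    if len(windows) != 1:
        raise ValueError(f"motifs span multiple windows: {sorted(windows)}")

    observed: dict[HaplotypeMotif, int] = {}
    for m, count in haplotypes.items():
        if count < 1:
            raise ValueError(f"non-positive frequency for {m}")
        key = m.without_region() if mask_length_variants else m
        observed[key] = observed.get(key, 0) + count

    nodes: set[HaplotypeMotif] = set(observed)
    discarded: set[HaplotypeMotif] = set()

    for _ in range(_MAX_ROUNDS):
        ordered = sorted(nodes, key=lambda m: m.sort_key())
        links = _msn_edges(ordered, weights, epsilon)
        adjacency: dict[int, set[int]] = {i: set() for i in range(len(ordered))}
        for i, j in links:
            adjacency[i].add(j)
            adjacency[j].add(i)

        # propose medians for every path v - u - w in the current MSN
        candidates: dict[HaplotypeMotif, float] = {}
        for u_idx, nbrs in adjacency.items():
            for v_idx, w_idx in combinations(sorted(nbrs), 2):
                u, v, w = ordered[u_idx], ordered[v_idx], ordered[w_idx]
                med = _median(u, v, w)
                if med in nodes or med in discarded:
                    continue
                cost = (
                    motif_distance(u, med, weights)
                    + motif_distance(v, med, weights)
                    + motif_distance(w, med, weights)
                )
                if med not in candidates or cost < candidates[med]:
                    candidates[med] = cost
        if not candidates:
            break
        cmin = min(candidates.values())
        accepted = {m for m, c in candidates.items() if c <= cmin + epsilon + 1e-12}
        nodes |= accepted

        # reduction: drop median vectors the spanning structure no longer needs
        while True:
            ordered = sorted(nodes, key=lambda m: m.sort_key())
            links = _msn_edges(ordered, weights, epsilon)
            degree = {i: 0 for i in range(len(ordered))}
            for i, j in links:
                degree[i] += 1
                degree[j] += 1
            removable = {
                ordered[i]
                for i, deg in degree.items()
                if deg <= 2 and ordered[i] not in observed
            }
            if not removable:
                break
            nodes -= removable
            discarded |= removable

    final = sorted(nodes, key=lambda m: m.sort_key())
    return _assemble(final, observed, weights, epsilon)


def _assemble(nodes: Sequence[HaplotypeMotif], observed: Mapping[HaplotypeMotif, int],
              weights, epsilon: float) -> HaploNetwork:
    g = nx.Graph()
    window = nodes[0].window if nodes else DEFAULT_WINDOW
    for m in nodes:
        freq = observed.get(m, 0)
        g.add_node(m, frequency=freq, kind=OBSERVED if m in observed else MEDIAN)
    for i, j in _msn_edges(nodes, weights, epsilon):
        u, v = nodes[i], nodes[j]
        g.add_edge(u, v, weight=motif_distance(u, v, weights),
                   positions=tuple(sorted(_diff_positions(u, v))))
    net = HaploNetwork(graph=g, epsilon=epsilon,
                       weights=dict(weights) if weights else None, window=window)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Center (candidate ancestral node)
# ---------------------------------------------------------------------------

def identify_center(net: HaploNetwork) -> HaplotypeMotif:
    """Node minimising frequency-weighted total graph distance to samples.

    In a star-like genealogy this recovers the ancestral haplotype.
    Ties break deterministically by canonical motif order.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net.graph):
        raise ValueError("network must be connected")
    sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
    best: tuple[float, tuple] | None = None
    best_node = None
    for node in net.graph.nodes:
        total = sum(
            d["frequency"] * sp[node][other]
            for other, d in net.graph.nodes(data=True)
            if d["frequency"] > 0
        )
        key = (total, node.sort_key())
        if best is None or key < best:
            best = key
            best_node = node
    return best_node


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _node_id(m: HaplotypeMotif) -> str:
    return format_motif(m) or "CRS"


def export_network(net: HaploNetwork, path: str | Path, format: str = "graphml") -> Path:
    """Write the network to disk; graphml round-trips losslessly."""
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.graph["window_low"], g.graph["window_high"] = net.window
        g.graph["epsilon"] = float(net.epsilon)
        g.graph["weights_json"] = json.dumps(net.weights or {})
        for m, d in net.graph.nodes(data=True):
            g.add_node(_node_id(m), motif=format_motif(m),
                       frequency=int(d["frequency"]), kind=d["kind"])
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(_node_id(u), _node_id(v), weight=float(d["weight"]),
                       positions=",".join(str(p) for p in d["positions"]))
        nx.write_graphml(g, path)
    elif format == "dot":
        _write_dot(net, path)
    elif format == "tsv-edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tpositions\n")
            for u, v, d in sorted(net.graph.edges(data=True),
                                  key=lambda e: (_node_id(e[0]), _node_id(e[1]))):
                pos = ",".join(str(p) for p in d["positions"])
                fh.write(f"{_node_id(u)}\t{_node_id(v)}\t{d['weight']}\t{pos}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def _write_dot(net: HaploNetwork, path: Path) -> None:
    # minimal hand-rolled DOT emitter (graphviz layout tools read it fine)
    lines = ["graph haplotypes {", "  node [shape=circle];"]
    for m, d in sorted(net.graph.nodes(data=True), key=lambda nd: _node_id(nd[0])):
        style = "filled" if d["kind"] == OBSERVED else "dashed"
        lines.append(
            f'  "{_node_id(m)}" [label="{_node_id(m)}\\n n={d["frequency"]}", style={style}];'
        )
    for u, v, d in sorted(net.graph.edges(data=True),
                          key=lambda e: (_node_id(e[0]), _node_id(e[1]))):
        pos = ",".join(str(p) for p in d["positions"])
        lines.append(f'  "{_node_id(u)}" -- "{_node_id(v)}" [label="{pos}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def import_network(path: str | Path) -> HaploNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(str(path))
    window = (int(g.graph["window_low"]), int(g.graph["window_high"]))
    weights_raw = json.loads(g.graph.get("weights_json", "{}"))
    weights = {int(k): float(v) for k, v in weights_raw.items()} or None
    out = nx.Graph()
    id_to_motif = {}
    for nid, d in g.nodes(data=True):
        text = d.get("motif", "")
        m = parse_motif("" if text in ("", "CRS") else text, window)
        id_to_motif[nid] = m
        out.add_node(m, frequency=int(d["frequency"]), kind=d["kind"])
    for u, v, d in g.edges(data=True):
        pos_text = d.get("positions", "")
        positions = tuple(int(p) for p in pos_text.split(",")) if pos_text else ()
        out.add_edge(id_to_motif[u], id_to_motif[v],
                     weight=float(d["weight"]), positions=positions)
    return HaploNetwork(graph=out, epsilon=float(g.graph.get("epsilon", 0.0)),
                        weights=weights, window=window)


def networks_equal(a: HaploNetwork, b: HaploNetwork) -> bool:
    """Structural equality: same nodes (with attributes) and edges."""
    if set(a.graph.nodes) != set(b.graph.nodes):
        return False
    for n in a.graph.nodes:
        da, db = a.graph.nodes[n], b.graph.nodes[n]
        if da["frequency"] != db["frequency"] or da["kind"] != db["kind"]:
            return False
    ea = {frozenset((u, v)): (d["weight"], tuple(d["positions"]))
          for u, v, d in a.graph.edges(data=True)}
    eb = {frozenset((u, v)): (d["weight"], tuple(d["positions"]))
          for u, v, d in b.graph.edges(data=True)}
    return ea == eb
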