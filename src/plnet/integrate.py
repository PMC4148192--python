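"""Integration of rescored evidence into one phenotypic-linkage network.

When several sources link the same gene pair, their benchmark-scale weights
are combined with a rank-down-weighted evidence sum: with the per-pair
weights sorted in decreasing order as L_0, L_1, ..., the integrated weight

    WS = L_0 + sum_i L_i / (D * i)        (harmonic kernel, default)
    WS = L_0 + sum_i L_i / D**i           (geometric kernel)

so the strongest evidence counts in full and every further, less reliable
source is increasingly discounted by the free parameter D (default 5).
"""

from __future__ import annotations

from collections.abc import Iterable

import networkx as nx
import numpy as np

from ._util import FormatError, PlnetError, pair_key
from .links import RESCORED, LinkSet

KERNELS = ("harmonic", "geometric")


class PhenotypicLinkageNetwork:
    """Weighted undirected simple graph over genes.

    Edge attributes: ``weight`` (the integrated score, > 0) and
    ``provenance`` (list of ``(source, rescored weight)`` in decreasing
    weight order).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "PhenotypicLinkageNetwork":
        """Edges as (gene_a, gene_b, weight[, provenance]) tuples."""
        net = cls()
        for edge in edges:
            a, b, w = edge[0], edge[1], float(edge[2])
            prov = list(edge[3]) if len(edge) > 3 else [("external", w)]
            net.add_edge(a, b, w, prov)
        return net

    def add_edge(self, a: str, b: str, weight: float, provenance=None) -> None:
        key = pair_key(a, b)  # refuses self-loops
        if weight <= 0:
            raise ValueError(f"edge weight must be > 0, got {weight} for {key}")
        self.graph.add_edge(key[0], key[1], weight=weight, provenance=provenance or [])

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def weight(self, a: str, b: str):
        data = self.graph.get_edge_data(a, b)
        return None if data is None else data["weight"]

    def degree(self, gene: str | None = None):
        if gene is not None:
            return self.graph.degree(gene) if gene in self.graph else 0
        return dict(self.graph.degree())

    def edges(self):
        for a, b, data in self.graph.edges(data=True):
            yield pair_key(a, b) + (data["weight"],)

    def top_edges(self, n: int) -> "PhenotypicLinkageNetwork":
        """Reporting-time filter: keep only the strongest ``n`` links."""
        ranked = sorted(self.edges(), key=lambda e: (-e[2], e[0], e[1]))[:n]
        out = PhenotypicLinkageNetwork()
        for a, b, w in ranked:
            out.add_edge(a, b, w, self.graph.edges[a, b].get("provenance"))
        return out

    def to_linkset(self, source: str = "integrated") -> LinkSet:
        return LinkSet(
            source=source,
            pairs={(a, b): w for a, b, w in self.edges()},
            score_kind=RESCORED,
        )

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str, provenance_path: str | None = None, header=None) -> None:
        with open(path, "w") as fh:
            for k, v in (header or {}).items():
                fh.write(f"# {k}={v}\n")
            for a, b, w in sorted(self.edges()):
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
        if provenance_path:
            with open(provenance_path, "w") as fh:
                fh.write("# gene_a\tgene_b\tsource\tweight\n")
                for a, b in sorted(pair_key(u, v) for u, v in self.graph.edges):
                    for src, w in self.graph.edges[a, b].get("provenance", []):
                        fh.write(f"{a}\t{b}\t{src}\t{w:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "PhenotypicLinkageNetwork":
        net = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 columns")
                try:
                    w = float(fields[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad weight {fields[2]!r}") from None
                net.add_edge(fields[0], fields[1], w, [("external", w)])
        return net


def combined_weight(weights: Iterable[float], D: float = 5.0, kernel: str = "harmonic") -> float:
    """Down-weighted evidence sum over one pair's per-source weights."""
    ws = sorted((float(w) for w in weights), reverse=True)
    if not ws:
        return 0.0
    total = ws[0]
    for i, w in enumerate(ws[1:], start=1):
        total += w / (D * i) if kernel == "harmonic" else w / D**i
    return total


def integrate(
    sources: Iterable[LinkSet],
    D: float = 5.0,
    kernel: str = "harmonic",
) -> PhenotypicLinkageNetwork:
    """Combine rescored link sets into the integrated network.

    Every source must be on the benchmark scale (``score_kind='rescored'``);
    a source contributes at most one weight per pair (its maximum), so
    duplicated records cannot double-count.  The result is independent of
    source order.
    """
    sources = list(sources)
    if D < 1:
        raise PlnetError(f"down-weighting parameter D must be >= 1, got {D}")
    if kernel not in KERNELS:
        raise PlnetError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    for ls in sources:
        if ls.score_kind != RESCORED:
            raise PlnetError(
                f"source {ls.source!r} is raw-scored; only rescored sources integrate"
            )

    per_pair: dict[tuple[str, str], dict[str, float]] = {}
    for ls in sources:
        for key, w in ls.pairs.items():
            by_src = per_pair.setdefault(key, {})
            if ls.source not in by_src or w > by_src[ls.source]:
                by_src[ls.source] = w

    net = PhenotypicLinkageNetwork()
    for (a, b), by_src in per_pair.items():
        prov = sorted(by_src.items(), key=lambda kv: (-kv[1], kv[0]))
        ws = combined_weight((w for _, w in prov), D=D, kernel=kernel)
        if ws > 0:
            net.add_edge(a, b, ws, prov)
    return net


def network_stats(net: PhenotypicLinkageNetwork) -> dict:
    """Deterministic summary: node/edge counts, weight quantiles, degrees."""
    weights = np.array([w for _, _, w in net.edges()], dtype=float)
    if weights.size:
        qs = np.quantile(weights, [0.0, 0.25, 0.5, 0.75, 1.0])
        quantiles = dict(zip(("min", "q25", "median", "q75", "max"), map(float, qs)))
    else:
        quantiles = {k: 0.0 for k in ("min", "q25", "median", "q75", "max")}
    return {
        "n_nodes": len(net.nodes),
        "n_edges": net.n_edges,
        "weight_quantiles": quantiles,
        "degrees": {g: int(d) for g, d in sorted(net.degree().items())},
    }
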