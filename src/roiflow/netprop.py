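"""Key-gene prioritization on a protein-protein interaction network.

Genes are mapped onto an undirected PPI graph, seeded with their fold
changes, and ranked by the steady state of a random walk with restart
``p(t+1) = (1-r) W' p(t) + r p0`` where W' is the column-normalized
adjacency matrix. Betweenness centrality (ordered-pair shortest-path
fractions) quantifies hub-ness. Key genes are the top-N by propagation
probability that also contribute to a significant pathway.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from roiflow.enrich import EnrichmentRow
from roiflow.errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)


@dataclass
class PpiNetwork:
    """Undirected, unweighted gene-symbol graph.

    Self-loops are dropped and duplicate edges collapsed on construction;
    ``node_order`` fixes the vector/matrix coordinate system.
    """

    graph: nx.Graph
    node_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_order:
            self.node_order = sorted(self.graph.nodes)

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "PpiNetwork":
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(g)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "PpiNetwork":
        g = nx.Graph(graph)  # copy; collapses multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def column_normalize(self) -> sp.csr_array:
        """W'[i, j] = A[i, j] / degree(j); isolated nodes keep a zero column
        (their lost mass is re-injected through the restart term)."""
        if self.n_nodes == 0:
            raise ConfigurationError("empty network")
        a = nx.adjacency_matrix(self.graph, nodelist=self.node_order).astype(float)
        deg = np.asarray(a.sum(axis=0)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return (a @ sp.diags_array(inv)).tocsr()


def read_network(path: str | Path, format: str = "edge_list") -> PpiNetwork:
    """Load a PPI network from a 2-column edge list or a BioGRID TAB3 file.

    TAB3 parsing extracts the "Official Symbol Interactor A"/"B" columns
    (header-detected), upper-cases symbols, and collapses multi-edges.
    """
    if format == "edge_list":
        edges = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise ParseError(f"{path}:{lineno}: expected 2 tab-separated symbols")
                edges.append((fields[0], fields[1]))
        return PpiNetwork.from_edges(edges)
    if format == "biogrid_tab3":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lstrip("#").strip(): c for c in df.columns}
        try:
            ca = cols["Official Symbol Interactor A"]
            cb = cols["Official Symbol Interactor B"]
        except KeyError as exc:
            raise ParseError(f"{path}: missing TAB3 column {exc}") from exc
        pairs = df[[ca, cb]].dropna()
        edges = [(a.upper(), b.upper()) for a, b in pairs.itertuples(index=False)]
        return PpiNetwork.from_edges(edges)
    raise ConfigurationError(f"unknown network format {format!r}")


def initialize_seed(
    deg_table: pd.DataFrame, net: PpiNetwork, mode: str = "abs"
) -> pd.Series:
    """Fold-change seed vector p0 over the network's nodes.

    Seeds come from the DEG-flagged rows when any are flagged, else from
    all genes with a nonzero fold change. ``abs`` uses |log2fc|;
    ``signed_positive`` floors negative fold changes at zero. The vector is
    normalized to sum 1; unmapped genes are logged.
    """
    if mode not in ("abs", "signed_positive"):
        raise ConfigurationError(f"unknown seed mode {mode!r}")
    if deg_table["is_deg"].any():
        source = deg_table[deg_table["is_deg"]]
    else:
        source = deg_table[deg_table["log2fc"] != 0]
    nodes = set(net.node_order)
    mapped = source.index[source.index.isin(nodes)]
    unmapped = len(source) - len(mapped)
    if unmapped:
        logger.info("%d seed genes not present in the network", unmapped)
    if len(mapped) == 0:
        raise ConfigurationError("no seed gene maps onto the network")
    lfc = source.loc[mapped, "log2fc"]
    weights = lfc.abs() if mode == "abs" else lfc.clip(lower=0.0)
    p0 = pd.Series(0.0, index=net.node_order)
    p0.loc[mapped] = weights
    total = p0.sum()
    if total <= 0:
        raise ConfigurationError("seed vector is all-zero after mapping")
    return p0 / total


def rwr(
    w_prime: sp.sparray | np.ndarray,
    p0: np.ndarray | pd.Series,
    r: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    method: str = "iterative",
) -> np.ndarray:
    """Random walk with restart: steady state of (1-r) W' p + r p0.

    ``iterative`` power-iterates to an L1 change below ``tol`` (mass lost
    through zero columns is re-injected proportionally to p0); ``exact``
    solves the linear system (I - (1-r) W') p = r p0 directly.
    """
    if not 0 < r <= 1:
        raise ConfigurationError("restart rate must lie in (0, 1]")
    p0 = np.asarray(p0, dtype=float)
    if (p0 < 0).any() or not np.isclose(p0.sum(), 1.0):
        raise ConfigurationError("p0 must be non-negative and sum to 1")
    if method == "exact":
        w = w_prime.toarray() if sp.issparse(w_prime) else np.asarray(w_prime)
        return np.linalg.solve(np.eye(len(p0)) - (1 - r) * w, r * p0)
    if method != "iterative":
        raise ConfigurationError(f"unknown RWR method {method!r}")
    p = p0.copy()
    for _ in range(max_iter):
        nxt = (1 - r) * (w_prime @ p) + r * p0
        lost = 1.0 - nxt.sum()
        if lost > 1e-15:
            nxt = nxt + lost * p0
        delta = np.abs(nxt - p).sum()
        p = nxt
        if delta < tol:
            return p
    raise ConfigurationError(
        f"RWR did not converge in {max_iter} iterations (last L1 residual {delta:.3e})"
    )


def betweenness(net: PpiNetwork) -> pd.Series:
    """Shortest-path betweenness over ordered node pairs s != v != t.

    Brandes' accumulation algorithm on the unweighted graph; disconnected
    pairs contribute nothing. Ordered pairs mean each unordered pair counts
    twice, matching the summation over all (s, t) with s != t.
    """
    if net.n_nodes == 0:
        raise ConfigurationError("empty network")
    g = net.graph
    bc = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        # single-source shortest paths (BFS) with path counting
        stack: list = []
        pred: dict = {v: [] for v in g.nodes}
        sigma = dict.fromkeys(g.nodes, 0.0)
        dist = dict.fromkeys(g.nodes, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in g.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = dict.fromkeys(g.nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return pd.Series({v: bc[v] for v in net.node_order}, name="betweenness")


@dataclass
class KeyGeneReport:
    ranked: pd.DataFrame  # gene-indexed: probability, betweenness, rank
    top: list[str]
    pathway_genes: set[str]
    key_genes: list[str]

    def __post_init__(self) -> None:
        assert set(self.key_genes) <= set(self.top)


def select_key_genes(
    probability: pd.Series,
    bc: pd.Series,
    enrichment: list[EnrichmentRow],
    top_n: int = 20,
) -> KeyGeneReport:
    """Rank genes by propagation probability and intersect with pathways.

    Ties on probability break by higher betweenness, then lexicographic.
    ``pathway_genes`` is the union of overlap genes of enrichment rows with
    adjusted p < 0.05; key genes are the top-N that fall in that union,
    reported in rank order.
    """
    if not enrichment:
        logger.warning("empty enrichment input; key gene set will be empty")
    common = probability.index
    bc = bc.reindex(common).fillna(0.0)
    ranked = pd.DataFrame(
        {"probability": probability, "betweenness": bc}, index=common
    )
    # probability desc, then betweenness desc, then gene id asc
    ranked = ranked.iloc[
        np.lexsort((ranked.index, -ranked["betweenness"], -ranked["probability"]))
    ]
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    top = list(ranked.index[: min(top_n, len(ranked))])
    pathway_genes: set[str] = set()
    for row in enrichment:
        if row.adj_p < 0.05:
            pathway_genes.update(row.genes)
    key = [g for g in top if g in pathway_genes]
    return KeyGeneReport(ranked=ranked, top=top, pathway_genes=pathway_genes,
                         key_genes=key)
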