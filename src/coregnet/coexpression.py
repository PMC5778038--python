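"""Per-species co-expression networks via Pearson correlation and HRR filtering.

The highest reciprocal rank (HRR) of a gene pair (g, h) is
``max(rank(g, h), rank(h, g))`` where ``rank(g, h)`` is the 1-based position
of h in g's neighbour list sorted by correlation, strongest first. Keeping
only edges with HRR ≤ k retains mutually strong correlations and bounds
every node's degree by k, which yields sparse networks suitable for visual
inspection and vicinity-based clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from coregnet.preprocessing import ExpressionDataset, InputError

logger = logging.getLogger(__name__)

_NODE_DEFAULTS = {"cazy_class": "", "cazy_family": "", "secreted": False, "de_call": "none"}


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson-r matrix over genes; zero-variance genes dropped.

    ``r[i, j]`` is the correlation between ``genes[i]`` and ``genes[j]``;
    the diagonal is 1 by construction but never consulted. ``dropped``
    records genes removed by the zero-variance screen.
    """

    genes: list[str]
    r: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.r.shape != (n, n):
            raise InputError(f"correlation matrix shape {self.r.shape} != ({n}, {n})")


@dataclass
class CoexpressionNetwork:
    """Undirected simple graph of genes; edges carry Pearson r and HRR rank."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def annotate(self, annotation) -> None:
        """Attach CAZy class/family node attributes from an annotation set."""
        for g in self.graph.nodes:
            fam = annotation.family_of(g)
            if fam is not None:
                self.graph.nodes[g]["cazy_family"] = fam
                self.graph.nodes[g]["cazy_class"] = annotation.class_of(g)

    def set_de_calls(self, de_table) -> None:
        calls = de_table.table["call"]
        for g in self.graph.nodes:
            if g in calls.index:
                self.graph.nodes[g]["de_call"] = calls[g]

    def node_table(self) -> pd.DataFrame:
        rows = [
            (
                g,
                d.get("cazy_family", ""),
                bool(d.get("secreted", False)),
                d.get("de_call", "none"),
            )
            for g, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene_id", "cazy_family", "secreted", "de_call"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (min(u, v), max(u, v), d["r"], d["hrr"])
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "hrr"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_edge_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_tsv(cls, path, nodes=None) -> "CoexpressionNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from((str(n), dict(_NODE_DEFAULTS)) for n in nodes)
        for row in df.itertuples(index=False):
            for n in (row.gene_a, row.gene_b):
                if n not in g:
                    g.add_node(n, **_NODE_DEFAULTS)
            g.add_edge(row.gene_a, row.gene_b, r=float(row.r), hrr=int(row.hrr))
        return cls(g)


def pearson_matrix(
    ds: ExpressionDataset,
    columns: list[str] | None = None,
    species: str | None = None,
    condition: str | None = None,
) -> CorrelationMatrix:
    """All-pairs Pearson correlation over a sample subset of a log2 dataset.

    Genes with zero variance over the selected columns cannot be correlated
    and are removed first (recorded in the result's ``dropped`` list).
    Requires at least 3 selected samples.
    """
    if not ds.log_scale:
        raise InputError("pearson_matrix expects a log2-transformed dataset")
    if columns is None:
        columns = ds.columns_for(species=species, condition=condition)
    if len(columns) < 3:
        raise InputError(f"need ≥3 samples to correlate, got {len(columns)}")
    arr = ds.values[list(columns)].to_numpy(dtype=float)
    genes = np.asarray(ds.genes)
    variable = arr.var(axis=1) > 0
    dropped = genes[~variable].tolist()
    if dropped:
        logger.info("pearson_matrix: dropped %d zero-variance genes", len(dropped))
    if not variable.any():
        raise InputError("all genes have zero variance over the selected samples")
    arr = arr[variable]
    r = np.corrcoef(arr)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(genes=genes[variable].tolist(), r=r, dropped=dropped)


def rank_neighbors(corr: CorrelationMatrix, absolute: bool = False) -> np.ndarray:
    """Neighbour rank matrix: ``rank[i, j]`` = 1-based position of j in i's list.

    Neighbours are sorted by r descending (or |r| descending with
    ``absolute=True``); exact ties are broken by lexicographic gene ID so
    ranks are deterministic across runs. The diagonal is set to 0 (a gene
    is not its own neighbour).
    """
    n = len(corr.genes)
    key = np.abs(corr.r) if absolute else corr.r.copy()
    key = key.astype(float).copy()
    np.fill_diagonal(key, -np.inf)  # self sorts last, then ignored
    lex = np.empty(n, dtype=int)
    lex[np.argsort(np.asarray(corr.genes))] = np.arange(n)
    ranks = np.zeros((n, n), dtype=int)
    positions = np.arange(1, n + 1)
    for i in range(n):
        order = np.lexsort((lex, -key[i]))
        ranks[i, order] = positions
    np.fill_diagonal(ranks, 0)
    return ranks


def hrr_network(
    corr: CorrelationMatrix,
    hrr_max: int = 3,
    absolute: bool = False,
) -> CoexpressionNetwork:
    """Build the co-expression network keeping edges with HRR ≤ ``hrr_max``.

    Every gene in ``corr`` becomes a node; the edge (g, h) is present iff
    ``max(rank(g, h), rank(h, g)) ≤ hrr_max``, i.e. each gene ranks the
    other within its top ``hrr_max`` correlations. Edge attributes store
    the Pearson r and the HRR value; the maximum degree is ≤ ``hrr_max``.
    """
    if hrr_max < 1:
        raise InputError(f"hrr_max must be ≥ 1, got {hrr_max}")
    ranks = rank_neighbors(corr, absolute=absolute)
    hrr = np.maximum(ranks, ranks.T)
    g = nx.Graph()
    g.add_nodes_from((gene, dict(_NODE_DEFAULTS)) for gene in corr.genes)
    ii, jj = np.nonzero(np.triu(hrr <= hrr_max, k=1) & (ranks > 0))
    for i, j in zip(ii, jj):
        g.add_edge(
            corr.genes[i],
            corr.genes[j],
            r=float(corr.r[i, j]),
            hrr=int(hrr[i, j]),
        )
    return CoexpressionNetwork(g)


def cazy_subnetwork(net: CoexpressionNetwork, annotation) -> CoexpressionNetwork:
    """Induced subgraph on CAZy-annotated genes; edge attributes preserved."""
    cazy_nodes = [g for g in net.graph.nodes if g in annotation.cazy_genes]
    return CoexpressionNetwork(net.graph.subgraph(cazy_nodes).copy())


def network_stats(net: CoexpressionNetwork) -> dict:
    """Node/edge counts, degree distribution and connected components."""
    g = net.graph
    degrees = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "max_degree": max(degrees) if degrees else 0,
        "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
        "degree_distribution": dict(sorted(hist.items())),
        "components": nx.number_connected_components(g) if g.number_of_nodes() else 0,
    }
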