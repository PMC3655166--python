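"""Co-expression network inference and consensus-network algebra.

A co-expression network links genes whose expression profiles correlate
above a Pearson correlation (PCC) threshold τ within one dataset. The
disease-specific consensus network is derived by

1. intersecting the networks of the two disease datasets (edges must recur
   in both),
2. subtracting every edge present in background networks (other cancers,
   normal tissues), and
3. removing genes whose regulation direction disagrees between the two
   disease datasets (concordance filter).

Edges are admitted on the signed convention, PCC ≥ τ, since the downstream
marker logic concerns co-up-regulation; an absolute-value mode is available
for exploratory use. Networks are thin wrappers around ``networkx.Graph``
so the full graph-algorithm toolbox stays available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import CONTROL, TUMOR, ExpressionDataset

logger = logging.getLogger(__name__)

UP, DOWN, FLAT = "up", "down", "flat"
FLAT_EPSILON = 0.1  # |log2 FC| below this is treated as no regulation change


@dataclass
class CoexpressionNetwork:
    """Undirected gene graph with PCC edge weights."""

    graph: nx.Graph
    threshold: float
    source_tag: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def write_edge_list(self, path: str | Path) -> None:
        """3-column TSV: gene_a, gene_b, pcc (pairs in sorted order)."""
        rows = sorted((min(u, v), max(u, v), d["weight"])
                      for u, v, d in self.graph.edges(data=True))
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_edge_list(cls, path: str | Path, threshold: float = 0.0,
                       source_tag: str = "") -> "CoexpressionNetwork":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for a, b, w in df.itertuples(index=False):
            g.add_edge(a, b, weight=float(w))
        return cls(g, threshold, source_tag or Path(path).stem)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class ThresholdDiagnostics:
    """Per-candidate-τ network summaries used for threshold selection."""

    table: pd.DataFrame          # columns: tau, n_nodes, n_edges, density, lcc_fraction
    chosen: float
    density_ceiling: float

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def infer_network(
    dataset: ExpressionDataset,
    threshold: float,
    absolute: bool = False,
) -> CoexpressionNetwork:
    """Build the PCC co-expression network of one dataset.

    An edge (g, h) is added iff PCC(g, h) ≥ τ (or |PCC| ≥ τ when
    ``absolute``). Genes with zero variance cannot carry a defined
    correlation and are excluded from edge formation with a warning.
    """
    if dataset.n_samples < 3:
        raise ValueError("network inference needs at least 3 samples")
    values = dataset.values
    sd = values.std(axis=1, ddof=1)
    flagged = sd.index[sd == 0.0]
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} zero-variance genes excluded from network "
            f"inference in {dataset.name!r}", stacklevel=2)
        values = values.drop(index=flagged)
    x = values.to_numpy()
    genes = values.index.to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    np.fill_diagonal(corr, 0.0)  # no self-loops
    passing = np.abs(corr) >= threshold if absolute else corr >= threshold
    iu = np.triu_indices_from(corr, k=1)
    mask = passing[iu]
    g = nx.Graph()
    g.add_nodes_from(genes)
    rows, cols = iu[0][mask], iu[1][mask]
    g.add_weighted_edges_from(
        zip(genes[rows], genes[cols], corr[rows, cols].astype(float)))
    # isolated genes are not part of the co-expression structure
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return CoexpressionNetwork(g, threshold, dataset.name)


def select_threshold(
    dataset: ExpressionDataset,
    grid: list[float] | np.ndarray | None = None,
    density_ceiling: float = 0.01,
    absolute: bool = False,
) -> ThresholdDiagnostics:
    """Scan a τ grid and pick the working threshold.

    For every candidate τ the network size, edge count, density (edges over
    possible gene pairs) and largest-component node coverage are recorded.
    The chosen τ is the smallest on the grid whose density is at or below
    ``density_ceiling`` — the loosest cutoff that still yields a sparse
    graph; if no candidate qualifies, the largest τ is returned.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.951, 0.05), 2)
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("candidate threshold grid is empty")
    n_possible = dataset.n_genes * (dataset.n_genes - 1) / 2
    rows = []
    for tau in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = infer_network(dataset, tau, absolute=absolute)
        if net.n_edges:
            comp = max(nx.connected_components(net.graph), key=len)
            lcc_fraction = len(comp) / net.n_nodes
        else:
            lcc_fraction = 0.0
        rows.append({
            "tau": tau,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "density": net.n_edges / n_possible if n_possible else 0.0,
            "lcc_fraction": lcc_fraction,
        })
    table = pd.DataFrame(rows)
    ok = table[table["density"] <= density_ceiling]
    chosen = float(ok["tau"].iloc[0]) if len(ok) else float(table["tau"].iloc[-1])
    return ThresholdDiagnostics(table, chosen, density_ceiling)


def _check_namespace(a: CoexpressionNetwork, b: CoexpressionNetwork) -> None:
    if a.n_nodes and b.n_nodes and not (a.nodes & b.nodes):
        raise ValueError(
            "networks share no gene identifiers — likely an identifier-"
            "mapping failure between datasets")


def intersect(a: CoexpressionNetwork, b: CoexpressionNetwork) -> CoexpressionNetwork:
    """Edges recurring in both networks; weight = mean of the two weights."""
    _check_namespace(a, b)
    g = nx.Graph()
    for u, v, d in a.graph.edges(data=True):
        if b.graph.has_edge(u, v):
            g.add_edge(u, v, weight=(d["weight"] + b.graph.edges[u, v]["weight"]) / 2.0)
    tag = f"{a.source_tag}&{b.source_tag}"
    return CoexpressionNetwork(g, max(a.threshold, b.threshold), tag)


def subtract(
    target: CoexpressionNetwork,
    backgrounds: list[CoexpressionNetwork],
    remove_genes: bool = False,
) -> CoexpressionNetwork:
    """Remove background co-expression from the target network.

    Every edge present in ANY background network is removed. With
    ``remove_genes`` every gene that appears as a node of a background
    network is removed outright with its incident edges — the stricter
    reading; off by default because background compendia cover most of the
    genome and gene-level removal would empty the target.
    """
    g = target.graph.copy()
    for bg in backgrounds:
        _check_namespace(target, bg)
        g.remove_edges_from([e for e in bg.graph.edges if g.has_edge(*e)])
        if remove_genes:
            hit = [n for n in bg.graph.nodes if g.has_node(n)]
            logger.info("gene-level subtraction removes %d genes from %s",
                        len(hit), target.source_tag)
            g.remove_nodes_from(hit)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return CoexpressionNetwork(g, target.threshold, target.source_tag)


@dataclass
class RegulationTable:
    """Per-gene regulation direction within one dataset.

    FC is mean(tumor) − mean(control) on the log2 scale; genes with
    |FC| < epsilon are called flat.
    """

    table: pd.DataFrame  # columns: mean_tumor, mean_control, log2_fc, direction
    source_tag: str = ""
    epsilon: float = FLAT_EPSILON

    def direction(self, gene: str) -> str:
        if gene not in self.table.index:
            warnings.warn(f"gene {gene!r} missing from regulation table "
                          f"{self.source_tag!r}; treated as flat", stacklevel=2)
            return FLAT
        return self.table.loc[gene, "direction"]

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset,
                     epsilon: float = FLAT_EPSILON) -> "RegulationTable":
        mean_tumor = dataset.class_columns(TUMOR).mean(axis=1)
        mean_control = dataset.class_columns(CONTROL).mean(axis=1)
        fc = mean_tumor - mean_control
        direction = pd.Series(
            np.where(fc.abs() < epsilon, FLAT, np.where(fc > 0, UP, DOWN)),
            index=fc.index)
        table = pd.DataFrame({
            "mean_tumor": mean_tumor,
            "mean_control": mean_control,
            "log2_fc": fc,
            "direction": direction,
        })
        return cls(table, dataset.name, epsilon)


def concordance_filter(
    network: CoexpressionNetwork,
    reg_a: RegulationTable,
    reg_b: RegulationTable,
) -> CoexpressionNetwork:
    """Drop genes regulated in opposite directions in the two disease datasets.

    Only genuinely divergent genes (up in one, down in the other) are
    removed with their incident edges; genes flat in either dataset are
    retained.
    """
    divergent = []
    for gene in network.graph.nodes:
        da, db = reg_a.direction(gene), reg_b.direction(gene)
        if {da, db} == {UP, DOWN}:
            divergent.append(gene)
    g = network.graph.copy()
    g.remove_nodes_from(divergent)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return CoexpressionNetwork(g, network.threshold, network.source_tag)


def largest_connected_component(
    network: CoexpressionNetwork,
) -> tuple[CoexpressionNetwork, float]:
    """The maximal component by edge count (ties broken by node count).

    Returns the component as a network plus the fraction of all edges it
    contains.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    components = [network.graph.subgraph(c) for c in nx.connected_components(network.graph)]
    best = max(components, key=lambda s: (s.number_of_edges(), s.number_of_nodes()))
    coverage = best.number_of_edges() / network.n_edges
    return CoexpressionNetwork(nx.Graph(best), network.threshold,
                               network.source_tag), coverage


def consensus_network(
    tissue_a: ExpressionDataset,
    tissue_b: ExpressionDataset,
    backgrounds: list[ExpressionDataset],
    threshold: float = 0.8,
    absolute: bool = False,
    remove_genes: bool = False,
) -> CoexpressionNetwork:
    """Full consensus construction: infer, intersect, subtract, concordance."""
    net_a = infer_network(tissue_a, threshold, absolute=absolute)
    net_b = infer_network(tissue_b, threshold, absolute=absolute)
    merged = intersect(net_a, net_b)
    bg_nets = [infer_network(ds, threshold, absolute=absolute) for ds in backgrounds]
    cleaned = subtract(merged, bg_nets, remove_genes=remove_genes)
    reg_a = RegulationTable.from_dataset(tissue_a)
    reg_b = RegulationTable.from_dataset(tissue_b)
    return concordance_filter(cleaned, reg_a, reg_b)
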