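"""Posterior association network (PAN) inference and density statistics.

Edges are kept when the posterior odds of association (SNR) reach a cutoff
lambda; the Jeffreys reading of odds >= 10 as "strong" evidence motivates
the default.  Edge sign compares the posterior probabilities of the
positive and negative components.
"""

from __future__ import annotations

import logging
from math import comb

import networkx as nx
import numpy as np

from .association import AssociationSet
from .errors import ValidationError
from .mixture import snr as _snr
from .screens import ScreenMatrix

logger = logging.getLogger(__name__)

__all__ = ["PAN", "infer_pan", "density", "edge_fraction"]


class PAN:
    """Signed, SNR-weighted gene network with node phenotype summaries."""

    def __init__(self, graph: nx.Graph, cutoff: float, n_tie_dropped: int = 0):
        self.graph = graph
        self.cutoff = float(cutoff)
        self.n_tie_dropped = int(n_tie_dropped)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges(data=True)

    def subgraph_edge_count(self, nodes) -> int:
        return self.graph.subgraph(nodes).number_of_edges()

    def mean_phenotype(self, nodes) -> float:
        vals = [self.graph.nodes[n].get("mean_phenotype", np.nan) for n in nodes]
        return float(np.nanmean(vals)) if vals else float("nan")

    def pruned(self) -> "PAN":
        """Copy without isolated nodes (for export)."""
        keep = [n for n in self.graph.nodes if self.graph.degree[n] > 0]
        return PAN(self.graph.subgraph(keep).copy(), self.cutoff, self.n_tie_dropped)

    def __repr__(self) -> str:
        return f"PAN({self.graph.number_of_nodes()} nodes, {self.n_edges} edges, cutoff={self.cutoff:g})"


def infer_pan(
    resp: np.ndarray,
    assoc: AssociationSet,
    screen: ScreenMatrix | None = None,
    cutoff: float = 10.0,
    mean_condition: str | None = None,
    prune_isolated: bool = False,
) -> PAN:
    """Build the signed network of pairs whose posterior odds reach ``cutoff``.

    Nodes carry a ``mean_phenotype`` attribute (mean Z-score of the first
    condition by default, configurable via ``mean_condition``) when a
    screen is supplied.  Pairs with exactly tied positive/negative
    posteriors are dropped and counted.
    """
    if not cutoff > 0:
        raise ValidationError("the SNR cutoff must be positive")
    odds = _snr(resp)
    graph = nx.Graph()
    if screen is not None:
        cond = mean_condition or screen.conditions[0]
        pheno = screen.mean_phenotype(cond)
        for g, v in zip(screen.genes, pheno):
            graph.add_node(g, mean_phenotype=float(v))
    else:
        graph.add_nodes_from(assoc.genes)
    n_ties = 0
    genes = assoc.genes
    for k in np.flatnonzero(odds >= cutoff):
        p_neg, p_pos = resp[k, 0], resp[k, 2]
        if p_neg == p_pos:
            n_ties += 1
            continue
        sign = "+" if p_pos > p_neg else "-"
        graph.add_edge(
            genes[assoc.i_idx[k]],
            genes[assoc.j_idx[k]],
            sign=sign,
            snr=float(odds[k]),
        )
    if n_ties:
        logger.info("dropped %d pairs with exactly tied edge-sign posteriors", n_ties)
    pan = PAN(graph, cutoff, n_ties)
    return pan.pruned() if prune_isolated else pan


def density(node_subset, pan: PAN) -> float:
    """Fraction of possible pairs within a gene set that are PAN edges."""
    nodes = list(dict.fromkeys(node_subset))
    if len(nodes) < 2:
        raise ValidationError("module density needs at least 2 genes")
    return pan.subgraph_edge_count(nodes) / comb(len(nodes), 2)


def edge_fraction(n_edges: int, n_nodes: int) -> float:
    """Edge count over all C(n, 2) possible pairs, as a fraction in [0, 1]."""
    if n_nodes < 2:
        raise ValidationError("need at least 2 nodes")
    if n_edges < 0:
        raise ValidationError("edge count must be nonnegative")
    return n_edges / comb(n_nodes, 2)
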