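"""Driver co-occurrence (DCO) networks: assembly, pruning, export.

A DCO network summarizes one treatment arm in one of three flavors:
``General`` (all differential signal), ``Resp`` (responder-enriched), and
``NonResp`` (non-responder-enriched).  Nodes are differentially altered
drivers (DiffD) and/or genes participating in selected co-occurring pairs
(DiP); edges are the selected pairs.  The sorted node set doubles as the
feature list (DiffD_DiP) for the downstream classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .cohort_io import AlterationMatrix, GeneCoordinates
from .diff_drivers import DiffDriverResult
from .driver_pairs import PairResult

logger = logging.getLogger(__name__)

__all__ = [
    "DCONetwork",
    "build_networks",
    "prune_by_importance",
    "network_summary",
    "write_network",
    "read_network",
]

FLAVORS = ("General", "Resp", "NonResp")

_DIFFD_KEY = {"General": "General_DiffD", "Resp": "Resp_DiffD", "NonResp": "NonResp_DiffD"}
_PAIR_KEY = {"General": "General_Ps", "Resp": "Resp_Ps", "NonResp": "NonResp_Ps"}


@dataclass
class DCONetwork:
    """One flavor of a treatment's driver co-occurrence network."""

    treatment_id: str
    flavor: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}")
        for u, v in self.graph.edges:
            if u == v:
                raise ValueError("self-loops are not allowed")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def feature_genes(self) -> list[str]:
        """Sorted DiffD_DiP gene list used as classifier features."""
        return self.nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "DCONetwork":
        return DCONetwork(self.treatment_id, self.flavor, self.graph.copy())


def build_networks(
    diffd_results: list[DiffDriverResult],
    pair_results: list[PairResult],
    treatment_id: str,
    coordinates: GeneCoordinates | None = None,
) -> dict[str, DCONetwork]:
    """Assemble the General / Resp / NonResp networks for one arm.

    Node set per flavor = flavor DiffD genes union genes in flavor-selected
    pairs; a gene present in both carries ``source="both"``.  Edges carry the
    pair statistics; when coordinates are supplied, pairs on the same
    chromosome arm get ``linked=True`` and a bp distance.
    """
    out = {}
    for flavor in FLAVORS:
        g = nx.Graph()
        diffd_in = [r for r in diffd_results if _DIFFD_KEY[flavor] in r.memberships]
        pairs_in = [p for p in pair_results if _PAIR_KEY[flavor] in p.memberships]
        for r in diffd_in:
            g.add_node(
                r.gene,
                source="DiffD",
                rate_resp=r.rate_resp,
                rate_nonresp=r.rate_nonresp,
                p_resp_gt_nonresp=r.p_resp_gt_nonresp,
            )
        for p in pairs_in:
            for gene in (p.gene_a, p.gene_b):
                if gene in g:
                    if g.nodes[gene].get("source") == "DiffD":
                        g.nodes[gene]["source"] = "both"
                else:
                    g.add_node(gene, source="DiP")
            attrs = {
                "count_resp": p.count_resp,
                "count_nonresp": p.count_nonresp,
                "rate_resp": p.rate_resp,
                "rate_nonresp": p.rate_nonresp,
                "tendency": {
                    "General": p.tendency_all,
                    "Resp": p.tendency_resp,
                    "NonResp": p.tendency_nonresp,
                }[flavor],
                "p_diff_cooccurrence": p.p_diff_cooccurrence,
            }
            if coordinates is not None:
                attrs["linked"] = coordinates.same_arm(p.gene_a, p.gene_b)
                dist = coordinates.distance_bp(p.gene_a, p.gene_b)
                if dist is not None:
                    attrs["distance_bp"] = dist
            g.add_edge(p.gene_a, p.gene_b, **attrs)
        out[flavor] = DCONetwork(treatment_id, flavor, g)
    return out


def prune_by_importance(
    network: DCONetwork, importances: dict[str, float], threshold: float = 0.0
) -> DCONetwork:
    """Drop nodes whose mean LOOCV feature importance is <= threshold.

    Genes with no recorded importance count as 0 (logged).  Incident edges
    are removed with their nodes; the operation is idempotent.
    """
    pruned = network.copy()
    missing = [n for n in pruned.graph.nodes if n not in importances]
    if missing:
        logger.info("%d nodes lack importances; treated as 0", len(missing))
    drop = [n for n in pruned.graph.nodes if importances.get(n, 0.0) <= threshold]
    pruned.graph.remove_nodes_from(drop)
    for n in pruned.graph.nodes:
        pruned.graph.nodes[n]["mean_importance"] = importances.get(n, 0.0)
    return pruned


def network_summary(
    networks: dict[str, DCONetwork], matrix: AlterationMatrix | None = None
) -> dict:
    """Node/edge counts per flavor plus, given a matrix, per-sample counts of
    altered network genes and altered selected pairs."""
    summary = {
        flavor: {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
        for flavor, net in networks.items()
    }
    if matrix is not None:
        per_sample = {}
        for flavor, net in networks.items():
            genes = [g for g in net.nodes if g in set(matrix.gene_ids)]
            gidx = matrix.gene_index(genes) if genes else []
            edges = [
                (a, b)
                for a, b in net.graph.edges
                if a in set(matrix.gene_ids) and b in set(matrix.gene_ids)
            ]
            counts_genes = (
                matrix.status[:, gidx].sum(axis=1).astype(int)
                if len(genes)
                else [0] * matrix.n_samples
            )
            pair_counts = []
            for i in range(matrix.n_samples):
                row = matrix.status[i]
                lookup = {g: row[j] for g, j in zip(matrix.gene_ids, range(matrix.n_genes))}
                pair_counts.append(sum(1 for a, b in edges if lookup[a] and lookup[b]))
            per_sample[flavor] = {
                "altered_drivers": list(map(int, counts_genes)),
                "altered_pairs": pair_counts,
            }
        summary["per_sample"] = per_sample
    return summary


def write_network(network: DCONetwork, path, format: str = "graphml") -> None:
    """Export to GraphML (typed attributes) or SIF (interaction label ``co``)."""
    if format == "graphml":
        g = network.graph.copy()
        g.graph["treatment_id"] = network.treatment_id
        g.graph["flavor"] = network.flavor
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            written = set()
            for a, b in sorted(network.graph.edges):
                fh.write(f"{a}\tco\t{b}\n")
                written.update((a, b))
            for n in sorted(set(network.graph.nodes) - written):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> DCONetwork:
    if format != "graphml":
        raise ValueError("only GraphML round-trips attributes; SIF is export-only")
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    treatment = g.graph.pop("treatment_id", "unknown")
    flavor = g.graph.pop("flavor", "General")
    return DCONetwork(treatment, flavor, g)
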