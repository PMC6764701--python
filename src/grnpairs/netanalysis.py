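"""Predicted-network extraction: top-K edges, hub genes, and exports.

Hubs are high-degree nodes of the subnetwork formed by the K most confident
predicted links.  Degree counts every incident retained edge (a TF's
out-edges and a target's in-edges both count; for a TF that is also a
predicted target, both directions accumulate on the same node).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["PredictedNetwork", "HubReport", "top_k_edges", "extract_hubs",
           "count_high_confidence_targets", "export_network",
           "export_gene_list"]


@dataclass
class PredictedNetwork:
    edges: list[tuple[str, str, float]]  # (tf_id, target_id, score), score desc
    k: int


@dataclass
class HubReport:
    hubs: list[tuple[str, int]]  # (gene_id, degree), degree desc
    min_degree: int
    degree_distribution: dict[str, int]  # every incident node


def _ranked(predictions):
    scorable = [p for p in predictions if p.scorable]
    return sorted(scorable, key=lambda p: (-p.score, p.tf_id, p.target_id))


def top_k_edges(predictions, k: int) -> PredictedNetwork:
    """The k most confident predicted links (ties broken lexicographically).

    If fewer than k scorable pairs exist, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = _ranked(predictions)
    kept = ranked[:k]
    return PredictedNetwork(
        edges=[(p.tf_id, p.target_id, p.score) for p in kept], k=k)


def extract_hubs(network: PredictedNetwork, min_degree: int = 1) -> HubReport:
    """Nodes of the retained subnetwork with degree >= min_degree."""
    if not network.edges:
        raise ValueError("cannot extract hubs from an empty network")
    deg: dict[str, int] = {}
    for tf, tg, _ in network.edges:
        deg[tf] = deg.get(tf, 0) + 1
        deg[tg] = deg.get(tg, 0) + 1
    hubs = sorted(((g, d) for g, d in deg.items() if d >= min_degree),
                  key=lambda x: (-x[1], x[0]))
    return HubReport(hubs=hubs, min_degree=min_degree,
                     degree_distribution=dict(sorted(deg.items())))


def count_high_confidence_targets(predictions, tf_id: str,
                                  score_floor: float = 0.8) -> int:
    """Number of a TF's predicted links with score strictly above the floor."""
    mine = [p for p in predictions if p.scorable and p.tf_id == tf_id]
    if not mine:
        known = {p.tf_id for p in predictions}
        raise KeyError(f"no predictions for TF {tf_id!r} (known TFs: "
                       f"{sorted(known)[:10]}...)")
    return sum(1 for p in mine if p.score > score_floor)


def export_network(network: PredictedNetwork, fmt: str, path) -> None:
    """Write the network as SIF, GraphML or TSV.

    TSV round-trips scores bit-exactly (written with ``repr``); SIF uses the
    `tf<TAB>regulates<TAB>target` convention consumed by Cytoscape.
    """
    path = Path(path)
    if fmt == "SIF":
        lines = [f"{tf}\tregulates\t{tg}" for tf, tg, _ in network.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "TSV":
        lines = ["tf_id\ttarget_id\tscore"]
        lines += [f"{tf}\t{tg}\t{score!r}" for tf, tg, score in network.edges]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "GraphML":
        import networkx as nx
        g = nx.DiGraph()
        for tf, tg, score in network.edges:
            g.add_edge(tf, tg, score=float(score))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r} "
                         "(expected SIF, GraphML or TSV)")


def read_network_tsv(path) -> PredictedNetwork:
    edges = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                tf, tg, s = line.rstrip("\n").split("\t")
                edges.append((tf, tg, float(s)))
    return PredictedNetwork(edges=edges, k=len(edges))


def export_gene_list(network: PredictedNetwork, path) -> None:
    """Plain-text gene list of the subnetwork, for external enrichment tools."""
    genes = sorted({g for tf, tg, _ in network.edges for g in (tf, tg)})
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))
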