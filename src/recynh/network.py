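"""Interaction network construction, layer assignment, and SxIP motif scan.

From a final score matrix we build an undirected network (one edge per
unordered pair scoring at or above the cut-off in either orientation),
assign each node an interaction layer as its unweighted shortest-path
distance from a chosen seed set (e.g. the microtubule end-binding proteins
EB1/2/3: layer 1 = direct binders, layers 2-3 = indirect partners one or two
nodes away), scan protein sequences for the extended nine-residue SxIP
motif that marks canonical EB-binding +TIPs, and test whether motif
carriers are enriched among direct over indirect interactors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .evaluation import hypergeom_tail
from .matrix import ISMatrix

__all__ = [
    "InteractionEdge",
    "build_network",
    "assign_layers",
    "scan_sxip",
    "sxip_carriers",
    "layer_enrichment",
    "write_edges",
]

_BASIC = frozenset("RHK")
_ACIDIC = frozenset("DE")
_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected scored interaction between two library members.

    ``both_orientations`` is a confidence annotation: the pair passed the
    cut-off with either protein on the DNA-binding-domain side.
    """

    a: str
    b: str
    avg_is: float
    both_orientations: bool
    in_reference_db: bool | None = None

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


def build_network(
    is_final: ISMatrix,
    cutoff: float,
    reference_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[InteractionEdge]:
    """One edge per unordered hetero-pair with max over orientations >= cutoff.

    The edge score is that maximum; self-pairs are omitted (the assay
    underdetects homodimers). When a reference pair list is supplied each
    edge is annotated with database membership.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ref = (
        None
        if reference_pairs is None
        else {frozenset(p) for p in reference_pairs}
    )
    lookup: dict[tuple[str, str], float] = {}
    for i, bait in enumerate(is_final.baits):
        for j, prey in enumerate(is_final.preys):
            lookup[(bait, prey)] = float(is_final.values[i, j])
    universe = sorted(set(is_final.baits) | set(is_final.preys))
    edges: list[InteractionEdge] = []
    for i, a in enumerate(universe):
        for b in universe[i + 1 :]:
            fwd = lookup.get((a, b), 0.0)
            rev = lookup.get((b, a), 0.0)
            best = max(fwd, rev)
            if best < cutoff:
                continue
            edges.append(
                InteractionEdge(
                    a=a,
                    b=b,
                    avg_is=best,
                    both_orientations=(fwd >= cutoff and rev >= cutoff),
                    in_reference_db=(
                        None if ref is None else frozenset((a, b)) in ref
                    ),
                )
            )
    return edges


def assign_layers(
    edges: Sequence[InteractionEdge],
    seeds: Iterable[str],
    max_layer: int = 3,
) -> dict[str, int]:
    """Breadth-first layers from the seed set on the undirected network.

    Seeds are layer 0, their direct partners layer 1, and so on up to
    ``max_layer``; unreachable or deeper nodes are absent from the result.
    Seeds absent from the node set are kept (at layer 0) with a warning.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    graph = nx.Graph()
    for edge in edges:
        graph.add_edge(edge.a, edge.b)
    missing = seeds - set(graph.nodes)
    if missing:
        warnings.warn(f"seed(s) {sorted(missing)} absent from the network")
        graph.add_nodes_from(missing)
    distances = nx.multi_source_dijkstra_path_length(graph, seeds)
    return {node: int(d) for node, d in distances.items() if d <= max_layer}


def scan_sxip(protein_seq: str) -> list[tuple[int, str]]:
    """Find extended SxIP nine-mers; returns (1-based position, window).

    A window X1-X2-[ST]-X3-[IL]-P-X4-X5-X6 matches when additionally at
    least one of X1..X4 is basic (R/H/K) and none of the six X positions is
    acidic (D/E). Windows containing non-standard letters are skipped with a
    warning.
    """
    seq = protein_seq
    hits: list[tuple[int, str]] = []
    warned = False
    for i in range(len(seq) - 8):
        window = seq[i : i + 9]
        if not set(window) <= _AMINO_ACIDS:
            if not warned:
                warnings.warn(
                    "window(s) with non-standard amino-acid letters skipped"
                )
                warned = True
            continue
        if window[2] not in "ST" or window[4] not in "IL" or window[5] != "P":
            continue
        x_all = (window[0], window[1], window[3], window[6], window[7], window[8])
        x1_to_x4 = (window[0], window[1], window[3], window[6])
        if not any(x in _BASIC for x in x1_to_x4):
            continue
        if any(x in _ACIDIC for x in x_all):
            continue
        hits.append((i + 1, window))
    return hits


def sxip_carriers(sequences: Mapping[str, str]) -> set[str]:
    """Ids of proteins carrying at least one extended SxIP motif."""
    return {pid for pid, seq in sequences.items() if scan_sxip(seq)}


def layer_enrichment(
    layers: Mapping[str, int], motif_carriers: Iterable[str]
) -> float:
    """Hypergeometric tail for motif-carrier enrichment among direct
    (layer 1) versus indirect (layer >= 2) interactors.

    Population = all direct + indirect nodes; successes = motif carriers in
    that population; sample = the direct interactors; the p-value is the
    probability of at least the observed carrier count among them.
    """
    carriers = set(motif_carriers)
    population = [node for node, layer in layers.items() if layer >= 1]
    direct = [node for node, layer in layers.items() if layer == 1]
    stray = carriers - set(layers)
    if stray:
        warnings.warn(
            f"{len(stray)} motif carrier(s) not in the layer assignment ignored"
        )
    N = len(population)
    K = sum(1 for node in population if node in carriers)
    n = len(direct)
    k = sum(1 for node in direct if node in carriers)
    return hypergeom_tail(k, n, K, N)


def write_edges(edges: Sequence[InteractionEdge], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "a": [e.a for e in edges],
            "b": [e.b for e in edges],
            "avg_is": [e.avg_is for e in edges],
            "both_orientations": [e.both_orientations for e in edges],
            "in_reference_db": [e.in_reference_db for e in edges],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
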