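"""TF-mediated miRNA-miRNA interaction network construction.

miRNAs repress transcription factors (TFs) by binding their 3'UTRs, and TFs
in turn activate or repress miRNA transcription.  Joining a miRNA->TF
regulation layer with a TF->miRNA layer therefore yields indirect, directed
miRNA->miRNA influences: an edge (a, b) exists whenever some TF t satisfies
a->t in the first layer and t->b in the second.  Each edge remembers the
set of TFs that mediate it.

Because miRNA->target resources name *mature* miRNAs (e.g. hsa-miR-21-5p)
while TF->miRNA resources name *precursor* miRNAs (e.g. hsa-mir-21), the
composed network may mix maturity levels; :func:`map_to_mature` expands
precursor endpoints through an explicit precursor->mature lookup table.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class Layer(enum.Enum):
    """Which regulation layer a record belongs to."""

    MIRNA_TO_TF = "mirna_to_tf"
    TF_TO_MIRNA = "tf_to_mirna"


@dataclass(frozen=True)
class RegulationRecord:
    """One directed regulatory edge in either layer.

    ``layer`` determines which side is the miRNA: for MIRNA_TO_TF the
    regulator is a miRNA and the target a TF, and vice versa.
    """

    regulator: str
    target: str
    layer: Layer
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("regulator and target must be non-empty")


@dataclass
class MiRNAInteractionNetwork:
    """Directed miRNA->miRNA edges, each carrying its mediating TF set.

    ``edges`` maps ``(source, target)`` to a non-empty frozenset of TF
    identifiers.  No self-loops, no duplicate pairs (dict keys are unique).
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (a, b), tfs in self.edges.items():
            g.add_edge(a, b, mediators=tfs)
        return g


@dataclass
class TopologyReport:
    degree_histogram: dict[int, int]
    powerlaw_exponent: float | None
    avg_clustering: float
    avg_shortest_path: float | None
    n_nodes: int
    n_edges: int


class NetworkCompositionError(ValueError):
    """Raised when no miRNA-miRNA edge can be composed from the layers."""


def compose_network(
    mirna_to_tf: Sequence[RegulationRecord],
    tf_to_mirna: Sequence[RegulationRecord],
    join_mode: str = "chain",
) -> MiRNAInteractionNetwork:
    """Join the two regulation layers into a miRNA-miRNA network.

    Parameters
    ----------
    mirna_to_tf : records with a miRNA regulator and a TF target.
    tf_to_mirna : records with a TF regulator and a miRNA target.
    join_mode : ``"chain"`` (default) composes a->t (layer 1) with t->b
        (layer 2); ``"co_target"`` instead connects a->b when both a and b
        regulate the same TF in layer 1 (the literal "TF regulated by
        miRNA_b" reading).  The chain mode is the one that uses both layers
        and matches how the two database families are oriented.

    Returns
    -------
    MiRNAInteractionNetwork with mediators(a, b) = the exact set of joining
    TFs; self-loops dropped; nodes = all miRNAs seen in either layer.
    """
    if not mirna_to_tf or not tf_to_mirna:
        raise NetworkCompositionError(
            "no edges composable: both regulation layers must be non-empty"
        )
    for rec, expected in [(mirna_to_tf[0], Layer.MIRNA_TO_TF), (tf_to_mirna[0], Layer.TF_TO_MIRNA)]:
        if rec.layer is not expected:
            raise ValueError(f"record layer {rec.layer} inconsistent with argument slot {expected}")

    mirnas_l1 = {r.regulator for r in mirna_to_tf}
    tfs = {r.target for r in mirna_to_tf} | {r.regulator for r in tf_to_mirna}
    ambiguous = mirnas_l1 & tfs
    if ambiguous:
        logger.warning(
            "%d identifiers appear as both miRNA and TF (records kept): %s",
            len(ambiguous), sorted(ambiguous)[:5],
        )

    # index layer 1 by TF target: t -> {a}
    by_tf: dict[str, set[str]] = {}
    for r in mirna_to_tf:
        by_tf.setdefault(r.target, set()).add(r.regulator)

    edges: dict[tuple[str, str], set[str]] = {}
    if join_mode == "chain":
        for r in tf_to_mirna:
            t, b = r.regulator, r.target
            for a in by_tf.get(t, ()):
                if a != b:
                    edges.setdefault((a, b), set()).add(t)
        nodes = mirnas_l1 | {r.target for r in tf_to_mirna}
    elif join_mode == "co_target":
        for t, regs in by_tf.items():
            for a in regs:
                for b in regs:
                    if a != b:
                        edges.setdefault((a, b), set()).add(t)
        nodes = set(mirnas_l1)
    else:
        raise ValueError(f"unknown join_mode {join_mode!r}")

    if not edges:
        raise NetworkCompositionError("no edges composable from the supplied layers")
    return MiRNAInteractionNetwork(
        nodes=nodes, edges={k: frozenset(v) for k, v in edges.items()}
    )


def map_to_mature(
    network: MiRNAInteractionNetwork,
    pmap: Mapping[str, Sequence[str]],
    precursors: set[str] | None = None,
) -> MiRNAInteractionNetwork:
    """Expand precursor endpoints to their mature forms.

    Each endpoint found in ``pmap`` is replaced by every mature id it maps
    to (cross-product over both endpoints); endpoints not in the map pass
    through unchanged, so layers that already name mature miRNAs need no
    entries.  Mediator sets of edges that collapse onto the same mature
    pair are merged by union; self-loops arising from the expansion are
    dropped.

    If ``precursors`` is given, any endpoint in that set that is missing
    from ``pmap`` causes its edges to be dropped (counted in the log)
    instead of passing through.
    """
    for pre, matures in pmap.items():
        if not matures:
            raise ValueError(f"precursor {pre!r} maps to no mature id")

    def expand(mid: str) -> list[str] | None:
        if mid in pmap:
            return list(pmap[mid])
        if precursors is not None and mid in precursors:
            return None  # unmappable precursor
        return [mid]

    edges: dict[tuple[str, str], set[str]] = {}
    nodes: set[str] = set()
    dropped = 0
    for (a, b), tfs in network.edges.items():
        ea, eb = expand(a), expand(b)
        if ea is None or eb is None:
            dropped += 1
            continue
        for ma in ea:
            for mb in eb:
                if ma == mb:
                    continue
                edges.setdefault((ma, mb), set()).update(tfs)
    if dropped:
        logger.info("map_to_mature: dropped %d edges with unmappable precursors", dropped)
    for n in network.nodes:
        en = expand(n)
        if en is not None:
            nodes.update(en)
    return MiRNAInteractionNetwork(
        nodes=nodes, edges={k: frozenset(v) for k, v in edges.items()}
    )


def topology_stats(network: MiRNAInteractionNetwork) -> TopologyReport:
    """Degree distribution, power-law tail fit, clustering and path length.

    All metrics are computed on the undirected projection; clustering and
    average shortest path on its largest connected component.  The
    power-law exponent is the negated slope of an ordinary least-squares
    fit of log(count) on log(degree) over observed degrees >= 1; it needs
    at least two distinct positive degrees, else None.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    g = network.to_networkx().to_undirected()

    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1

    pos = sorted(d for d in hist if d >= 1)
    exponent = None
    if len(pos) >= 2:
        x = np.log([float(d) for d in pos])
        y = np.log([float(hist[d]) for d in pos])
        slope = np.polyfit(x, y, 1)[0]
        exponent = float(-slope)

    if g.number_of_nodes() > 1:
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        avg_path = (
            float(nx.average_shortest_path_length(sub)) if sub.number_of_nodes() > 1 else None
        )
    else:
        avg_path = None
    clustering = float(nx.average_clustering(g)) if g.number_of_nodes() > 0 else 0.0

    return TopologyReport(
        degree_histogram=hist,
        powerlaw_exponent=exponent,
        avg_clustering=clustering,
        avg_shortest_path=avg_path,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
    )


def connected_pairs(
    network: MiRNAInteractionNetwork, retained: Iterable[str]
) -> list[tuple[str, str, frozenset[str]]]:
    """Directed edges with both endpoints retained, sorted by (source, target)."""
    keep = set(retained)
    out = [
        (a, b, tfs)
        for (a, b), tfs in network.edges.items()
        if a in keep and b in keep
    ]
    out.sort(key=lambda e: (e[0], e[1]))
    return out
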