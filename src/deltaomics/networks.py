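"""Association / consensus network containers and Cytoscape-compatible export.

Two network flavours flow through the pipeline:

* :class:`BipartiteAssociationNetwork` — thresholded feature-feature
  association edges between two blocks, signed by the association coefficient.
* :class:`ConsensusNetwork` — the merged conditional-dependency graph over the
  reduced variable set, with per-edge engine votes.

Sign colour convention for downstream visualisation: green = positive
correlation of change, red = negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger("deltaomics")

EXPORT_FORMATS = ("graphml", "sif", "edge_tsv")


@dataclass
class BipartiteAssociationNetwork:
    """Thresholded bipartite association network between two blocks.

    ``edges`` holds ``(feature_x, feature_y, coefficient)`` with
    ``|coefficient| >= threshold``; ``node_classes`` maps every incident
    feature to its block class.
    """

    pair: str
    threshold: float
    edges: list = field(default_factory=list)
    node_classes: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> list:
        seen = {}
        for u, v, _ in self.edges:
            seen.setdefault(u)
            seen.setdefault(v)
        return list(seen)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(pair=self.pair, threshold=self.threshold)
        for u, v, c in self.edges:
            g.add_edge(u, v, weight=float(c), sign=1 if c >= 0 else -1)
        for nd in g.nodes:
            g.nodes[nd]["block_class"] = self.node_classes.get(nd, "")
        return g


@dataclass
class ConsensusNetwork:
    """Undirected consensus dependency graph with per-edge vote support.

    ``edges`` holds ``(u, v, votes, sign)`` where ``votes`` is the maximum
    engine-vote count over the subsets in which the pair was evaluated and
    ``sign`` is +1 / -1 from the Spearman correlation of the pair (0 when the
    correlation is exactly zero: neutral).
    """

    nodes: dict = field(default_factory=dict)       # id -> block class
    edges: list = field(default_factory=list)       # (u, v, votes, sign)
    engines: tuple = ()
    quorum: int = 2

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return {frozenset((u, v)) for u, v, *_ in self.edges}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(engines=",".join(self.engines), quorum=self.quorum)
        g.add_nodes_from((n, {"block_class": c}) for n, c in self.nodes.items())
        m = max(len(self.engines), 1)
        for u, v, votes, sign in self.edges:
            g.add_edge(u, v, votes=int(votes), support=votes / m,
                       sign=int(sign), weight=float(votes))
        return g


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(net, path, fmt: str = "graphml",
                   allow_empty: bool = True) -> Path:
    """Write a network to ``path`` as GraphML, SIF or an edge TSV.

    GraphML carries node ``block_class`` and edge ``weight``/``sign`` (and
    ``votes``/``support`` for consensus networks).  SIF uses the interaction
    label ``assoc``.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected {EXPORT_FORMATS}")
    g = net if isinstance(net, nx.Graph) else net.to_graph()
    if g.number_of_edges() == 0 and not allow_empty:
        raise ValueError("refusing to export empty network (allow_empty=False)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in g.edges:
                fh.write(f"{u}\tassoc\t{v}\n")
    else:  # edge_tsv
        attrs = sorted({k for _, _, d in g.edges(data=True) for k in d})
        with open(path, "w") as fh:
            fh.write("source\ttarget\t" + "\t".join(attrs) + "\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\t{v}\t"
                         + "\t".join(repr(d.get(a, "")) for a in attrs) + "\n")
    logger.info("exported %d-edge network to %s (%s)",
                g.number_of_edges(), path, fmt)
    return path


def import_graphml(path) -> nx.Graph:
    """Re-read a GraphML network written by :func:`export_network`."""
    return nx.read_graphml(path)
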