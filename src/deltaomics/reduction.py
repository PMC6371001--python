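"""Data reduction: from thresholded PLS networks to the variable set entering
network reconstruction, plus pipeline bookkeeping counts.

Within each bipartite network the non-clinical variables are ranked by their
best absolute association coefficient and the top fraction is kept per
network; the union across networks, plus an unconditional anchor list (the IS
markers, adipocyte diameter, NEFA), forms the reduced set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger("deltaomics")


@dataclass
class ReducedVariableSet:
    """Ordered selection of (feature, class, best |association|, source pair)."""

    members: list = field(default_factory=list)   # (feature, class, score, source)
    anchors: list = field(default_factory=list)

    @property
    def feature_ids(self) -> list:
        return [m[0] for m in self.members]

    def __len__(self):
        return len(self.members)

    def classes(self) -> dict:
        return {m[0]: m[1] for m in self.members}


#: Counts printed in the published study, used as bookkeeping inputs: block
#: sizes of the seven inputs, per-block variable counts retained by the
#: thresholded PLS stage, and the reduced-set composition entering network
#: reconstruction.
STUDY_PRINTED_COUNTS = {
    "input_block_sizes": {
        "clinical": 45,
        "food_groups": 26,
        "nutrients": 34,
        "physical_activity": 3,
        "mgs": 741,
        "fecal_metab": 835,
        "urine_metab": 562,
        "serum_metab": 180,
        "transcriptome": 7560,
    },
    "retained_by_pls": {
        "nutrients": 10,
        "mgs": 10,
        "serum_metab": 84,
        "urine_metab": 73,
        "fecal_metab": 131,
        "transcriptome": 257,
    },
    "reduced_set": {
        "nutrients": 3,
        "mgs": 3,
        "serum_metab": 22,
        "urine_metab": 19,
        "fecal_metab": 24,
        "transcriptome": 32,
        "is_markers": 10,
        "adipocyte_diameter": 1,
        "nefa": 1,
    },
}


def select_top_fraction(networks, fraction: float = 0.20, anchors=(),
                        anchor_classes=None,
                        mode: str = "variables") -> ReducedVariableSet:
    """Keep the strongest fraction of variables (or edges) per network.

    ``mode="variables"``: within each network, non-clinical variables are
    ranked by max |association coefficient| and the top ``ceil(fraction * m)``
    kept, where ``m`` is that network's non-clinical variable count.
    ``mode="edges"``: the top ``ceil(fraction * n_edges)`` edges per network
    are taken and their non-clinical variables kept.  The union is taken
    across networks (deduplication keeps the best score); anchors are
    appended unconditionally.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if mode not in ("variables", "edges"):
        raise ValueError("mode must be 'variables' or 'edges'")
    best = {}        # feature -> (score, class, source)
    for net in networks:
        if net.n_edges == 0:
            logger.info("network %s is empty; contributes nothing", net.pair)
            continue
        scores = {}
        for u, v, c in net.edges:
            for f in (u, v):
                if net.node_classes.get(f) == "clinical":
                    continue
                if abs(c) > scores.get(f, (0.0,))[0]:
                    scores[f] = (abs(c),)
        if mode == "variables":
            ranked = sorted(scores, key=lambda f: -scores[f][0])
            kept = ranked[:math.ceil(fraction * len(ranked))]
        else:
            edges = sorted(net.edges, key=lambda e: -abs(e[2]))
            kept_set = set()
            for u, v, _c in edges[:math.ceil(fraction * len(edges))]:
                for f in (u, v):
                    if net.node_classes.get(f) != "clinical":
                        kept_set.add(f)
            kept = [f for f in scores if f in kept_set]
        for f in kept:
            sc = scores[f][0]
            if f not in best or sc > best[f][0]:
                best[f] = (sc, net.node_classes.get(f, ""), net.pair)
    members = sorted(((f, cls, sc, src) for f, (sc, cls, src) in best.items()),
                     key=lambda m: -m[2])
    anchor_classes = anchor_classes or {}
    present = {m[0] for m in members}
    for a in anchors:
        if a not in present:
            members.append((a, anchor_classes.get(a, "clinical"),
                            float("nan"), "anchor"))
            present.add(a)
    logger.info("reduced set: %d variables (%d anchors)", len(members),
                len(anchors))
    return ReducedVariableSet(members=members, anchors=list(anchors))


def count_report(blocks=None, networks=None, reduced=None,
                 printed: dict | None = None) -> dict:
    """Machine-readable bookkeeping of variable counts through the pipeline.

    When ``printed`` (a dict shaped like :data:`STUDY_PRINTED_COUNTS`) is
    given, its per-stage totals are computed with the same summation code;
    otherwise counts come from the supplied pipeline objects.
    """
    report = {}
    if printed is not None:
        report["total_input_variables"] = sum(
            printed["input_block_sizes"].values())
        report["retained_by_pls"] = dict(printed["retained_by_pls"])
        report["total_retained_by_pls"] = sum(
            printed["retained_by_pls"].values())
        report["reduced_set_breakdown"] = dict(printed["reduced_set"])
        report["reduced_set_size"] = sum(printed["reduced_set"].values())
        return report

    report["input_block_sizes"] = {b.name: b.n_features for b in blocks or []}
    report["total_input_variables"] = sum(
        report["input_block_sizes"].values())
    if networks is not None:
        retained = {}
        for net in networks:
            for f in net.nodes():
                cls = net.node_classes.get(f, "")
                if cls != "clinical":
                    retained.setdefault(cls, set()).add(f)
        report["retained_by_pls"] = {c: len(s) for c, s in sorted(
            retained.items())}
        report["total_retained_by_pls"] = len(
            set().union(*retained.values()) if retained else set())
    if reduced is not None:
        breakdown = {}
        for _f, cls, _sc, _src in reduced.members:
            breakdown[cls] = breakdown.get(cls, 0) + 1
        report["reduced_set_breakdown"] = dict(sorted(breakdown.items()))
        report["reduced_set_size"] = len(reduced)
        assert report["reduced_set_size"] == sum(breakdown.values())
    return report
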