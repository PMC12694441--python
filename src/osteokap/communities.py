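"""Community detection and feature over-representation profiling.

The compatibility graph is partitioned with greedy modularity
maximization (Clauset-Newman-Moore with deterministic tie-breaking) —
a documented stand-in for the original study's Mathematica
energy-layout clustering, whose algorithm is unspecified.  Isolates are
excluded before clustering, mirroring the study's 157-of-160 analysis
set.  Each community is then profiled by its over-representation
ratios: the prevalence of every discrete feature level inside the
community divided by its prevalence across all partitioned
(non-isolate) nodes, the quantity behind statements like "1.7 times the
network average".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx
import numpy as np
import pandas as pd

from osteokap.network import DiscreteProfile, FEATURE_CLASSES

__all__ = [
    "CommunityPartition", "NoCommunitiesError",
    "detect_communities", "enrichment_ratios", "community_report",
]


class NoCommunitiesError(ValueError):
    """Raised for an edgeless graph: nothing to cluster."""


@dataclass(frozen=True)
class CommunityPartition:
    """Community labels over the non-isolate nodes.

    Labels are contiguous integers from 1, ordered by community size
    descending (ties broken by smallest member id).  ``isolates`` lists
    the excluded degree-zero nodes.
    """
    assignment: dict               # node id -> community label (1-based)
    community_sizes: dict          # label -> size
    modularity: float
    isolates: tuple

    def members(self, label: int) -> list:
        return sorted(n for n, c in self.assignment.items() if c == label)

    @property
    def n_communities(self) -> int:
        return len(self.community_sizes)


def detect_communities(G: nx.Graph, seed: int = 0) -> CommunityPartition:
    """Partition the non-isolate subgraph by greedy modularity maximization.

    Deterministic for a given graph: nodes are processed in sorted order
    and community labels are assigned by (size, smallest member)
    ordering.  ``seed`` is accepted for interface stability and recorded
    workflows; the greedy algorithm itself is deterministic.
    """
    isolates = tuple(sorted(nx.isolates(G)))
    H = G.subgraph([n for n in G.nodes if n not in set(isolates)]).copy()
    if H.number_of_edges() == 0:
        raise NoCommunitiesError("graph has no edges; no communities to detect")
    communities = nx.community.greedy_modularity_communities(H)
    ordered = sorted((frozenset(c) for c in communities),
                     key=lambda c: (-len(c), min(c)))
    assignment = {node: label for label, comm in enumerate(ordered, start=1)
                  for node in comm}
    sizes = {label: len(comm) for label, comm in enumerate(ordered, start=1)}
    q = nx.community.modularity(H, ordered)
    return CommunityPartition(assignment=assignment, community_sizes=sizes,
                              modularity=float(q), isolates=isolates)


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def enrichment_ratios(partition: CommunityPartition,
                      profiles: list[DiscreteProfile],
                      features: dict[str, tuple] | None = None) -> pd.DataFrame:
    """Per-(community, feature, level) over-representation ratios.

    The denominator is the prevalence over the partitioned (non-isolate)
    node set.  Rows with zero network prevalence are flagged undefined
    rather than divided.  Display ratios are rounded half-up to one
    decimal.  The size-weighted mean of community prevalences equals the
    network prevalence for every level (conservation identity).
    """
    if features is None:
        features = FEATURE_CLASSES
    by_id = {p.id: p for p in profiles}
    missing = [n for n in partition.assignment if n not in by_id]
    if missing:
        raise ValueError(f"profiles missing for partitioned nodes: {missing[:5]}")
    nodes = sorted(partition.assignment)
    labels = np.array([partition.assignment[n] for n in nodes])

    rows = []
    for cname, feat_names in features.items():
        for j, feat in enumerate(feat_names):
            values = np.array([by_id[n].features(cname)[j] for n in nodes],
                              dtype=object)
            for level in pd.unique(values):
                hit = values == level
                net_prev = hit.mean()
                for label in sorted(partition.community_sizes):
                    in_c = labels == label
                    comm_prev = hit[in_c].mean()
                    defined = net_prev > 0
                    ratio = comm_prev / net_prev if defined else np.nan
                    rows.append({
                        "community": label,
                        "class": cname,
                        "feature": feat,
                        "level": str(level),
                        "community_prevalence": comm_prev,
                        "network_prevalence": net_prev,
                        "ratio": ratio,
                        "ratio_display": _round1(ratio) if defined else np.nan,
                        "undefined": not defined,
                    })
    return pd.DataFrame(rows)


def community_report(partition: CommunityPartition,
                     enrichment: pd.DataFrame,
                     min_ratio: float = 1.1,
                     small_size: int = 5) -> pd.DataFrame:
    """Narrative table: per community, the feature levels enriched above min_ratio.

    Rows are sorted by descending ratio within each community; communities
    of ``small_size`` or fewer members carry an exploratory flag and
    should be read as hypothesis-generating only.
    """
    keep = enrichment[(~enrichment["undefined"])
                      & (enrichment["ratio"] >= min_ratio)].copy()
    keep.sort_values(["community", "ratio"], ascending=[True, False], inplace=True)
    keep["size"] = keep["community"].map(partition.community_sizes)
    keep["exploratory"] = keep["size"] <= small_size
    cols = ["community", "size", "exploratory", "class", "feature", "level",
            "community_prevalence", "network_prevalence", "ratio", "ratio_display"]
    return keep[cols].reset_index(drop=True)
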