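"""Core-sample extraction: from a clustering of subtypes to consensus subtypes.

A cluster of subtypes (one or more per method) defines a consensus subtype.
A training sample belongs to that consensus subtype when its per-method
labels are over-represented among the cluster's subtypes — a one-sided
hypergeometric test per (sample, cluster): draw the sample's n per-method
labels from the population of all N subtype nodes, of which the cluster
holds K; significance means the q labels landing in the cluster exceed
chance.  Samples significant for no cluster stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

from .methods import SubtypeSystem

UNCLASSIFIED = "T0"


def core_sample_p(
    sample_labels: list[str],
    cluster_nodes: set[str],
    all_nodes: set[str],
) -> float:
    """Hypergeometric over-representation of one sample's labels in one cluster.

    With N = |all_nodes| subtypes overall, K = |cluster_nodes| of them in the
    cluster, and the sample carrying n per-method labels of which q lie in
    the cluster: returns P(X >= q) for X ~ Hypergeom(N, K, n).
    """
    if not cluster_nodes <= all_nodes:
        raise ValueError("cluster_nodes must be a subset of all_nodes")
    labels = [l for l in sample_labels if l is not None]
    if any(l not in all_nodes for l in labels):
        raise ValueError("sample label not among the network's subtype nodes")
    N, K, n = len(all_nodes), len(cluster_nodes), len(labels)
    q = sum(1 for l in labels if l in cluster_nodes)
    return float(hypergeom.sf(q - 1, N, K, n))


@dataclass(frozen=True)
class ConsensusSubtypes:
    """Per-sample consensus assignment (cluster id or unclassified)."""

    assignment: dict[str, int | None]       # sample -> cluster id, None = unclassified
    p_values: dict[tuple[str, int], float]  # (sample, cluster) -> p

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self.assignment.values():
            if cid is not None:
                sizes[cid] = sizes.get(cid, 0) + 1
        return sizes

    @property
    def n_unclassified(self) -> int:
        return sum(1 for cid in self.assignment.values() if cid is None)

    def to_table(self, prefix: str = "T") -> pd.DataFrame:
        """Table with columns sample_id, cluster_label (T1..Tk or T0), p_value."""
        rows = []
        for sample, cid in self.assignment.items():
            if cid is None:
                rows.append((sample, f"{prefix}0", float("nan")))
            else:
                rows.append((sample, f"{prefix}{cid}", self.p_values[(sample, cid)]))
        return pd.DataFrame(rows, columns=["sample_id", "cluster_label", "p_value"])

    def labels(self, prefix: str = "T") -> pd.Series:
        t = self.to_table(prefix)
        return pd.Series(t["cluster_label"].to_numpy(), index=t["sample_id"], name="consensus")


def assign_core_samples(
    systems: list[SubtypeSystem],
    cluster_of: Mapping[str, int] | None = None,
    alpha: float = 0.05,
    clustering=None,
) -> ConsensusSubtypes:
    """Assign each training sample to the consensus subtype it is core to.

    Every sample is tested against every cluster of subtypes; it is assigned
    to the unique cluster with p < ``alpha``.  When several clusters are
    significant the smallest p wins; an exact tie (or no significant cluster)
    leaves the sample unclassified.  ``cluster_of`` maps each subtype node to
    its cluster id (a :class:`~consub.network.NetworkClustering` may be
    passed instead via ``clustering``).
    """
    if cluster_of is None:
        if clustering is None:
            raise ValueError("provide cluster_of or clustering")
        cluster_of = clustering.cluster_of
    all_nodes = {lab for s in systems for lab in s.subtype_names}
    missing = all_nodes - set(cluster_of)
    if missing:
        raise ValueError(f"clustering does not cover node(s) {sorted(missing)}")
    clusters: dict[int, set[str]] = {}
    for node, cid in cluster_of.items():
        clusters.setdefault(cid, set()).add(node)

    sample_ids = list(systems[0].labels)
    assignment: dict[str, int | None] = {}
    p_values: dict[tuple[str, int], float] = {}
    for sample in sample_ids:
        labels = [s.labels.get(sample) for s in systems]
        best_cid, best_p, tie = None, 1.0, False
        for cid, nodes in clusters.items():
            p = core_sample_p(labels, nodes, all_nodes)
            p_values[(sample, cid)] = p
            if p < alpha:
                if best_cid is None or p < best_p:
                    best_cid, best_p, tie = cid, p, False
                elif p == best_p:
                    tie = True
        assignment[sample] = None if (best_cid is None or tie) else best_cid
    return ConsensusSubtypes(assignment=assignment, p_values=p_values)
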