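"""Subtype-association network and its Markov clustering.

Subtypes produced by independent methods become nodes of a graph; two
subtypes are connected when their sample overlap is larger than chance
(one-sided hypergeometric test, Benjamini-Hochberg adjusted p < alpha).  The
graph is clustered with the Markov cluster algorithm (MCL) across a sweep of
inflation factors; cluster robustness is scored by resampling samples and
re-deriving the network, and the final inflation is the lowest one on the
maximal plateau of the stability-weighted silhouette, subject to each
multi-node cluster retaining a minimum number of core samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .methods import SubtypeSystem

logger = logging.getLogger(__name__)


class MclConvergenceError(RuntimeError):
    pass


class CoverageError(RuntimeError):
    """A node was empty in every resampling iteration."""


class InflationSelectionError(RuntimeError):
    pass


def hypergeom_overlap_p(n_total: int, size_a: int, size_b: int, overlap: int) -> float:
    """Upper-tail probability P(X >= overlap), X ~ Hypergeom(n_total, size_a, size_b).

    The probability that two random subsets of sizes ``size_a`` and ``size_b``
    drawn from ``n_total`` samples share at least ``overlap`` members.
    """
    if not (0 <= size_a <= n_total and 0 <= size_b <= n_total):
        raise ValueError(f"subtype sizes {size_a}, {size_b} impossible for n={n_total}")
    if not 0 <= overlap <= min(size_a, size_b):
        raise ValueError(f"overlap {overlap} impossible for sizes {size_a}, {size_b}")
    return float(hypergeom.sf(overlap - 1, n_total, size_a, size_b))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SubtypeNetwork:
    """Graph over subtypes of several systems with hypergeometric edge tests."""

    node_method: dict[str, str]          # node (subtype label) -> method id
    node_size: dict[str, int]
    edges: pd.DataFrame                  # node_a, node_b, overlap, raw_p, adj_p (all tested pairs)
    alpha: float
    n_total: int

    @property
    def nodes(self) -> list[str]:
        return list(self.node_method)

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["adj_p"] < self.alpha].reset_index(drop=True)

    def adjacency(self) -> pd.DataFrame:
        """Binary adjacency over all nodes from the significant edges."""
        nodes = self.nodes
        A = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for _, row in self.significant_edges().iterrows():
            A.loc[row["node_a"], row["node_b"]] = 1.0
            A.loc[row["node_b"], row["node_a"]] = 1.0
        return A

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, m in self.node_method.items():
            g.add_node(node, method=m, size=self.node_size[node])
        for _, row in self.significant_edges().iterrows():
            g.add_edge(row["node_a"], row["node_b"], raw_p=row["raw_p"], adj_p=row["adj_p"])
        return g


def _network_from_label_maps(
    label_maps: list[tuple[str, dict[str, str]]], alpha: float
) -> SubtypeNetwork:
    """Build the network from (method_id, sample->subtype) maps.

    Internal entry point that skips SubtypeSystem validation so that
    subsampled systems (where a subtype may hold a single sample, or k may
    drift) can still be networked during stability resampling.
    """
    sample_sets = [frozenset(lm) for _, lm in label_maps]
    if len(set(sample_sets)) != 1:
        raise ValueError("systems label different sample sets; align them first")
    n_total = len(sample_sets[0])

    node_method: dict[str, str] = {}
    node_members: dict[str, set[str]] = {}
    for method_id, lm in label_maps:
        for sample, label in lm.items():
            if label not in node_method:
                node_method[label] = method_id
                node_members[label] = set()
            node_members[label].add(sample)

    rows = []
    nodes = list(node_method)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if node_method[a] == node_method[b]:
                continue  # same-method subtypes are disjoint by construction
            ov = len(node_members[a] & node_members[b])
            p = hypergeom_overlap_p(n_total, len(node_members[a]), len(node_members[b]), ov)
            rows.append((a, b, ov, p))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "overlap", "raw_p"])
    edges["adj_p"] = bh_adjust(edges["raw_p"].to_numpy()) if len(edges) else []
    return SubtypeNetwork(
        node_method=node_method,
        node_size={n: len(m) for n, m in node_members.items()},
        edges=edges,
        alpha=alpha,
        n_total=n_total,
    )


def build_network(systems: list[SubtypeSystem], alpha: float = 0.001) -> SubtypeNetwork:
    """Test all cross-method subtype pairs for sample over-representation.

    BH adjustment is performed once over the whole set of tested pairs; edges
    keep adjusted p < ``alpha``.  Same-method pairs are never tested (their
    subtypes are disjoint, so the overlap p-value is 1 by construction).
    """
    return _network_from_label_maps(
        [(s.method_id, s.labels) for s in systems], alpha
    )


# ---------------------------------------------------------------------------
# Markov cluster algorithm
# ---------------------------------------------------------------------------

def mcl(
    adjacency: np.ndarray,
    inflation: float,
    expansion: int = 2,
    tol: float = 1e-8,
    max_iter: int = 300,
    prune: float = 1e-5,
) -> list[set[int]]:
    """Markov clustering of a symmetric (weighted or binary) adjacency matrix.

    Self-loops of weight 1 are added, columns are normalized to a stochastic
    flow matrix, and the expand (matrix power) / inflate (entrywise power +
    renormalize) / prune cycle is iterated to convergence.  Clusters are read
    off the attractors of the limit matrix; overlapping attractor basins are
    merged so the result is a partition.  Clusters can never span
    disconnected components of the graph.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    if n == 0:
        return []
    M = A.copy()
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, expansion)
        new = new ** inflation
        new[new < prune] = 0.0
        col = new.sum(axis=0, keepdims=True)
        if np.any(col == 0):  # pruning emptied a column; restore self-loop
            idx = np.flatnonzero(col[0] == 0)
            new[idx, idx] = 1.0
            col = new.sum(axis=0, keepdims=True)
        new /= col
        residual = float(np.abs(new - M).max())
        M = new
        if residual < tol:
            break
    else:
        raise MclConvergenceError(
            f"MCL did not converge in {max_iter} iterations (residual {residual:.2e})"
        )

    attractors = np.flatnonzero(M.diagonal() > tol)
    clusters: list[set[int]] = []
    for a in attractors:
        basin = set(np.flatnonzero(M[a] > tol).tolist()) | {int(a)}
        merged = False
        for c in clusters:
            if c & basin:
                c |= basin
                merged = True
                break
        if not merged:
            clusters.append(basin)
    # merge any overlaps created transitively, then add orphans as singletons
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    covered = set().union(*clusters) if clusters else set()
    for orphan in range(n):
        if orphan not in covered:
            clusters.append({orphan})
    return sorted(clusters, key=min)


def mcl_partition(adjacency: pd.DataFrame, inflation: float, **kwargs) -> dict[str, int]:
    """MCL over a labeled adjacency; returns node -> cluster id (1-based)."""
    clusters = mcl(adjacency.to_numpy(), inflation, **kwargs)
    nodes = list(adjacency.index)
    out: dict[str, int] = {}
    for cid, members in enumerate(clusters, start=1):
        for i in members:
            out[nodes[i]] = cid
    return out


@dataclass(frozen=True)
class NetworkClustering:
    """An MCL partition of the subtype network with resampling-based stability."""

    inflation: float
    cluster_of: dict[str, int]
    frequency: pd.DataFrame          # node x node co-cluster frequency
    stability: dict[str, float]      # NaN for nodes in singleton clusters
    weighted_silhouette: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.cluster_of.items():
            out.setdefault(cid, []).append(node)
        return out


# ---------------------------------------------------------------------------
# stability resampling
# ---------------------------------------------------------------------------

def _resampled_networks(
    systems: list[SubtypeSystem],
    n_iter: int,
    fraction: float,
    alpha: float,
    seed: int,
) -> list[SubtypeNetwork]:
    """Networks rebuilt on ``n_iter`` random subsamples of the samples.

    The subsampled networks depend only on the seed (not on the inflation
    factor), so one set serves the whole inflation sweep.
    """
    sample_ids = list(systems[0].labels)
    n = len(sample_ids)
    n_pick = max(2, int(round(fraction * n)))
    nets = []
    for t in range(n_iter):
        rng = np.random.default_rng([seed, t])
        picked = [sample_ids[i] for i in np.sort(rng.choice(n, n_pick, replace=False))]
        maps = []
        for s in systems:
            maps.append((s.method_id, {x: s.labels[x] for x in picked}))
        nets.append(_network_from_label_maps(maps, alpha))
    return nets


def stability_frequencies(
    systems: list[SubtypeSystem],
    inflation: float,
    n_iter: int = 1000,
    fraction: float = 0.8,
    alpha: float = 0.001,
    seed: int = 0,
    resampled: list[SubtypeNetwork] | None = None,
) -> pd.DataFrame:
    """Node x node co-cluster frequency under sample resampling.

    Each iteration subsamples ``fraction`` of the samples, rebuilds the
    network and runs MCL at the given inflation.  The frequency for a node
    pair is the fraction of iterations in which the pair co-clusters, among
    iterations where both nodes retain at least one sample.  Diagonal is 1.
    """
    all_nodes = sorted({lab for s in systems for lab in s.subtype_names})
    idx = {node: i for i, node in enumerate(all_nodes)}
    K = len(all_nodes)
    co = np.zeros((K, K))
    both = np.zeros((K, K))
    if resampled is None:
        resampled = _resampled_networks(systems, n_iter, fraction, alpha, seed)
    for net in resampled:
        present = [idx[node] for node in net.nodes]
        part = mcl_partition(net.adjacency(), inflation)
        pv = np.array([part[node] for node in net.nodes])
        pi = np.array(present)
        both[np.ix_(pi, pi)] += 1
        co[np.ix_(pi, pi)] += pv[:, None] == pv[None, :]
    never = np.flatnonzero(both.diagonal() == 0)
    if len(never):
        raise CoverageError(
            f"node(s) {[all_nodes[i] for i in never]} empty in every iteration"
        )
    freq = np.divide(co, both, out=np.full((K, K), np.nan), where=both > 0)
    np.fill_diagonal(freq, 1.0)
    return pd.DataFrame(freq, index=all_nodes, columns=all_nodes)


def stability_scores(
    cluster_of: dict[str, int], frequency: pd.DataFrame
) -> dict[str, float]:
    """Per-node stability: mean co-cluster frequency with its cluster mates.

    Undefined (NaN) for nodes in singleton clusters.
    """
    out: dict[str, float] = {}
    for node, cid in cluster_of.items():
        mates = [m for m, c in cluster_of.items() if c == cid and m != node]
        if not mates:
            out[node] = float("nan")
        else:
            out[node] = float(np.nanmean([frequency.loc[node, m] for m in mates]))
    return out


def weighted_silhouette(
    cluster_of: dict[str, int],
    frequency: pd.DataFrame,
    weights: dict[str, float],
) -> float:
    """Stability-weighted mean silhouette width with dissimilarity 1 - frequency.

    Nodes in singleton clusters have no silhouette value and are excluded
    from the weighted mean (logged).  Returns NaN when no node contributes.
    """
    D = 1.0 - frequency
    num = den = 0.0
    n_excluded = 0
    cluster_members: dict[int, list[str]] = {}
    for node, cid in cluster_of.items():
        cluster_members.setdefault(cid, []).append(node)
    for node, cid in cluster_of.items():
        own = [m for m in cluster_members[cid] if m != node]
        if not own:
            n_excluded += 1
            continue
        a = float(np.nanmean([D.loc[node, m] for m in own]))
        b = np.inf
        for other_cid, members in cluster_members.items():
            if other_cid == cid:
                continue
            b = min(b, float(np.nanmean([D.loc[node, m] for m in members])))
        if not np.isfinite(b):
            n_excluded += 1  # single cluster overall: silhouette undefined
            continue
        s = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
        w = weights.get(node, float("nan"))
        if np.isnan(w):
            n_excluded += 1
            continue
        num += w * s
        den += w
    if n_excluded:
        logger.debug("silhouette: %d node(s) excluded (singletons/undefined)", n_excluded)
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# inflation sweep
# ---------------------------------------------------------------------------

def select_inflation(
    systems: list[SubtypeSystem],
    inflation_grid: np.ndarray | None = None,
    min_core: int = 50,
    n_iter: int = 1000,
    fraction: float = 0.8,
    alpha: float = 0.001,
    core_alpha: float = 0.05,
    seed: int = 0,
) -> tuple[NetworkClustering, pd.DataFrame]:
    """Sweep MCL inflation factors and choose the clustering to keep.

    For each inflation on the grid (default 1.0..10.0 step 0.25): cluster the
    full network, compute resampling co-cluster frequencies and per-node
    stability scores, and evaluate the stability-weighted silhouette.
    Inflations whose downstream core-sample counts leave any multi-node
    cluster below ``min_core`` are disqualified, as are all-singleton
    partitions (undefined silhouette).  Among the qualifying inflations, the
    "maximal plateau" is the contiguous run of grid points within 0.01 of the
    maximum silhouette that contains the maximum; the lowest inflation of
    that run wins.

    Returns the chosen :class:`NetworkClustering` and a per-inflation
    diagnostics table.
    """
    from .core import assign_core_samples  # late import: core has no network dependency

    if inflation_grid is None:
        inflation_grid = np.arange(1.0, 10.0 + 1e-9, 0.25)
    inflation_grid = np.asarray(inflation_grid, dtype=float)
    if inflation_grid.size == 0:
        raise ValueError("inflation grid is empty")

    network = build_network(systems, alpha=alpha)
    adjacency = network.adjacency()
    resampled = _resampled_networks(systems, n_iter, fraction, alpha, seed)

    rows = []
    candidates: dict[float, NetworkClustering] = {}
    for infl in inflation_grid:
        cluster_of = mcl_partition(adjacency, infl)
        freq = stability_frequencies(
            systems, infl, n_iter=n_iter, fraction=fraction,
            alpha=alpha, seed=seed, resampled=resampled,
        )
        stab = stability_scores(cluster_of, freq)
        sil = weighted_silhouette(cluster_of, freq, stab)
        clustering = NetworkClustering(
            inflation=float(infl), cluster_of=cluster_of, frequency=freq,
            stability=stab, weighted_silhouette=sil,
        )
        sizes = [len(m) for m in clustering.clusters().values()]
        reason = ""
        qualified = True
        if np.isnan(sil):
            qualified, reason = False, "silhouette undefined (all clusters singletons)"
            min_core_count = 0
        else:
            consensus = assign_core_samples(systems, cluster_of, alpha=core_alpha)
            multi = [cid for cid, m in clustering.clusters().items() if len(m) >= 2]
            core_counts = [consensus.cluster_sizes.get(cid, 0) for cid in multi]
            min_core_count = min(core_counts) if core_counts else 0
            if not multi or min_core_count < min_core:
                qualified, reason = False, f"smallest multi-node cluster has {min_core_count} core samples (< {min_core})"
        rows.append(
            {
                "inflation": float(infl),
                "n_clusters": len(sizes),
                "n_singletons": sum(1 for s in sizes if s == 1),
                "weighted_silhouette": sil,
                "min_core_count": min_core_count,
                "qualified": qualified,
                "reason": reason,
            }
        )
        if qualified:
            candidates[float(infl)] = clustering
        else:
            logger.info("inflation %.2f disqualified: %s", infl, reason)

    diagnostics = pd.DataFrame(rows)
    if not candidates:
        raise InflationSelectionError(
            f"no inflation on the grid satisfies min_core={min_core}; "
            "lower min_core explicitly if the training domain is small"
        )
    qual = diagnostics[diagnostics["qualified"]]
    sils = qual["weighted_silhouette"].to_numpy()
    infls = qual["inflation"].to_numpy()
    best_pos = int(np.argmax(sils))
    on_plateau = sils >= sils[best_pos] - 0.01
    start = best_pos
    while start > 0 and on_plateau[start - 1]:
        start -= 1
    chosen = float(infls[start])
    return candidates[chosen], diagnostics
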