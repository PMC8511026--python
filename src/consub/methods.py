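"""The six independent subtyping methods (A-F).

Each method filters genes, clusters samples with an unsupervised algorithm,
and automatically selects a number of clusters k in 2..8:

* A-C: resampled consensus clustering around hierarchical clustering on
  1-Pearson distance (A: MAD > 0.5 filter, average linkage, gene resampling;
  B: top 15% variance, Ward, sample resampling; C: variance-test screen then
  top 10% CV, Ward, gene+sample resampling), k selected from the consensus
  CDF-area plateau.
* D: top 5% IQR filter, PAM (k-medoids) with the gap statistic.
* E/F: non-negative matrix factorization; rank from the elbow of the
  reconstruction-error curve, gene set by cophenetic coefficient (E sweeps
  SD thresholds; F uses an IQR > 1.2 filter).

Every stochastic step takes an explicit integer seed; per-resample generators
are ``numpy.random.default_rng([seed, counter])`` so any single resample can
be replayed in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .expression import ExpressionMatrix, FilterRule, filter_genes, gene_stats

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """A sample vector has zero variance; Pearson correlation is undefined."""


class UndefinedConsensusEntryError(ValueError):
    """A sample pair was never co-included across resamples."""


@dataclass(frozen=True)
class SubtypeSystem:
    """One method's partition of the training samples into labeled subtypes."""

    method_id: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        k = len(set(self.labels.values()))
        if not 2 <= k <= 8:
            raise ValueError(f"subtype system {self.method_id}: k={k} outside 2..8")

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def subtype_names(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def members(self, subtype: str) -> set[str]:
        return {s for s, l in self.labels.items() if l == subtype}

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.labels.values():
            out[l] = out.get(l, 0) + 1
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name=self.method_id)


@dataclass(frozen=True)
class ConsensusMatrixResult:
    """Consensus (co-clustering fraction) matrix and derived quantities at one k."""

    k: int
    consensus: pd.DataFrame
    cdf_area: float
    final_labels: pd.Series  # sample -> 1..k


@dataclass(frozen=True)
class KSelection:
    k: int
    areas: pd.Series   # indexed by k
    deltas: pd.Series  # indexed by k (k >= k_min+1): relative area gain from k-1 to k


@dataclass(frozen=True)
class MethodConfig:
    """Configuration of one subtyping method.

    ``clusterer`` chooses the algorithm family; fields irrelevant to the
    chosen family are ignored.  ``n_resamples``/``nmf_runs``/``n_reference``
    defaults follow the full-scale protocol; reduced-scale runs must set them
    explicitly (see :func:`default_method_configs`).
    """

    method_id: str
    clusterer: str = "hierarchical"            # hierarchical | pam | nmf
    gene_filter: FilterRule | None = None
    linkage: str = "average"                   # average | ward
    resample_mode: str = "genes"               # genes | samples | both
    resample_fraction: float = 0.9
    n_resamples: int = 1000
    k_range: tuple[int, int] = (2, 8)
    plateau_tolerance: float = 0.025
    # PAM / gap statistic
    n_reference: int = 100
    # NMF
    sd_thresholds: tuple[float, ...] = (0.5, 0.8, 1.0, 1.1)
    nmf_runs: int = 30
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.resample_fraction <= 1:
            raise ValueError("resample_fraction must be in (0, 1]")
        lo, hi = self.k_range
        if not (2 <= lo <= hi <= 8):
            raise ValueError("k_range must lie within 2..8")
        if self.clusterer not in {"hierarchical", "pam", "nmf"}:
            raise ValueError(f"unknown clusterer {self.clusterer!r}")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _corr_distance_values(X: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """1 - Pearson correlation between columns of X (genes x samples)."""
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmin(sd))
        name = sample_ids[j] if sample_ids else f"column {j}"
        raise UndefinedCorrelationError(
            f"sample {name!r} has zero variance; 1-Pearson distance undefined"
        )
    D = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def correlation_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample x sample 1-Pearson distance (symmetric, zero diagonal, in [0, 2])."""
    D = _corr_distance_values(matrix.values, matrix.sample_ids)
    return pd.DataFrame(D, index=matrix.sample_ids, columns=matrix.sample_ids)


def _hierarchical_cut(D: np.ndarray, method: str, ks: list[int]) -> np.ndarray:
    """Cluster a square distance matrix; returns (n, len(ks)) label array."""
    Z = linkage(squareform(D, checks=False), method=method)
    return cut_tree(Z, n_clusters=ks)


# ---------------------------------------------------------------------------
# consensus clustering (methods A-C)
# ---------------------------------------------------------------------------

def consensus_cluster(
    matrix: ExpressionMatrix, config: MethodConfig, seed: int
) -> list[ConsensusMatrixResult]:
    """Resampled consensus clustering over ``config.k_range``.

    Per resample ``r`` (generator ``default_rng([seed, r])``): draw the
    configured fraction of genes and/or samples, cluster the resampled matrix
    hierarchically on 1-Pearson distance, and record co-cluster indicators at
    every k.  The consensus entry for a sample pair is the fraction of
    resamples co-clustering the pair among resamples co-including it.  The
    final partition at each k re-clusters 1-consensus with the same linkage.

    The CDF area reported for each k is the exact area under the empirical
    CDF of the off-diagonal consensus entries, i.e. ``1 - mean(entries)``.
    """
    X = matrix.values
    n_genes, n = X.shape
    lo, hi = config.k_range
    ks = list(range(lo, hi + 1))
    counts = np.zeros((len(ks), n, n))
    incl = np.zeros((n, n))

    n_gene_pick = max(2, int(round(config.resample_fraction * n_genes)))
    n_sample_pick = max(3, int(round(config.resample_fraction * n)))
    pick_genes = config.resample_mode in ("genes", "both")
    pick_samples = config.resample_mode in ("samples", "both")

    for r in range(config.n_resamples):
        rng = np.random.default_rng([seed, r])
        gidx = (
            np.sort(rng.choice(n_genes, n_gene_pick, replace=False))
            if pick_genes
            else np.arange(n_genes)
        )
        sidx = (
            np.sort(rng.choice(n, n_sample_pick, replace=False))
            if pick_samples
            else np.arange(n)
        )
        sub = X[np.ix_(gidx, sidx)]
        cuts = _hierarchical_cut(_corr_distance_values(sub), config.linkage, ks)
        ix = np.ix_(sidx, sidx)
        incl[ix] += 1
        for j in range(len(ks)):
            lab = cuts[:, j]
            counts[j][ix] += lab[:, None] == lab[None, :]

    off_diag = ~np.eye(n, dtype=bool)
    if np.any(incl[off_diag] == 0):
        i, j = np.argwhere((incl == 0) & off_diag)[0]
        raise UndefinedConsensusEntryError(
            f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} were never "
            f"co-included in {config.n_resamples} resamples; increase n_resamples"
        )

    results = []
    for j, k in enumerate(ks):
        consensus = np.where(incl > 0, counts[j] / np.maximum(incl, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        area = float(1.0 - consensus[off_diag].mean())
        final = _hierarchical_cut(1.0 - consensus, config.linkage, [k])[:, 0] + 1
        results.append(
            ConsensusMatrixResult(
                k=k,
                consensus=pd.DataFrame(consensus, index=matrix.sample_ids, columns=matrix.sample_ids),
                cdf_area=area,
                final_labels=pd.Series(final, index=matrix.sample_ids),
            )
        )
    return results


def select_k_by_cdf(
    results: list[ConsensusMatrixResult],
    tolerance: float = 0.025,
    dominance: float = 2.0,
) -> KSelection:
    """Pick k at the plateau of the consensus-CDF area curve.

    The relative gain at k is ``delta(k) = (A(k) - A(k-1)) / A(k-1)``.  The
    selected k is the largest one whose gain is at least ``tolerance`` AND at
    least ``dominance`` times every later gain; if no k qualifies, the
    smallest candidate k is returned.  An absolute tolerance alone is not a
    reliable plateau test: splitting a true cluster still moves fractional
    consensus entries around and yields gains of a few percent indefinitely,
    so a gain only counts as structure when it clearly dominates everything
    after it.  Decreases in area beyond the tolerance produce a warning only
    — sampling noise can make the curve locally non-monotone.
    """
    ks = [r.k for r in results]
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("results must cover consecutive k")
    areas = pd.Series([r.cdf_area for r in results], index=ks)
    eps = 1e-12
    deltas = pd.Series(
        [
            (areas[k] - areas[k - 1]) / max(areas[k - 1], eps)
            for k in ks[1:]
        ],
        index=ks[1:],
    )
    if (deltas < -tolerance).any():
        worst = deltas.idxmin()
        warnings.warn(
            f"consensus CDF area decreases by {-deltas[worst]:.3f} at k={worst}",
            stacklevel=2,
        )
    k_sel = ks[0]
    # the largest selectable k is ks[-1] - 1: declaring a plateau requires at
    # least one later gain to have fallen off
    for k in reversed(ks[1:-1]):
        later = deltas[deltas.index > k]
        if deltas[k] >= tolerance and (deltas[k] >= dominance * later).all():
            k_sel = k
            break
    return KSelection(k=int(k_sel), areas=areas, deltas=deltas)


# ---------------------------------------------------------------------------
# PAM + gap statistic (method D)
# ---------------------------------------------------------------------------

def pam(D: np.ndarray, k: int, max_swaps: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partition Around Medoids on a square dissimilarity matrix.

    Classical build phase (greedy min-cost seeding) followed by swap phase to
    convergence.  Returns (medoid indices, labels as medoid positions 0..k-1).
    Ties break to the lowest index, so the result is deterministic.
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} invalid for n={n}")
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    for _ in range(max_swaps):
        dm = D[:, medoids]                       # (n, k)
        nearest = dm.min(axis=1)
        which = dm.argmin(axis=1)
        part = np.partition(dm, 1, axis=1)
        second = part[:, 1] if k > 1 else np.full(n, np.inf)
        cost = nearest.sum()
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            fallback = np.where(which == mi, second, nearest)
            new_costs = np.minimum(fallback[:, None], D).sum(axis=0)
            new_costs[medoids] = np.inf
            h = int(np.argmin(new_costs))
            delta = new_costs[h] - cost
            if delta < best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)

    medoids_arr = np.asarray(medoids)
    labels = D[:, medoids_arr].argmin(axis=1)
    return medoids_arr, labels


def _within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of pairwise dissimilarities) / (2 * size)."""
    w = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            w += D[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return w


def pam_with_gap(
    matrix: ExpressionMatrix,
    k_range: tuple[int, int] = (2, 8),
    n_reference: int = 100,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """PAM over 1-Pearson distance with k selected by the gap statistic.

    Reference datasets draw each gene uniformly over its observed range; the
    full distance+PAM pipeline is re-run on each.  k is chosen by the
    one-standard-error rule (smallest k with
    ``gap(k) >= gap(k+1) - se(k+1)``), falling back to argmax gap.

    Returns (labels 1..k, diagnostics table with gap and se per k).
    """
    if n_reference < 2:
        raise ValueError("n_reference must be >= 2")
    X = matrix.values
    lo, hi = k_range
    ks = list(range(lo, hi + 1))
    D = _corr_distance_values(X, matrix.sample_ids)
    log_w = np.empty(len(ks))
    labels_by_k = {}
    for j, k in enumerate(ks):
        _, lab = pam(D, k)
        labels_by_k[k] = lab
        log_w[j] = np.log(_within_dispersion(D, lab))

    gmin, gmax = X.min(axis=1), X.max(axis=1)
    log_w_ref = np.empty((n_reference, len(ks)))
    for b in range(n_reference):
        rng = np.random.default_rng([seed, 10_000 + b])
        ref = rng.uniform(gmin[:, None], gmax[:, None], size=X.shape)
        Dref = _corr_distance_values(ref)
        for j, k in enumerate(ks):
            _, lab = pam(Dref, k)
            log_w_ref[b, j] = np.log(_within_dispersion(Dref, lab))

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)
    k_sel = ks[-1] if len(ks) == 1 else None
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            k_sel = ks[j]
            break
    if k_sel is None:
        k_sel = ks[int(np.argmax(gap))]
    diagnostics = pd.DataFrame({"log_w": log_w, "gap": gap, "se": se}, index=ks)
    labels = pd.Series(labels_by_k[k_sel] + 1, index=matrix.sample_ids)
    return labels, diagnostics


# ---------------------------------------------------------------------------
# NMF with cophenetic rank selection (methods E, F)
# ---------------------------------------------------------------------------

def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between 1-consensus and the average-linkage tree distances."""
    d = squareform(1.0 - consensus, checks=False)
    if np.allclose(d, d[0] if len(d) else 0.0):
        return 1.0  # degenerate: all pairs equally (dis)similar
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def nmf_consensus_run(
    X: np.ndarray, k: int, n_runs: int, run_seeds: np.ndarray,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Run NMF ``n_runs`` times at rank k.

    Returns (consensus matrix, best-run labels, cophenetic coefficient,
    minimum reconstruction error).
    """
    n = X.shape[1]
    conn = np.zeros((n, n))
    best_err, best_labels = np.inf, None
    X32 = np.asarray(X, dtype=np.float32)  # halves the multiplicative-update cost
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence at capped max_iter is expected
        for r in range(n_runs):
            model = NMF(
                n_components=k, init="random", solver="mu",
                beta_loss="frobenius", max_iter=max_iter, tol=tol,
                random_state=int(run_seeds[r]),
            )
            model.fit_transform(X32)
            labels = model.components_.argmax(axis=0)
            conn += labels[:, None] == labels[None, :]
            if model.reconstruction_err_ < best_err:
                best_err = model.reconstruction_err_
                best_labels = labels
    consensus = conn / n_runs
    return consensus, best_labels, _cophenetic_coefficient(consensus), float(best_err)


def _rss_elbow(errors: dict[int, float], tolerance: float = 0.05,
               dominance: float = 2.0) -> int:
    """Rank at the elbow of the reconstruction-error curve.

    The drop ``d(k) = err(k-1) - err(k)`` collapses to a flat noise-fitting
    rate once k exceeds the effective rank of the data.  The selected k is
    the largest one (below the top of the range) whose drop is at least
    ``tolerance`` of the total error range and at least ``dominance`` times
    every later drop; if none qualifies, the smallest k.
    """
    ks = sorted(errors)
    drops = {k: errors[k - 1] - errors[k] for k in ks[1:]}
    total = errors[ks[0]] - errors[ks[-1]]
    if total <= 0:
        return ks[0]
    for k in reversed(ks[1:-1]):
        later = [drops[j] for j in drops if j > k]
        if drops[k] >= tolerance * total and drops[k] >= dominance * max(later):
            return k
    return ks[0]


def nmf_subtype(
    matrix: ExpressionMatrix,
    sd_thresholds: tuple[float, ...] = (0.5, 0.8, 1.0, 1.1),
    k_range: tuple[int, int] = (2, 8),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    gene_filter: FilterRule | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Subtype by NMF: error-elbow rank per gene set, cophenetic choice of gene set.

    Log expression is shifted to non-negative by subtracting the global
    minimum.  For each candidate gene set (``sd > t`` for each threshold, or
    the explicit ``gene_filter`` if given) and each k, NMF runs ``n_runs``
    times from random initializations, recording the run-consensus matrix,
    its cophenetic coefficient, and the best reconstruction error.  Within a
    gene set the rank is taken at the elbow of the reconstruction-error
    curve (see :func:`_rss_elbow`); among gene sets the one whose consensus
    at its chosen rank has the highest cophenetic coefficient wins (ties
    prefer the smaller rank, then the earlier gene set).  Sample labels are
    read from the winning gene set's run-consensus matrix (average-linkage
    cut at the chosen rank) rather than from any single factorization, whose
    dominant-metagene assignment can be an outlier partition.

    The cophenetic coefficient alone cannot set the rank on weakly filtered
    gene sets: run-consensus stability saturates near 1 for every k at or
    above the effective rank and its ordering between neighbouring ks is
    then dominated by noise, while the error curve's slope change at the
    effective rank stays sharp.  The coefficient remains the arbiter between
    gene sets, where its differences are large.

    Returns (labels 1..k, diagnostics with error and cophenetic coefficient
    per (gene set, k)).
    """
    stats_table = gene_stats(matrix)
    if gene_filter is not None:
        candidates = [("filter", np.asarray([g in set(gene_filter.apply(stats_table)) for g in matrix.gene_ids]))]
    else:
        candidates = []
        for t in sd_thresholds:
            mask = stats_table["sd"].to_numpy() > t
            # thresholds that retain identical gene sets are computed once
            for prev_name, prev_mask in candidates:
                if np.array_equal(mask, prev_mask):
                    logger.info("gene set for sd>%s identical to %s; merged", t, prev_name)
                    break
            else:
                candidates.append((f"sd>{t}", mask))
    X_all = matrix.values
    global_min = X_all.min()
    shift = -global_min if global_min < 0 else 0.0

    lo, hi = k_range
    ks = list(range(lo, hi + 1))
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(len(candidates) * len(ks) * n_runs).reshape(
        len(candidates), len(ks), n_runs
    ) % (2**31)

    rows = []
    best = None
    for ci, (name, mask) in enumerate(candidates):
        if mask.sum() < 2:
            rows.append({"gene_set": name, "n_genes": int(mask.sum()), "k": np.nan,
                         "error": np.nan, "cophenetic": np.nan, "chosen_k": False})
            continue
        Xc = X_all[mask] + shift
        if Xc.min() < 0:
            raise ValueError("NMF input has negative values after shift policy")
        errors, cophs, labels_by_k = {}, {}, {}
        for kj, k in enumerate(ks):
            consensus_k, _, coph, err = nmf_consensus_run(
                Xc, k, n_runs, run_seeds[ci, kj], max_iter, tol
            )
            errors[k], cophs[k] = err, coph
            # label from the run consensus, not a single factorization: the
            # minimum-error run can still be an outlier partition
            labels_by_k[k] = _hierarchical_cut(1.0 - consensus_k, "average", [k])[:, 0]
        k_c = _rss_elbow(errors)
        for k in ks:
            rows.append({"gene_set": name, "n_genes": int(mask.sum()), "k": k,
                         "error": errors[k], "cophenetic": cophs[k],
                         "chosen_k": k == k_c})
        key = (cophs[k_c], -k_c, -ci)  # max coph; ties -> smaller k, earlier gene set
        if best is None or key > best[0]:
            best = (key, labels_by_k[k_c])
    if best is None:
        raise ValueError("no candidate gene set retained >=2 genes")
    diagnostics = pd.DataFrame(rows)
    raw = best[1]
    # renumber labels 1..k' consecutively, ordered by first appearance
    seen: dict[int, int] = {}
    final = np.array([seen.setdefault(int(l), len(seen) + 1) for l in raw])
    return pd.Series(final, index=matrix.sample_ids), diagnostics


# ---------------------------------------------------------------------------
# method dispatch
# ---------------------------------------------------------------------------

def default_method_configs(profile: str = "full") -> dict[str, MethodConfig]:
    """The six standard method configurations.

    ``profile="full"`` uses full-scale resampling counts (1000 consensus
    resamples, 30 NMF runs, 100 gap references); ``profile="desk"`` is an
    explicit reduced-scale profile for interactive and test use (100
    consensus resamples, 6 NMF runs at a looser NMF tolerance, 20 gap
    references).  Scale never changes silently: it is part of the config.
    """
    if profile not in {"full", "desk"}:
        raise ValueError(f"unknown profile {profile!r}")
    desk = profile == "desk"
    n_res = 100 if desk else 1000
    nmf_runs = 10 if desk else 30
    nmf_iter = 500
    nmf_tol = 1e-5 if desk else 1e-6
    n_ref = 20 if desk else 100
    return {
        "A": MethodConfig(
            method_id="A", clusterer="hierarchical",
            gene_filter=FilterRule("threshold", "mad", 0.5),
            linkage="average", resample_mode="genes", n_resamples=n_res,
        ),
        "B": MethodConfig(
            method_id="B", clusterer="hierarchical",
            gene_filter=FilterRule("top_fraction", "variance", 0.15),
            linkage="ward", resample_mode="samples", n_resamples=n_res,
        ),
        "C": MethodConfig(
            method_id="C", clusterer="hierarchical",
            gene_filter=FilterRule("var_test_then_top_cv", "cv", 0.10, p_threshold=0.01),
            linkage="ward", resample_mode="both", n_resamples=n_res,
        ),
        "D": MethodConfig(
            method_id="D", clusterer="pam",
            gene_filter=FilterRule("top_fraction", "iqr", 0.05),
            n_reference=n_ref,
        ),
        "E": MethodConfig(
            method_id="E", clusterer="nmf",
            sd_thresholds=(0.5, 0.8, 1.0, 1.1),
            nmf_runs=nmf_runs, nmf_max_iter=nmf_iter, nmf_tol=nmf_tol,
        ),
        "F": MethodConfig(
            method_id="F", clusterer="nmf",
            gene_filter=FilterRule("threshold", "iqr", 1.2),
            nmf_runs=nmf_runs, nmf_max_iter=nmf_iter, nmf_tol=nmf_tol,
        ),
    }


def run_method(matrix: ExpressionMatrix, config: MethodConfig, seed: int) -> SubtypeSystem:
    """Run one subtyping method end to end; labels are prefixed by method id."""
    if config.clusterer == "hierarchical":
        filtered, _ = filter_genes(matrix, config.gene_filter)
        results = consensus_cluster(filtered, config, seed)
        sel = select_k_by_cdf(results, config.plateau_tolerance)
        labels = results[sel.k - config.k_range[0]].final_labels
    elif config.clusterer == "pam":
        filtered, _ = filter_genes(matrix, config.gene_filter)
        labels, _ = pam_with_gap(filtered, config.k_range, config.n_reference, seed)
    elif config.clusterer == "nmf":
        labels, _ = nmf_subtype(
            matrix,
            sd_thresholds=config.sd_thresholds,
            k_range=config.k_range,
            n_runs=config.nmf_runs,
            seed=seed,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
            gene_filter=config.gene_filter,
        )
    else:  # pragma: no cover - guarded by MethodConfig validation
        raise ValueError(config.clusterer)
    return SubtypeSystem(
        method_id=config.method_id,
        labels={s: f"{config.method_id}{int(c)}" for s, c in labels.items()},
    )


def run_all_methods(
    matrix: ExpressionMatrix, configs: dict[str, MethodConfig], seed: int
) -> list[SubtypeSystem]:
    """Run every configured method on the same training matrix."""
    if not configs:
        raise ValueError("no methods configured")
    return [run_method(matrix, cfg, seed) for cfg in configs.values()]
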