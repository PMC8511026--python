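"""k Top-Scoring Pairs (kTSP) classifiers and the Multi-kTSP ensemble.

A TSP compares the expression of two genes *within* one sample, so every
classifier here is invariant to strictly increasing per-sample transforms
(quantile normalization, rank transforms, monotone batch distortions) — the
property that makes it a single-sample subtype predictor.

Layers:

* ``KTSPModel`` — binary classifier: k disjoint gene pairs vote by within-
  sample ordering, majority wins (k odd).
* ``MulticlassKTSP`` — one kTSP per unordered class pair; a sample takes the
  modal pairwise prediction, or ``"tie"`` if no unique mode exists.
* ``MultiKTSPModel`` — m multiclass models, each trained on a random 75%
  subset of a candidate gene pool (the most-varying 1500 genes); the
  ensemble prediction is the modal sub-model label, or ``"tie"``.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import accuracy_score, cohen_kappa_score

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

TIE = "tie"
_MODEL_FORMAT_VERSION = 1


class PairSelectionError(ValueError):
    """Too few disjoint candidate pairs for the requested k."""


class StratificationError(ValueError):
    """A class is too small for the requested stratified split."""


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairScore:
    delta: float       # |P(X_i > X_j | A) - P(X_i > X_j | B)|
    rank_score: float  # secondary tie-break: |mean rank gap in A - mean rank gap in B|


def pair_score(
    matrix: ExpressionMatrix, labels: pd.Series, gene_i: str, gene_j: str
) -> PairScore:
    """Score one ordered gene pair for separating two classes.

    ``delta`` is the classical TSP statistic: the absolute difference between
    the two classes of the within-class frequency of ``gene_i > gene_j``.
    ``rank_score`` is the secondary statistic used to break delta ties: the
    absolute between-class difference of the average within-sample rank gap
    of the two genes.
    """
    for g in (gene_i, gene_j):
        if g not in matrix.data.index:
            raise KeyError(f"gene {g!r} not in matrix")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got {list(classes)}")
    X = matrix.values
    R = rankdata(X, axis=0)
    gi = matrix.data.index.get_loc(gene_i)
    gj = matrix.data.index.get_loc(gene_j)
    freqs, gaps = [], []
    for c in classes:
        cols = np.flatnonzero((labels.reindex(matrix.sample_ids) == c).to_numpy())
        if len(cols) == 0:
            raise ValueError(f"class {c!r} has no samples")
        freqs.append((X[gi, cols] > X[gj, cols]).mean())
        gaps.append((R[gi, cols] - R[gj, cols]).mean())
    return PairScore(delta=abs(freqs[0] - freqs[1]), rank_score=abs(gaps[0] - gaps[1]))


def _greedy_disjoint_pairs(
    delta: np.ndarray, gamma: np.ndarray, k_max: int, shortlist: int = 4000
) -> list[tuple[int, int]]:
    """Greedy gene-disjoint pair selection by descending (delta, gamma).

    Exact lexicographic order whenever the number of candidate pairs is at
    most ``shortlist`` (all oracle-scale inputs); above that, candidates are
    shortlisted by delta first, which preserves the greedy order except for
    delta ties straddling the shortlist boundary.
    """
    p = delta.shape[0]
    iu, ju = np.triu_indices(p, 1)
    dv, gv = delta[iu, ju], gamma[iu, ju]
    if len(dv) > shortlist:
        keep = np.argpartition(-dv, shortlist - 1)[:shortlist]
        iu, ju, dv, gv = iu[keep], ju[keep], dv[keep], gv[keep]
    order = np.lexsort((ju, iu, -gv, -dv))
    used = np.zeros(p, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairs.append((i, j))
        if len(pairs) == k_max:
            break
    return pairs


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KTSPModel:
    """Binary kTSP: ``gene_i > gene_j`` votes ``label_a``, else ``label_b``."""

    label_a: str
    label_b: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        genes = [g for pr in self.pairs for g in pr]
        if len(genes) != len(set(genes)):
            raise PairSelectionError("gene pairs must be mutually disjoint")
        if len(self.pairs) % 2 == 0 or len(self.pairs) < 1:
            raise ValueError(f"k must be odd and >= 1, got {len(self.pairs)}")

    @property
    def k(self) -> int:
        return len(self.pairs)

    def predict(self, profile: pd.Series) -> str:
        votes_a = sum(1 for gi, gj in self.pairs if profile[gi] > profile[gj])
        return self.label_a if votes_a * 2 > self.k else self.label_b


@dataclass(frozen=True)
class MulticlassKTSP:
    """One-vs-one ensemble of binary kTSP models over n classes."""

    classes: tuple[str, ...]
    models: tuple[KTSPModel, ...]   # one per unordered class pair

    def __post_init__(self) -> None:
        n = len(self.classes)
        if len(self.models) != n * (n - 1) // 2:
            raise ValueError("need exactly one sub-model per unordered class pair")

    def predict(self, profile: pd.Series) -> str:
        votes = Counter(m.predict(profile) for m in self.models)
        return _unique_mode(votes)

    def predict_matrix(self, matrix: ExpressionMatrix) -> pd.Series:
        X, index = matrix.values, matrix.data.index
        loc = {g: i for i, g in enumerate(index)}
        n = matrix.n_samples
        per_model = []
        for m in self.models:
            gi = np.array([loc[a] for a, _ in m.pairs])
            gj = np.array([loc[b] for _, b in m.pairs])
            votes_a = (X[gi] > X[gj]).sum(axis=0)
            per_model.append(np.where(votes_a * 2 > m.k, m.label_a, m.label_b))
        out = [
            _unique_mode(Counter(per_model[mi][s] for mi in range(len(self.models))))
            for s in range(n)
        ]
        return pd.Series(out, index=matrix.sample_ids)


def _unique_mode(votes: Counter) -> str:
    if not votes:
        return TIE
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return TIE
    return ranked[0][0]


@dataclass(frozen=True)
class MultiKTSPModel:
    """Ensemble of m multiclass kTSP models over gene-pool resamples."""

    candidate_pool: tuple[str, ...]
    gene_subsets: tuple[tuple[str, ...], ...]
    models: tuple[MulticlassKTSP, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.models) != len(self.gene_subsets) or not self.models:
            raise ValueError("one gene subset per model, m >= 1")
        pool = set(self.candidate_pool)
        for sub in self.gene_subsets:
            if not set(sub) <= pool:
                raise ValueError("gene subsets must lie inside the candidate pool")

    @property
    def m(self) -> int:
        return len(self.models)

    def truncate(self, m: int) -> "MultiKTSPModel":
        """The ensemble of the first m members (members depend only on (seed, index))."""
        if not 1 <= m <= self.m:
            raise ValueError(f"cannot truncate ensemble of {self.m} to m={m}")
        return MultiKTSPModel(
            candidate_pool=self.candidate_pool,
            gene_subsets=self.gene_subsets[:m],
            models=self.models[:m],
            seed=self.seed,
        )

    def predict(self, profile: pd.Series) -> str:
        tallies = Counter(
            lab for lab in (m.predict(profile) for m in self.models) if lab != TIE
        )
        return _unique_mode(tallies)

    def predict_matrix(self, matrix: ExpressionMatrix) -> pd.Series:
        per_model = [m.predict_matrix(matrix) for m in self.models]
        out = []
        for s in matrix.sample_ids:
            tallies = Counter(pm[s] for pm in per_model if pm[s] != TIE)
            out.append(_unique_mode(tallies))
        return pd.Series(out, index=matrix.sample_ids)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "seed": self.seed,
            "candidate_pool": list(self.candidate_pool),
            "gene_subsets": [list(s) for s in self.gene_subsets],
            "models": [
                {
                    "classes": list(mc.classes),
                    "submodels": [
                        {
                            "label_a": m.label_a,
                            "label_b": m.label_b,
                            "pairs": [list(pr) for pr in m.pairs],
                        }
                        for m in mc.models
                    ],
                }
                for mc in self.models
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MultiKTSPModel":
        payload = json.loads(text)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {payload.get('format_version')}")
        models = tuple(
            MulticlassKTSP(
                classes=tuple(mc["classes"]),
                models=tuple(
                    KTSPModel(
                        label_a=sm["label_a"],
                        label_b=sm["label_b"],
                        pairs=tuple(tuple(pr) for pr in sm["pairs"]),
                    )
                    for sm in mc["submodels"]
                ),
            )
            for mc in payload["models"]
        )
        return cls(
            candidate_pool=tuple(payload["candidate_pool"]),
            gene_subsets=tuple(tuple(s) for s in payload["gene_subsets"]),
            models=models,
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _class_fold_counts(X: np.ndarray, labels: np.ndarray, classes: list[str],
                       n_folds: int, rng: np.random.Generator):
    """Per (class, fold): pairwise greater-than counts, rank sums, sizes.

    One pass over samples; fold- and class-level score matrices are then
    formed by summing blocks, so cross-validation costs no extra passes.
    """
    p, n = X.shape
    R = rankdata(X, axis=0)
    counts = np.zeros((len(classes), n_folds, p, p), dtype=np.uint16)
    rank_sums = np.zeros((len(classes), n_folds, p))
    sizes = np.zeros((len(classes), n_folds), dtype=int)
    fold_of = np.empty(n, dtype=int)
    for ci, c in enumerate(classes):
        cols = np.flatnonzero(labels == c)
        fold_of[cols[rng.permutation(len(cols))]] = np.arange(len(cols)) % n_folds
    for s in range(n):
        ci = classes.index(labels[s])
        f = fold_of[s]
        x = X[:, s]
        np.add(counts[ci, f], x[:, None] > x[None, :], out=counts[ci, f], casting="unsafe")
        rank_sums[ci, f] += R[:, s]
        sizes[ci, f] += 1
    return counts, rank_sums, sizes, fold_of


def _scores_from_counts(counts_a, counts_b, ranks_a, ranks_b, n_a, n_b):
    """(delta, gamma) matrices for one class pair from count/rank-sum blocks."""
    Pa = counts_a / n_a
    Pb = counts_b / n_b
    delta = np.abs(Pa - Pb)
    e = ranks_a / n_a - ranks_b / n_b
    gamma = np.abs(e[:, None] - e[None, :])
    return delta, gamma, Pa, Pb


def _oriented_pairs(pairs, Pa, Pb):
    """Orient each (i, j) so that gene_i > gene_j is evidence for class a."""
    oriented = []
    for i, j in pairs:
        if Pa[i, j] >= Pb[i, j]:
            oriented.append((i, j))
        else:
            oriented.append((j, i))
    return oriented


def _fit_pairwise(
    X: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray,
    label_a: str,
    label_b: str,
    counts, rank_sums, sizes, fold_of,
    classes: list[str],
    k_grid: tuple[int, ...],
) -> KTSPModel:
    """Fit one binary kTSP for classes (a, b) with internal CV choice of k."""
    p = X.shape[0]
    ai, bi = classes.index(label_a), classes.index(label_b)
    n_folds = sizes.shape[1]
    max_pairs = p // 2
    k_options = [k for k in sorted(k_grid) if k <= max_pairs]
    if not k_options:
        raise PairSelectionError(
            f"only {max_pairs} disjoint pairs available from {p} genes; "
            f"smallest requested k is {min(k_grid)}"
        )
    k_max = max(k_options)

    if len(k_options) > 1 and n_folds >= 2:
        cv_hits = {k: 0 for k in k_options}
        cv_total = 0
        cols_ab = np.flatnonzero((labels == label_a) | (labels == label_b))
        for f in range(n_folds):
            n_a = sizes[ai].sum() - sizes[ai, f]
            n_b = sizes[bi].sum() - sizes[bi, f]
            if n_a == 0 or n_b == 0:
                continue
            ca = counts[ai].sum(axis=0, dtype=np.int64) - counts[ai, f]
            cb = counts[bi].sum(axis=0, dtype=np.int64) - counts[bi, f]
            ra = rank_sums[ai].sum(axis=0) - rank_sums[ai, f]
            rb = rank_sums[bi].sum(axis=0) - rank_sums[bi, f]
            delta, gamma, Pa, Pb = _scores_from_counts(ca, cb, ra, rb, n_a, n_b)
            pairs = _oriented_pairs(_greedy_disjoint_pairs(delta, gamma, k_max), Pa, Pb)
            val = cols_ab[fold_of[cols_ab] == f]
            if len(val) == 0 or not pairs:
                continue
            gi = np.array([i for i, _ in pairs])
            gj = np.array([j for _, j in pairs])
            votes = X[np.ix_(gi, val)] > X[np.ix_(gj, val)]
            cum = np.cumsum(votes, axis=0)
            for k in k_options:
                kk = min(k, len(pairs))
                pred_a = cum[kk - 1] * 2 > kk
                truth_a = labels[val] == label_a
                cv_hits[k] += int((pred_a == truth_a).sum())
            cv_total += len(val)
        if cv_total > 0:
            acc = {k: cv_hits[k] / cv_total for k in k_options}
            best = max(acc.values())
            k_sel = min(k for k in k_options if acc[k] >= best - 0.01)
        else:
            k_sel = k_options[0]
    else:
        k_sel = k_options[0]

    n_a, n_b = sizes[ai].sum(), sizes[bi].sum()
    delta, gamma, Pa, Pb = _scores_from_counts(
        counts[ai].sum(axis=0, dtype=np.int64),
        counts[bi].sum(axis=0, dtype=np.int64),
        rank_sums[ai].sum(axis=0),
        rank_sums[bi].sum(axis=0),
        n_a, n_b,
    )
    pairs = _greedy_disjoint_pairs(delta, gamma, k_sel)
    if len(pairs) < k_sel:
        raise PairSelectionError(
            f"only {len(pairs)} disjoint pairs available, requested k={k_sel}"
        )
    oriented = _oriented_pairs(pairs, Pa, Pb)
    return KTSPModel(
        label_a=label_a,
        label_b=label_b,
        pairs=tuple((gene_ids[i], gene_ids[j]) for i, j in oriented),
    )


def fit_multiclass_ktsp(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    k_grid: tuple[int, ...] = (3, 5, 7, 9),
    seed: int = 0,
) -> MulticlassKTSP:
    """Fit one binary kTSP per class pair (shared score machinery).

    k for each sub-model is picked by internal cross-validated accuracy over
    ``k_grid`` (smallest k within 0.01 of the best fold-averaged accuracy);
    folds are stratified and derived from ``seed``.
    """
    X = matrix.values
    lab = labels.reindex(matrix.sample_ids).to_numpy()
    if pd.isna(lab).any():
        raise ValueError("labels missing for some samples")
    classes = sorted(pd.unique(lab))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    min_class = min((lab == c).sum() for c in classes)
    if min_class < 2:
        raise ValueError("every class needs >= 2 samples")
    n_folds = max(2, min(5, int(min_class)))
    rng = np.random.default_rng(seed)
    counts, rank_sums, sizes, fold_of = _class_fold_counts(X, lab, classes, n_folds, rng)
    models = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            models.append(
                _fit_pairwise(
                    X, matrix.gene_ids, lab, a, b,
                    counts, rank_sums, sizes, fold_of, classes, k_grid,
                )
            )
    return MulticlassKTSP(classes=tuple(classes), models=tuple(models))


def fit_ktsp(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    k_grid: tuple[int, ...] = (3, 5, 7, 9),
    seed: int = 0,
) -> KTSPModel:
    """Fit a binary kTSP (two-class special case of the multiclass fit)."""
    model = fit_multiclass_ktsp(matrix, labels, k_grid=k_grid, seed=seed)
    return model.models[0]


def fit_multi_ktsp(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    m: int = 500,
    pool_size: int = 1500,
    gene_fraction: float = 0.75,
    k_grid: tuple[int, ...] = (3, 5, 7, 9),
    seed: int = 0,
) -> MultiKTSPModel:
    """Fit the Multi-kTSP ensemble.

    The candidate pool is the ``pool_size`` most-varying genes of the
    training matrix (all genes, with a log note, if fewer are available).
    Member e draws ``round(gene_fraction * |pool|)`` pool genes without
    replacement using ``default_rng([seed, e])`` — so member e is identical
    across runs and across different m with the same seed.
    """
    if m < 1:
        raise ValueError("ensemble size m must be >= 1")
    variances = matrix.data.var(axis=1, ddof=1)
    if matrix.n_genes <= pool_size:
        pool = list(matrix.gene_ids)
        logger.info("gene pool capped to all %d genes (< %d)", len(pool), pool_size)
    else:
        order = np.argsort(-variances.to_numpy(), kind="stable")[:pool_size]
        keep = set(np.asarray(matrix.gene_ids)[order])
        pool = [g for g in matrix.gene_ids if g in keep]
    n_sub = int(round(gene_fraction * len(pool)))
    pool_arr = np.asarray(pool)
    subsets, models = [], []
    for e in range(m):
        rng = np.random.default_rng([seed, e])
        sub = pool_arr[np.sort(rng.choice(len(pool_arr), n_sub, replace=False))]
        subsets.append(tuple(sub))
        sub_matrix = matrix.subset_genes(list(sub))
        models.append(
            fit_multiclass_ktsp(sub_matrix, labels, k_grid=k_grid, seed=int(rng.integers(2**31)))
        )
    return MultiKTSPModel(
        candidate_pool=tuple(pool),
        gene_subsets=tuple(subsets),
        models=tuple(models),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

def stratified_split(
    labels: pd.Series, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Per-class random split into discovery/test sets (deterministic by seed)."""
    train, test = [], []
    for ci, c in enumerate(sorted(labels.unique())):
        members = list(labels.index[labels == c])
        if len(members) < 4:
            raise StratificationError(
                f"class {c!r} has {len(members)} samples; need >= 4 to stratify"
            )
        rng = np.random.default_rng([seed, 50_000 + ci])
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 2), len(members) - 2)
        train += [members[i] for i in order[:n_train]]
        test += [members[i] for i in order[n_train:]]
    return sorted(train), sorted(test)


def evaluate_predictions(truth: pd.Series, predicted: pd.Series) -> dict[str, float]:
    """Accuracy and Cohen's kappa; ``tie`` predictions count as errors."""
    truth = truth.reindex(predicted.index)
    return {
        "accuracy": float(accuracy_score(truth, predicted)),
        "kappa": float(cohen_kappa_score(truth, predicted)),
        "tie_rate": float((predicted == TIE).mean()),
    }


def train_and_select(
    matrix: ExpressionMatrix,
    consensus_labels: pd.Series,
    unclassified_label: str = "T0",
    split: tuple[float, float] = (0.75, 0.25),
    m_grid: tuple[int, ...] = (250, 500, 750),
    pool_size: int = 1500,
    gene_fraction: float = 0.75,
    k_grid: tuple[int, ...] = (3, 5, 7, 9),
    plateau_tolerance: float = 0.005,
    seed: int = 0,
) -> tuple[MultiKTSPModel, pd.DataFrame]:
    """Train Multi-kTSP on consensus subtypes and pick the ensemble size.

    Unclassified samples are excluded; the rest are split (stratified by
    consensus label) into discovery and test sets per ``split``.  One maximal
    ensemble is fitted on the discovery set and truncated to each m in
    ``m_grid`` (valid because member e depends only on (seed, e)); the
    selected m is the smallest whose test accuracy is within
    ``plateau_tolerance`` of the grid maximum.

    Returns (selected model, report with accuracy/kappa/tie rate per m).
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    labels = consensus_labels[consensus_labels != unclassified_label].dropna()
    if labels.empty:
        raise ValueError("no classified samples to train on")
    train_ids, test_ids = stratified_split(labels, split[0], seed)
    train_m = matrix.subset_samples(train_ids)
    test_m = matrix.subset_samples(test_ids)

    m_grid = tuple(sorted(m_grid))
    full = fit_multi_ktsp(
        train_m, labels[train_ids], m=m_grid[-1],
        pool_size=pool_size, gene_fraction=gene_fraction, k_grid=k_grid, seed=seed,
    )
    rows, by_m = [], {}
    for m in m_grid:
        model = full.truncate(m)
        by_m[m] = model
        metrics = evaluate_predictions(labels[test_ids], model.predict_matrix(test_m))
        rows.append({"m": m, **metrics})
    report = pd.DataFrame(rows)
    best = report["accuracy"].max()
    m_sel = int(report.loc[report["accuracy"] >= best - plateau_tolerance, "m"].min())
    report["selected"] = report["m"] == m_sel
    return by_m[m_sel], report
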