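from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from consub.methods import SubtypeSystem
from consub.network import (
    MclConvergenceError,
    bh_adjust,
    build_network,
    hypergeom_overlap_p,
    mcl,
    mcl_partition,
    select_inflation,
    stability_frequencies,
    stability_scores,
    weighted_silhouette,
)
from consub.simulate import generate_system_fixtures


def exact_overlap_tail(n_total: int, size_a: int, size_b: int, overlap: int) -> float:
    """Exact enumeration of P(X >= overlap) over all draw configurations."""
    total = comb(n_total, size_b)
    acc = Fraction(0)
    for q in range(overlap, min(size_a, size_b) + 1):
        acc += Fraction(comb(size_a, q) * comb(n_total - size_a, size_b - q), total)
    return float(acc)


class TestHypergeomOverlap:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_overlap_p(10, 4, 3, 0) == 1.0

    def test_documented_exact_values(self):
        assert hypergeom_overlap_p(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)
        assert hypergeom_overlap_p(4, 2, 2, 1) == pytest.approx(5 / 6, rel=1e-12)

    def test_matches_enumeration_for_all_small_configurations(self):
        """Exhaustive sweep n_total <= 12 against the exact combinatorial tail."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1):
                    for q in range(max(0, a + b - n), min(a, b) + 1):
                        expected = exact_overlap_tail(n, a, b, q)
                        assert hypergeom_overlap_p(n, a, b, q) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_p(10, 5, 5, 6)
        with pytest.raises(ValueError):
            hypergeom_overlap_p(4, 5, 2, 1)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.01, 0.02, 0.04], [0.02, 0.02, 0.08 / 3, 0.04]),
            ([0.5, 0.1], [0.5, 0.2]),
            ([0.01, 0.011, 0.9], [0.0165, 0.0165, 0.9]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_computed_step_up(self, raw, expected):
        np.testing.assert_allclose(bh_adjust(raw), expected, rtol=1e-12)

    def test_never_decreases_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            adj = bh_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all((adj >= 0) & (adj <= 1))

    def test_domain_violation(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _systems_from_arrays(label_arrays, method_ids):
    systems = []
    for arr, mid in zip(label_arrays, method_ids):
        labels = {f"S{i:03d}": f"{mid}{v}" for i, v in enumerate(arr)}
        systems.append(SubtypeSystem(method_id=mid, labels=labels))
    return systems


class TestBuildNetwork:
    def test_identical_partitions_form_perfect_matching(self):
        base = np.repeat([1, 2, 3], 40)
        systems = _systems_from_arrays([base, base], ["A", "B"])
        net = build_network(systems, alpha=0.001)
        edges = net.significant_edges()
        assert len(edges) == 3
        matched = {tuple(sorted((r["node_a"], r["node_b"]))) for _, r in edges.iterrows()}
        assert matched == {("A1", "B1"), ("A2", "B2"), ("A3", "B3")}

    def test_single_system_has_no_edges(self):
        base = np.repeat([1, 2, 3], 10)
        net = build_network(_systems_from_arrays([base], ["A"]))
        assert len(net.edges) == 0

    def test_same_method_nodes_never_tested(self):
        base = np.repeat([1, 2], 20)
        other = np.tile([1, 2], 20)
        net = build_network(_systems_from_arrays([base, other], ["A", "B"]))
        for _, row in net.edges.iterrows():
            assert net.node_method[row["node_a"]] != net.node_method[row["node_b"]]

    def test_mismatched_sample_sets_rejected(self):
        s1 = SubtypeSystem("A", {"x1": "A1", "x2": "A2", "x3": "A1", "x4": "A2"})
        s2 = SubtypeSystem("B", {"y1": "B1", "y2": "B2", "y3": "B1", "y4": "B2"})
        with pytest.raises(ValueError, match="sample sets"):
            build_network([s1, s2])

    def test_adjusted_p_at_least_raw(self):
        systems, _ = generate_system_fixtures(3, n_samples=90, k_latent=3,
                                              agreement=0.8, seed=2)
        net = build_network(systems)
        assert (net.edges["adj_p"] >= net.edges["raw_p"] - 1e-15).all()


def naive_mcl(A: np.ndarray, inflation: float, iters: int = 200) -> list[tuple[int, ...]]:
    """Independent literal MCL: expand, inflate, renormalize; read attractor rows.

    Deliberately naive (dense powers, no pruning heuristics) so it can serve
    as a cross-implementation oracle for the optimized version.
    """
    M = A.astype(float).copy()
    np.fill_diagonal(M, 1.0)
    M = M / M.sum(axis=0)
    for _ in range(iters):
        M = M @ M
        M = M ** inflation
        M = M / M.sum(axis=0)
        M[M < 1e-12] = 0.0
        M = M / M.sum(axis=0)
    clusters: list[set] = []
    for i in np.flatnonzero(M.diagonal() > 1e-6):
        c = set(np.flatnonzero(M[i] > 1e-6).tolist()) | {int(i)}
        for cc in clusters:
            if cc & c:
                cc |= c
                break
        else:
            clusters.append(c)
    covered = set().union(*clusters) if clusters else set()
    clusters += [{i} for i in range(A.shape[0]) if i not in covered]
    return sorted(tuple(sorted(c)) for c in clusters)


def two_clique_graph():
    A = np.zeros((10, 10))
    for block in (range(5), range(5, 10)):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1
    A[4, 5] = A[5, 4] = 1
    return A


def two_community_chord_graph():
    B = np.zeros((10, 10))
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (2, 4), (0, 4),
             (5, 6), (6, 7), (7, 8), (8, 9), (5, 7), (6, 8), (7, 9), (5, 9), (4, 5)]
    for i, j in edges:
        B[i, j] = B[j, i] = 1
    return B


class TestMcl:
    def test_disconnected_triangles_yield_components(self):
        A = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        A[i, j] = 1
        for inflation in (1.2, 2.0, 5.0):
            clusters = sorted(tuple(sorted(c)) for c in mcl(A, inflation))
            assert clusters == [(0, 1, 2), (3, 4, 5)]

    def test_single_node_is_singleton(self):
        assert mcl(np.zeros((1, 1)), 2.0) == [{0}]

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 4.0])
    @pytest.mark.parametrize("graph", [two_clique_graph, two_community_chord_graph])
    def test_matches_independent_reference_on_fixtures(self, graph, inflation):
        A = graph()
        expected = [(0, 1, 2, 3, 4), (5, 6, 7, 8, 9)]  # verified with naive_mcl
        assert naive_mcl(A, inflation) == expected
        assert sorted(tuple(sorted(c)) for c in mcl(A, inflation)) == expected

    def test_partition_never_spans_components(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n2 = rng.integers(2, 6, size=2)
            A = np.zeros((n1 + n2, n1 + n2))
            A[:n1, :n1] = rng.random((n1, n1)) < 0.8
            A[n1:, n1:] = rng.random((n2, n2)) < 0.8
            A = np.triu(A, 1)
            A = A + A.T
            for c in mcl(A, 2.0):
                assert c <= set(range(n1)) or c <= set(range(n1, n1 + n2))

    def test_column_stochasticity_is_preserved(self, monkeypatch):
        """Flow matrix columns sum to 1 within 1e-9 at every iteration."""
        import consub.network as net_mod

        sums = []
        orig = np.linalg.matrix_power

        def spy(M, p):
            sums.append(np.abs(M.sum(axis=0) - 1).max())
            return orig(M, p)

        monkeypatch.setattr(np.linalg, "matrix_power", spy)
        mcl(two_clique_graph(), 2.0)
        assert sums and max(sums) < 1e-9

    def test_nonconvergence_raises(self):
        with pytest.raises(MclConvergenceError):
            mcl(two_clique_graph(), 1.01, max_iter=2)


@pytest.fixture(scope="module")
def strong_systems():
    systems, _ = generate_system_fixtures(3, n_samples=120, k_latent=3,
                                          agreement=1.0, seed=0)
    return systems


class TestStability:

    def test_identical_systems_have_unit_matched_frequency(self, strong_systems):
        freq = stability_frequencies(strong_systems, inflation=2.0, n_iter=20,
                                     fraction=0.8, seed=0)
        for g in ("1", "2", "3"):
            assert freq.loc[f"A{g}", f"B{g}"] == 1.0
            assert freq.loc[f"B{g}", f"C{g}"] == 1.0
        assert np.all(np.diag(freq.to_numpy()) == 1.0)
        assert np.allclose(freq.to_numpy(), freq.to_numpy().T)

    def test_single_iteration_is_binary(self, strong_systems):
        freq = stability_frequencies(strong_systems, inflation=2.0, n_iter=1, seed=1)
        assert set(np.unique(freq.to_numpy())) <= {0.0, 1.0}

    def test_replay_oracle_same_seed(self, strong_systems):
        """Frequencies equal an explicit recomputation over the same subsamples."""
        from consub.network import _network_from_label_maps

        n_iter, fraction = 15, 0.8
        freq = stability_frequencies(strong_systems, inflation=2.0, n_iter=n_iter,
                                     fraction=fraction, seed=7)
        sample_ids = list(strong_systems[0].labels)
        nodes = sorted({l for s in strong_systems for l in s.subtype_names})
        idx = {n: i for i, n in enumerate(nodes)}
        co = np.zeros((len(nodes),) * 2)
        both = np.zeros_like(co)
        n_pick = round(fraction * len(sample_ids))
        for t in range(n_iter):
            rng = np.random.default_rng([7, t])
            picked = [sample_ids[i] for i in np.sort(rng.choice(len(sample_ids), n_pick, replace=False))]
            maps = [(s.method_id, {x: s.labels[x] for x in picked}) for s in strong_systems]
            net = _network_from_label_maps(maps, 0.001)
            part = mcl_partition(net.adjacency(), 2.0)
            present = np.array([idx[n] for n in net.nodes])
            pv = np.array([part[n] for n in net.nodes])
            both[np.ix_(present, present)] += 1
            co[np.ix_(present, present)] += pv[:, None] == pv[None, :]
        expected = np.divide(co, both, out=np.full_like(co, np.nan), where=both > 0)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(freq.to_numpy(), expected, atol=1e-12)

    def test_stability_scores_in_unit_interval_and_singletons_missing(self, strong_systems):
        freq = stability_frequencies(strong_systems, inflation=2.0, n_iter=10, seed=0)
        cluster_of = {n: (1 if n.endswith("1") else 2) for n in freq.index}
        cluster_of["A3"] = 99  # force a singleton
        cluster_of["B3"] = 3
        cluster_of["C3"] = 3
        scores = stability_scores(cluster_of, freq)
        assert np.isnan(scores["A3"])
        for node, s in scores.items():
            if node != "A3":
                assert 0.0 <= s <= 1.0


class TestWeightedSilhouette:
    def test_perfect_separation_scores_one(self):
        nodes = ["A1", "B1", "A2", "B2"]
        freq = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=nodes, columns=nodes, dtype=float,
        )
        cluster_of = {"A1": 1, "B1": 1, "A2": 2, "B2": 2}
        weights = {n: 1.0 for n in nodes}
        assert weighted_silhouette(cluster_of, freq, weights) == pytest.approx(1.0)

    def test_all_singletons_undefined(self):
        nodes = ["A1", "B1"]
        freq = pd.DataFrame(np.eye(2), index=nodes, columns=nodes)
        assert np.isnan(weighted_silhouette({"A1": 1, "B1": 2}, freq, {"A1": 1, "B1": 1}))


class TestSelectInflation:
    def test_planted_four_cluster_network_resolved(self):
        systems, _ = generate_system_fixtures(6, n_samples=240, k_latent=4,
                                              agreement=0.9, seed=3)
        clustering, diag = select_inflation(systems, min_core=30, n_iter=40, seed=3)
        clusters = clustering.clusters()
        multi = {cid: sorted(m) for cid, m in clusters.items() if len(m) >= 2}
        assert len(multi) == 4
        # each cluster gathers the corresponding subtype of every method
        for members in multi.values():
            groups = {m[1:] for m in members}
            assert len(groups) == 1
            assert len(members) == 6
        assert (diag["qualified"]).any()

    def test_lowest_inflation_on_plateau_chosen(self):
        systems, _ = generate_system_fixtures(4, n_samples=160, k_latent=2,
                                              agreement=1.0, seed=5)
        clustering, diag = select_inflation(systems, min_core=20, n_iter=10, seed=5)
        qual = diag[diag["qualified"]]
        top = qual["weighted_silhouette"].max()
        plateau = qual[qual["weighted_silhouette"] >= top - 0.01]
        assert clustering.inflation == plateau["inflation"].min()

    def test_min_core_unsatisfiable_raises(self):
        systems, _ = generate_system_fixtures(3, n_samples=60, k_latent=3,
                                              agreement=0.9, seed=1)
        from consub.network import InflationSelectionError

        with pytest.raises(InflationSelectionError, match="min_core"):
            select_inflation(systems, min_core=10_000, n_iter=5, seed=1)
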