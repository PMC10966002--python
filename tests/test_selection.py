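"""Conflict graph, compatible-combination enumeration, BIC best-subset
search, and pool/prune — each checked against an independent brute-force
reference."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecorisk.datagen import SyntheticSpec, generate_exposures, generate_outcome, noise_sd_for_r2
from ecorisk.screening import standardize
from ecorisk.selection import (
    FittedModel,
    adjusted_r2,
    best_subset,
    bic,
    build_conflict_graph,
    enumerate_combinations,
    n_subsets,
    pool_and_prune,
    race_candidate_mode,
)

# ---------------------------------------------------------------------------
# brute-force references


def brute_force_mis(nodes, edges):
    """All maximal independent sets by scanning every subset."""
    edge_set = {frozenset(e) for e in edges}
    independent = [
        s for r in range(len(nodes) + 1)
        for s in itertools.combinations(sorted(nodes), r)
        if not any(frozenset(p) <= set(s) for p in edge_set)
    ]
    ind_sets = [set(s) for s in independent]
    maximal = [
        tuple(sorted(s)) for s in ind_sets
        if not any(s < t for t in ind_sets)
    ]
    return sorted(set(maximal))


def brute_force_best_subset(y, X, combination, forced):
    """Independent reference: enumerate subsets, score BIC from first
    principles (no shared code with the implementation)."""
    yv = y.to_numpy()
    n = len(yv)
    best = None
    for r in range(len(combination) + 1):
        for subset in itertools.combinations(sorted(combination), r):
            cols = [np.ones(n)]
            cols += [forced[c].to_numpy() for c in forced.columns]
            cols += [X[v].to_numpy() for v in subset]
            M = np.column_stack(cols)
            if np.linalg.matrix_rank(M) < M.shape[1] or n <= M.shape[1]:
                continue
            beta = np.linalg.pinv(M) @ yv
            rss = float(np.sum((yv - M @ beta) ** 2))
            k = M.shape[1]
            b = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
            key = (b, len(subset), subset)
            if best is None or key < best[0]:
                best = (key, subset, rss, k)
    return best


def reference_pool_and_prune(models, adj_r2_min, delta_bic):
    """Literal reimplementation of the five pooling/pruning steps."""
    order = lambda m: (m.bic, len(m.selected), tuple(sorted(m.selected)))
    step1 = [m for m in models if m.adj_r2 >= adj_r2_min]
    if not step1:
        return None
    seen, step2 = {}, []
    for m in sorted(step1, key=order):
        key = frozenset(m.selected)
        if key not in seen:
            seen[key] = m
            step2.append(m)
    # nested groups = connected components of the proper-subset relation
    parent = list(range(len(step2)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(step2)), 2):
        a, b = set(step2[i].selected), set(step2[j].selected)
        if a < b or b < a:
            parent[find(i)] = find(j)
    groups = {}
    for i, m in enumerate(step2):
        groups.setdefault(find(i), []).append(m)
    survivors = sorted((min(g, key=order) for g in groups.values()), key=order)
    comparable = [m for m in survivors if m.bic - survivors[0].bic < delta_bic]
    return survivors, comparable


def _make_model(selected, bic_value, adj_r2_value):
    return FittedModel(selected=tuple(sorted(selected)), forced=("f",), n=62,
                       k=2 + len(selected), rss=1.0, tss=2.0,
                       bic=bic_value, adj_r2=adj_r2_value)


# ---------------------------------------------------------------------------


class TestConflictGraph:
    def test_duplicate_variable_makes_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        g = build_conflict_graph(X)
        assert g.edges == (("a", "b"),)

    def test_independent_noise_has_no_edges(self):
        X = generate_exposures(
            SyntheticSpec(n_counties=1000,
                          variable_blocks=tuple((1, 0.0) for _ in range(8)), seed=2)
        )
        assert build_conflict_graph(X).edges == ()

    def test_boundary_correlation_is_strict(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": 0.9 * x + z})
        r = abs(X["a"].corr(X["b"]))
        g = build_conflict_graph(X, r_threshold=r)
        assert g.edges == ()  # r == threshold exactly -> no conflict

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            build_conflict_graph(X)

    def test_pairwise_complete_observations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": x + 0.05 * rng.normal(size=60),
                          "c": rng.normal(size=60)})
        X.loc[X.index[:10], "c"] = np.nan
        g = build_conflict_graph(X)
        assert ("a", "b") in g.edges


class TestEnumerateCombinations:
    def test_edgeless_graph_single_combination(self):
        X = generate_exposures(
            SyntheticSpec(n_counties=500,
                          variable_blocks=tuple((1, 0.0) for _ in range(5)), seed=4)
        )
        g = build_conflict_graph(X)
        assert enumerate_combinations(g) == [tuple(sorted(X.columns))]

    def test_single_edge_three_nodes(self):
        g = build_conflict_graph(
            pd.DataFrame(
                {
                    "A": np.arange(50.0) + np.random.default_rng(0).normal(size=50) * 0.1,
                    "B": np.arange(50.0),
                    "C": np.random.default_rng(1).normal(size=50),
                }
            )
        )
        assert g.edges == (("A", "B"),)
        assert enumerate_combinations(g) == [("A", "C"), ("B", "C")]

    def test_complete_graph_gives_singletons(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=100)
        X = pd.DataFrame({f"v{i}": base + 0.01 * rng.normal(size=100) for i in range(4)})
        g = build_conflict_graph(X)
        assert enumerate_combinations(g) == [("v0",), ("v1",), ("v2",), ("v3",)]

    def test_node_ceiling_enforced(self):
        X = generate_exposures(
            SyntheticSpec(n_counties=100,
                          variable_blocks=tuple((1, 0.0) for _ in range(6)), seed=6)
        )
        with pytest.raises(ValueError, match="ceiling"):
            enumerate_combinations(build_conflict_graph(X), max_nodes=5)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 11))
        nodes = [f"n{i}" for i in range(p)]
        edges = [
            tuple(sorted(e)) for e in itertools.combinations(nodes, 2)
            if rng.random() < 0.3
        ]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        from ecorisk.selection import ConflictGraph

        cg = ConflictGraph(graph=g, threshold=0.6)
        combos = enumerate_combinations(cg)
        assert combos == brute_force_mis(nodes, edges)
        # coverage: every independent set is inside some combination
        for r in range(p + 1):
            for s in itertools.combinations(nodes, r):
                if cg.is_independent(s):
                    assert any(set(s) <= set(c) for c in combos)


class TestInformationCriteria:
    def test_null_fit_adjusted_r2_zero(self):
        assert adjusted_r2(rss=61.0, tss=61.0, n=62, k=1) == pytest.approx(0.0)

    def test_worked_example(self):
        assert adjusted_r2(30.0, 61.0, 62, 5) == pytest.approx(1 - (30 / 57) / (61 / 61), rel=1e-12)
        assert bic(30.0, 62, 5) == pytest.approx(62 * np.log(30 / 62) + 5 * np.log(62), rel=1e-12)

    def test_perfect_fit_limits(self):
        assert adjusted_r2(0.0, 10.0, 20, 3) == pytest.approx(1.0)
        assert np.isfinite(bic(0.0, 20, 3))  # floored, not -inf

    def test_guards(self):
        with pytest.raises(ValueError):
            bic(1.0, 5, 5)
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 0.0, 10, 2)

    def test_subset_count(self):
        assert n_subsets(5) == 32
        assert n_subsets(0) == 1


class TestBestSubset:
    def _data(self, seed, p=3, beta=None, noise=0.5):
        X = generate_exposures(
            SyntheticSpec(n_counties=62,
                          variable_blocks=tuple((1, 0.0) for _ in range(p)),
                          seed=seed)
        )
        forced = generate_exposures(
            SyntheticSpec(n_counties=62, variable_blocks=((2, 0.0),), seed=seed + 999,
                          variable_names=("f1", "f2"))
        )
        y = generate_outcome(
            pd.concat([X, forced], axis=1), beta or {}, noise, seed=seed
        ).y
        return y, X, forced

    def test_planted_single_factor_selected(self):
        hits = 0
        for seed in range(200):
            y, X, forced = self._data(seed, p=3, beta={"x01": 0.6, "f1": 0.3, "f2": 0.3},
                                      noise=0.5)
            m = best_subset(y, ["x01", "x02", "x03"], X, forced)
            hits += m.selected == ("x01",)
        assert hits / 200 >= 0.90

    def test_pure_noise_prefers_forced_only(self):
        empties = 0
        for seed in range(100):
            y, X, forced = self._data(seed + 500, p=3, beta={}, noise=1.0)
            m = best_subset(y, ["x01", "x02", "x03"], X, forced)
            empties += m.selected == ()
        assert empties / 100 > 0.5  # BIC penalty dominates under the null

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        y, X, forced = self._data(seed, p=6, beta={"x02": 0.5}, noise=0.7)
        combo = list(X.columns)
        m = best_subset(y, combo, X, forced)
        (ref_bic, _, _), ref_subset, ref_rss, ref_k = brute_force_best_subset(y, X, combo, forced)
        assert m.selected == ref_subset
        assert m.bic == pytest.approx(ref_bic, rel=1e-10)
        assert m.rss == pytest.approx(ref_rss, rel=1e-8)
        assert m.k == ref_k

    def test_weak_hierarchy_for_latitude_terms(self):
        rng = np.random.default_rng(7)
        lat = pd.Series(rng.uniform(40, 45, size=62), name="latitude")
        X = pd.DataFrame({
            "latitude": standardize(lat),
            "latitude2": standardize(lat**2),
        })
        # strongly quadratic outcome: the squared term alone would win,
        # but hierarchy forces latitude alongside it
        y = X["latitude2"] * 0.8 + pd.Series(rng.normal(size=62) * 0.3)
        m = best_subset(y, ["latitude", "latitude2"], X, None,
                        hierarchy={"latitude2": "latitude"})
        assert "latitude2" not in m.selected or "latitude" in m.selected

    def test_forced_always_included_and_counted(self):
        y, X, forced = self._data(3, p=2, beta={"x01": 0.5}, noise=0.5)
        m = best_subset(y, ["x01", "x02"], X, forced)
        assert m.forced == ("f1", "f2")
        assert m.k == 1 + 2 + len(m.selected)
        assert set(m.coefficients().index) == {"const", "f1", "f2", *m.selected}

    def test_guard_on_combination_size(self):
        X = pd.DataFrame(np.zeros((10, 26)), columns=[f"v{i}" for i in range(26)])
        with pytest.raises(ValueError, match="guard"):
            best_subset(pd.Series(np.zeros(10)), list(X.columns), X, None)

    def test_overlap_between_forced_and_candidates_rejected(self):
        y, X, forced = self._data(11, p=2)
        with pytest.raises(ValueError, match="forced"):
            best_subset(y, ["x01", "f1"], pd.concat([X, forced], axis=1), forced)


class TestPoolAndPrune:
    def test_nested_pair_keeps_lower_bic(self):
        m1 = _make_model(["a"], bic_value=-10.0, adj_r2_value=0.5)
        m2 = _make_model(["a", "b"], bic_value=-8.0, adj_r2_value=0.55)
        res = pool_and_prune([m1, m2])
        assert [m.selected for m in res.ranked] == [("a",)]

    def test_low_r2_pool_is_explicitly_empty(self):
        models = [_make_model(["a"], -5.0, 0.1), _make_model(["b"], -6.0, 0.2)]
        res = pool_and_prune(models)
        assert res.empty
        assert res.ranked == ()
        assert "No model" in res.summary()

    def test_duplicates_removed(self):
        m1 = _make_model(["a"], -10.0, 0.5)
        m2 = _make_model(["a"], -10.0, 0.5)
        res = pool_and_prune([m1, m2])
        assert len(res.ranked) == 1

    def test_comparable_set_strict_delta(self):
        m1 = _make_model(["a"], -10.0, 0.5)
        m2 = _make_model(["b"], -8.0, 0.5)   # delta exactly 2 -> not comparable
        m3 = _make_model(["c"], -8.5, 0.5)   # delta 1.5 -> comparable
        res = pool_and_prune([m1, m2, m3])
        assert [m.selected for m in res.comparable] == [("a",), ("c",)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reference_on_random_pools(self, seed):
        rng = np.random.default_rng(seed)
        vars_ = list("abcde")
        models = []
        for _ in range(int(rng.integers(2, 11))):
            size = int(rng.integers(0, 4))
            sel = tuple(sorted(rng.choice(vars_, size=size, replace=False)))
            models.append(_make_model(sel, float(rng.normal(-5, 3)),
                                      float(rng.uniform(0, 0.8))))
        res = pool_and_prune(models, adj_r2_min=0.3, delta_bic=2.0)
        ref = reference_pool_and_prune(models, 0.3, 2.0)
        if ref is None:
            assert res.empty
        else:
            survivors, comparable = ref
            assert [m.selected for m in res.ranked] == [m.selected for m in survivors]
            assert [m.selected for m in res.comparable] == [m.selected for m in comparable]

    def test_best_always_comparable(self):
        models = [_make_model([v], float(-v_i), 0.5) for v_i, v in enumerate("abc")]
        res = pool_and_prune(models)
        assert res.best in res.comparable


class TestRaceCandidateMode:
    def _frames(self):
        rng = np.random.default_rng(9)
        cand = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        forced = pd.DataFrame(rng.normal(size=(30, 3)),
                              columns=["poverty", "uninsured", "pct_white"])
        return cand, forced

    def test_flag_off_keeps_three_forced(self):
        cand, forced = self._frames()
        c2, f2 = race_candidate_mode(cand, forced, enabled=False)
        assert list(f2.columns) == ["poverty", "uninsured", "pct_white"]
        assert list(c2.columns) == ["a", "b"]

    def test_flag_on_moves_race_to_candidates(self):
        cand, forced = self._frames()
        c2, f2 = race_candidate_mode(cand, forced, enabled=True)
        assert list(f2.columns) == ["poverty", "uninsured"]
        assert "pct_white" in c2.columns

    def test_race_conflicts_exclude_cooccurrence(self):
        rng = np.random.default_rng(10)
        race = rng.normal(size=100)
        cand = pd.DataFrame({"smoking": 0.95 * race + 0.1 * rng.normal(size=100),
                             "other": rng.normal(size=100)})
        forced = pd.DataFrame({"poverty": rng.normal(size=100),
                               "uninsured": rng.normal(size=100),
                               "pct_white": race})
        c2, _ = race_candidate_mode(cand, forced, enabled=True)
        g = build_conflict_graph(c2, r_threshold=0.6)
        for combo in enumerate_combinations(g):
            assert not {"smoking", "pct_white"} <= set(combo)


def test_full_stage_determinism(planted_frame):
    from ecorisk.study import EcologicalStudy

    y, X, forced, planted = planted_frame(2)
    runs = []
    for _ in range(2):
        res = EcologicalStudy(y, X, forced).fit()
        runs.append(
            (
                tuple(res.screening.pooled),
                res.combinations,
                tuple(m.key for m in res.selection.ranked),
                tuple(m.bic for m in res.selection.ranked),
            )
        )
    assert runs[0] == runs[1]
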