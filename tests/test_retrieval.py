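"""Retrieval statistics vs an independent brute-force enumeration oracle."""

import numpy as np
import pytest

from surfshape.retrieval import (ClassHierarchy, DissimilarityMatrix,
                                 mean_average_precision, nn_ft_st,
                                 precision_recall_curve, rank_targets,
                                 top_k_class_count)


# ---------------------------------------------------------------- oracle ---

def oracle_rank(values, q):
    order = sorted(range(len(values)), key=lambda j: (values[q][j], j))
    return [j for j in order if j != q]


def oracle_stats(values, labels, st_window_literal=True):
    """Naive per-query window enumeration of NN/FT/ST/MAP."""
    n = len(labels)
    sizes = {c: labels.count(c) for c in set(labels)}
    nn_l, ft_l, st_l, ap_l = [], [], [], []
    for q in range(n):
        size_c = sizes[labels[q]]
        if size_c < 2:
            continue
        ranked = oracle_rank(values, q)
        rel = [labels[j] == labels[q] for j in ranked]
        n_rel = size_c - 1
        nn_l.append(1.0 if rel[0] else 0.0)
        ft_l.append(sum(rel[:n_rel]) / n_rel)
        w = min(2 * size_c - 1 if st_window_literal else 2 * n_rel, len(ranked))
        st_l.append(sum(rel[:w]) / n_rel)
        precs = []
        hits = 0
        for rank, r in enumerate(rel, start=1):
            if r:
                hits += 1
                precs.append(hits / rank)
        ap_l.append(sum(precs) / len(precs))
    mean = lambda xs: sum(xs) / len(xs)
    return mean(nn_l), mean(ft_l), mean(st_l), mean(ap_l)


def random_instance(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = [f"C{rng.integers(0, max(2, n // 4))}" for _ in range(n)]
    # ensure no singleton-only instance
    while min(labels.count(c) for c in set(labels)) < 2:
        labels[rng.integers(0, n)] = labels[rng.integers(0, n)]
    ids = [f"s{i}" for i in range(n)]
    matrix = DissimilarityMatrix(ids=ids, values=v)
    hierarchy = ClassHierarchy(levels={"protein": dict(zip(ids, labels))})
    return matrix, hierarchy, v.tolist(), labels


# ----------------------------------------------------------------- tests ---

def test_rank_targets_sorting_and_ties():
    m = DissimilarityMatrix(ids=["a", "b", "c"],
                            values=np.array([[0, .2, .1], [.2, 0, .3],
                                             [.1, .3, 0]]))
    assert rank_targets(m, "a") == ["c", "b"]
    tie = DissimilarityMatrix(ids=["a", "b", "c"],
                              values=np.array([[0, .3, .3], [.3, 0, .1],
                                               [.3, .1, 0]]))
    assert tie.values[0][1] == tie.values[0][2]
    assert rank_targets(tie, "a") == ["b", "c"]
    assert len(rank_targets(m, "b")) == 2
    with pytest.raises(KeyError):
        rank_targets(m, "zz")


def test_perfect_block_matrix_gives_ones():
    ids = [f"s{i}" for i in range(8)]
    labels = ["A"] * 4 + ["B"] * 4
    v = np.full((8, 8), 5.0)
    for i in range(8):
        for j in range(8):
            if labels[i] == labels[j]:
                v[i, j] = 1.0
    np.fill_diagonal(v, 0)
    m = DissimilarityMatrix(ids=ids, values=v)
    h = ClassHierarchy(levels={"protein": dict(zip(ids, labels))})
    nn, ft, st = nn_ft_st(m, h, "protein")
    assert (nn, ft, st) == (1.0, 1.0, 1.0)
    assert mean_average_precision(m, h, "protein") == 1.0
    curve = precision_recall_curve(m, h, "protein")
    assert all(p == 1.0 for _, p in curve)


def test_hand_enumerated_windows():
    """4 shapes, classes A={1,2}, B={3,4}; ranking for query 1 is (3,2,4)."""
    ids = ["1", "2", "3", "4"]
    labels = {"1": "A", "2": "A", "3": "B", "4": "B"}
    v = np.zeros((4, 4))
    # distances from query 1: 3 < 2 < 4; others symmetric but irrelevant
    v[0, 2], v[0, 1], v[0, 3] = 0.1, 0.2, 0.3
    v[1, 2], v[1, 3], v[2, 3] = 0.9, 0.8, 0.05
    v = v + v.T
    m = DissimilarityMatrix(ids=ids, values=v)
    h = ClassHierarchy(levels={"protein": labels})
    assert rank_targets(m, "1") == ["3", "2", "4"]
    # for query "1": NN=0 (3 not in A), FT window=1 -> 0, ST window=3 -> 1
    ranked = rank_targets(m, "1")
    rel = [labels[t] == "A" for t in ranked]
    assert rel[0] is False
    assert sum(rel[:1]) == 0
    assert sum(rel[:3]) / 1 == 1.0


def test_ap_hand_example():
    """2 relevant among 4 targets at ranks 1 and 3: AP = (1 + 2/3)/2."""
    ids = ["q", "r1", "x1", "r2", "x2"]
    labels = dict(zip(ids, ["R", "R", "X", "R", "X"]))
    v = np.zeros((5, 5))
    v[0, 1:] = [0.1, 0.2, 0.3, 0.4]     # ranks: r1, x1, r2, x2
    v[1, 2:] = [9, 9, 9]
    v[2, 3:] = [9, 9]
    v[3, 4:] = [9]
    v = v + v.T
    m = DissimilarityMatrix(ids=ids, values=v)
    ranked = rank_targets(m, "q")
    rel = [labels[t] == "R" for t in ranked]
    hits, precs = 0, []
    for rank, r in enumerate(rel, 1):
        if r:
            hits += 1
            precs.append(hits / rank)
    assert np.mean(precs) == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)


def test_worst_case_pr_tail():
    """All relevant ranked last: precision at recall 1 equals n_rel / n."""
    ids = [f"s{i}" for i in range(11)]
    labels = {i: ("R" if i in ("s0", "s9", "s10") else f"X{i}") for i in ids}
    # query s0: both relevant targets at the very end
    v = np.zeros((11, 11))
    v[0, 1:9] = np.arange(1, 9)
    v[0, 9], v[0, 10] = 20.0, 21.0
    v += v.T
    for i in range(1, 11):
        for j in range(i + 1, 11):
            v[i, j] = v[j, i] = 50 + i + j
    m = DissimilarityMatrix(ids=ids, values=v)
    ranked = rank_targets(m, "s0")
    rel = np.array([labels[t] == "R" for t in ranked], float)
    cum = np.cumsum(rel)
    precision = cum / np.arange(1, 11)
    assert precision[np.flatnonzero(rel)[-1]] == pytest.approx(2 / 10)


def test_pr_curve_nonincreasing(tiny_benchmark_matrix=None):
    rng = np.random.default_rng(0)
    m, h, _, _ = random_instance(rng, 20)
    curve = precision_recall_curve(m, h, "protein")
    precisions = [p for _, p in curve]
    assert all(a >= b - 1e-12 for a, b in zip(precisions, precisions[1:]))


def test_statistics_match_bruteforce_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(8, 26))
        m, h, vals, labels = random_instance(rng, n)
        nn, ft, st = nn_ft_st(m, h, "protein")
        o_nn, o_ft, o_st, o_ap = oracle_stats(vals, labels)
        assert nn == pytest.approx(o_nn, abs=1e-12)
        assert ft == pytest.approx(o_ft, abs=1e-12)
        assert st == pytest.approx(o_st, abs=1e-12)
        assert mean_average_precision(m, h, "protein") == pytest.approx(
            o_ap, abs=1e-12)
        assert ft <= st + 1e-12      # window nesting


def test_alternative_st_window_convention():
    rng = np.random.default_rng(3)
    m, h, vals, labels = random_instance(rng, 15)
    _, _, st_alt = nn_ft_st(m, h, "protein", st_window="2(|C|-1)")
    _, _, _, _ = oracle_stats(vals, labels)
    o = oracle_stats(vals, labels, st_window_literal=False)
    assert st_alt == pytest.approx(o[2], abs=1e-12)


def test_monotone_transform_invariance():
    """Statistics depend on ranks only, not on the distance values."""
    rng = np.random.default_rng(9)
    m, h, _, _ = random_instance(rng, 18)
    for f in (np.square, lambda x: np.log1p(x)):
        m2 = DissimilarityMatrix(ids=m.ids, values=f(m.values))
        assert nn_ft_st(m2, h, "protein") == nn_ft_st(m, h, "protein")
        assert mean_average_precision(m2, h, "protein") == pytest.approx(
            mean_average_precision(m, h, "protein"), abs=1e-12)


def test_top_k_class_count_perfect_and_oracle():
    # perfectly separated class of 5 in a set of 12, k=30 -> every count 4
    ids = [f"s{i}" for i in range(12)]
    labels = {i: ("H" if k < 5 else f"X{k}") for k, i in enumerate(ids)}
    v = np.full((12, 12), 9.0)
    v[:5, :5] = 1.0
    np.fill_diagonal(v, 0)
    for i in range(5, 12):
        labels[ids[i]] = "X"        # one distractor class
    m = DissimilarityMatrix(ids=ids, values=v)
    h = ClassHierarchy(levels={"protein": labels})
    counts, mean, sd = top_k_class_count(m, h, "protein", "H", k=30)
    assert counts == [4] * 5 and mean == 4.0 and sd == 0.0
    # k=1 equals the NN indicator per query
    counts1, _, _ = top_k_class_count(m, h, "protein", "H", k=1)
    assert counts1 == [1] * 5
    # random instance vs brute force
    rng = np.random.default_rng(17)
    mr, hr, vals, lab = random_instance(rng, 20)
    cls = max(set(lab), key=lab.count)
    counts, mean, sd = top_k_class_count(mr, hr, "protein", cls, k=7)
    expect = []
    for q in [i for i, c in enumerate(lab) if c == cls]:
        ranked = oracle_rank(vals, q)
        expect.append(sum(lab[j] == cls for j in ranked[:7]))
    assert counts == expect
    assert mean == pytest.approx(np.mean(expect))
    assert sd == pytest.approx(np.std(expect))


def test_singleton_class_excluded():
    ids = ["a", "b", "c"]
    labels = {"a": "A", "b": "A", "c": "B"}
    v = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
    m = DissimilarityMatrix(ids=ids, values=v)
    h = ClassHierarchy(levels={"protein": labels})
    nn, ft, st = nn_ft_st(m, h, "protein")   # only a, b are queries
    assert nn == 1.0


def test_matrix_validation():
    with pytest.raises(ValueError):
        DissimilarityMatrix(ids=["a", "b"],
                            values=np.array([[0, 1.0], [2.0, 0]]))
    with pytest.raises(ValueError):
        DissimilarityMatrix(ids=["a", "b"],
                            values=np.array([[0.5, 1.0], [1.0, 0]]))


def test_hierarchy_nesting_validated():
    with pytest.raises(ValueError, match="spans"):
        ClassHierarchy(levels={
            "protein": {"a": "P1", "b": "P2"},
            "species": {"a": "S1", "b": "S1"},
        })
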