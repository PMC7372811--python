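"""Hypothesis-testing machinery against exact enumeration and library oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as ss
from scipy.spatial.distance import pdist, squareform

from mucosanet import (
    DistanceMatrix,
    anosim,
    bh_two_stage,
    freeman_halton,
    kruskal_wallis,
    mann_whitney_u,
    min_datapoints_gate,
    permanova,
)
from conftest import make_table


def euclidean_dm(points) -> DistanceMatrix:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    ids = [f"s{i}" for i in range(points.shape[0])]
    return DistanceMatrix(ids, squareform(pdist(points)))


# ---------------------------------------------------------------------------
# ANOSIM


def anosim_r_oracle(dm: DistanceMatrix, labels) -> float:
    """Independent ANOSIM R: direct rank bookkeeping over explicit pair lists."""
    labels = np.asarray(labels)
    pairs = list(itertools.combinations(range(dm.n), 2))
    dists = [dm.values[i, j] for i, j in pairs]
    ranks = ss.rankdata(dists)
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


def test_anosim_full_separation_gives_r_one():
    # every between-group distance exceeds every within-group distance
    points = np.array([0.0, 0.1, 0.2, 0.3, 10.0, 10.1, 10.2, 10.3])
    labels = ["a"] * 4 + ["b"] * 4
    res = anosim(euclidean_dm(points), labels, n_perm=999, seed=0)
    assert res.statistic == pytest.approx(1.0)
    assert res.p_value <= 0.05


def test_anosim_matches_exact_enumeration_at_small_n():
    """Sampled permutation p within ±0.02 of the exact p over all 70 labelings."""
    rng = np.random.default_rng(3)
    points = np.concatenate([rng.normal(0, 1, 4), rng.normal(1.5, 1, 4)])
    dm = euclidean_dm(points)
    labels = np.array(["a"] * 4 + ["b"] * 4)
    r_obs = anosim_r_oracle(dm, labels)
    extreme = 0
    total = 0
    for group_a in itertools.combinations(range(8), 4):
        perm = np.array(["b"] * 8)
        perm[list(group_a)] = "a"
        total += 1
        if anosim_r_oracle(dm, perm) >= r_obs - 1e-12:
            extreme += 1
    exact_p = extreme / total
    assert total == 70
    res = anosim(dm, labels, n_perm=999, seed=11)
    assert res.statistic == pytest.approx(r_obs)
    assert abs(res.p_value - exact_p) <= 0.02


def test_anosim_matches_scikit_bio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    points = rng.normal(size=(12, 3))
    dm = euclidean_dm(points)
    labels = ["a"] * 6 + ["b"] * 6
    ours = anosim(dm, labels, n_perm=9, seed=0).statistic
    theirs = skbio.stats.distance.anosim(
        skbio.DistanceMatrix(dm.values, ids=dm.sample_ids), grouping=labels, permutations=0
    )["test statistic"]
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_anosim_null_permutation_distribution_is_centered():
    """Mean permuted R is 0 ± 0.02 (rank sums are fixed under relabeling)."""
    rng = np.random.default_rng(7)
    dm = euclidean_dm(rng.normal(size=(16, 4)))
    labels = np.array(["a"] * 8 + ["b"] * 8)
    perms = [anosim_r_oracle(dm, rng.permutation(labels)) for _ in range(999)]
    assert abs(np.mean(perms)) <= 0.02


def test_anosim_statistic_invariant_to_sample_reordering():
    rng = np.random.default_rng(9)
    points = rng.normal(size=(10, 2))
    labels = np.array(["a"] * 5 + ["b"] * 5)
    dm = euclidean_dm(points)
    order = rng.permutation(10)
    dm2 = DistanceMatrix([dm.sample_ids[i] for i in order], dm.values[np.ix_(order, order)])
    r1 = anosim(dm, labels, n_perm=999, seed=1)
    r2 = anosim(dm2, labels[order], n_perm=999, seed=2)
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
    assert abs(r1.p_value - r2.p_value) <= 0.05


def test_anosim_rejects_undersized_groups():
    dm = euclidean_dm([0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="fewer than 2"):
        anosim(dm, ["a", "a", "b"], n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_equals_anova_f_on_univariate_euclidean_data():
    rng = np.random.default_rng(2)
    x = rng.normal(size=15)
    labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    f_classic = ss.f_oneway(x[:5], x[5:10], x[10:]).statistic
    res = permanova(euclidean_dm(x), labels, n_perm=9, seed=0)
    assert res.statistic == pytest.approx(f_classic, abs=1e-10)


def test_permanova_zero_between_variance_for_duplicated_groups():
    rng = np.random.default_rng(4)
    block = rng.normal(size=(6, 3))
    points = np.vstack([block, block])  # group b duplicates group a exactly
    labels = ["a"] * 6 + ["b"] * 6
    res = permanova(euclidean_dm(points), labels, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value > 0.5


def test_permanova_pseudo_f_increases_with_separation():
    rng = np.random.default_rng(6)
    base = rng.normal(size=(20, 2))
    labels = ["a"] * 10 + ["b"] * 10
    f_values = []
    for shift in (0.5, 1.5, 3.0, 6.0):
        points = base.copy()
        points[10:, 0] += shift
        f_values.append(permanova(euclidean_dm(points), labels, n_perm=9, seed=0).statistic)
    assert all(a < b for a, b in zip(f_values, f_values[1:]))


# ---------------------------------------------------------------------------
# Mann-Whitney / Kruskal-Wallis


def test_mwu_exact_small_sample():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)


def test_mwu_identical_multisets_give_p_one():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.p_value == pytest.approx(1.0)
    assert "exact" in res.notes


def test_mwu_normal_approximation_close_to_enumeration():
    """Asymptotic p vs exact enumeration over all 5|5 partitions of 10 values."""
    values = np.array([0.3, 0.9, 1.4, 2.2, 2.9, 3.6, 4.1, 5.0, 5.8, 6.7])
    worst = 0.0
    for group_a in itertools.combinations(range(10), 5):
        x = values[list(group_a)]
        y = np.delete(values, list(group_a))
        exact = ss.mannwhitneyu(x, y, method="exact").pvalue
        approx = ss.mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
        worst = max(worst, abs(exact - min(approx, 1.0)))
    assert worst < 0.03


def test_mwu_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_kruskal_two_groups_close_to_mwu():
    rng = np.random.default_rng(8)
    x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
    kw = kruskal_wallis([x, y]).p_value
    mwu = mann_whitney_u(x, y).p_value
    assert abs(kw - mwu) < 0.02


def test_kruskal_identical_values():
    res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_three_ordered_groups_hand_formula():
    # fully separated groups of 5: rank sums 15, 40, 65 -> H = 12.5
    groups = [np.arange(1, 6), np.arange(6, 11), np.arange(11, 16)]
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(12.5)


# ---------------------------------------------------------------------------
# Freeman-Halton


def fh_oracle(table: np.ndarray) -> float:
    """Brute-force oracle: explicit iteration over all tables with the margins."""
    table = np.asarray(table, dtype=int)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()

    def prob(t: np.ndarray) -> float:
        logp = (
            sum(math.lgamma(r + 1) for r in rows)
            + sum(math.lgamma(c + 1) for c in cols)
            - math.lgamma(n + 1)
            - sum(math.lgamma(v + 1) for v in t.ravel())
        )
        return math.exp(logp)

    # iterate candidate tables cell-by-cell via cartesian product, filter margins
    r, c = table.shape
    free_cells = [(i, j) for i in range(r - 1) for j in range(c - 1)]
    ranges = [range(min(rows[i], cols[j]) + 1) for i, j in free_cells]
    p_obs = prob(table)
    p = 0.0
    for combo in itertools.product(*ranges):
        t = np.zeros((r, c), dtype=int)
        for (i, j), v in zip(free_cells, combo):
            t[i, j] = v
        t[:-1, -1] = rows[:-1] - t[:-1, :-1].sum(axis=1)
        t[-1, :] = cols - t[:-1, :].sum(axis=0)
        if (t >= 0).all() and t[-1].sum() == rows[-1]:
            pt = prob(t)
            if pt <= p_obs * (1 + 1e-7):
                p += pt
    return min(p, 1.0)


def test_freeman_halton_reduces_to_fisher_2x2():
    res = freeman_halton([[3, 0], [0, 3]])
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    fisher = ss.fisher_exact([[3, 0], [0, 3]])[1]
    assert res.p_value == pytest.approx(fisher, abs=1e-12)


def test_freeman_halton_cohort_contingency_matches_oracle():
    # cause-of-infertility 4x2 breakdown: 4 pregnant vs 30 non-pregnant patients
    table = np.array([[2, 11], [0, 3], [1, 6], [1, 8]])
    res = freeman_halton(table)
    assert res.p_value == pytest.approx(fh_oracle(table), abs=1e-12)


@pytest.mark.parametrize("table", [
    [[1, 2, 3], [3, 2, 1]],
    [[4, 0, 1], [0, 4, 2]],
    [[2, 2], [2, 2]],
    [[5, 1], [1, 5]],
    [[0, 3, 1], [2, 0, 4]],
])
def test_freeman_halton_matches_bruteforce_oracle(table):
    assert freeman_halton(table).p_value == pytest.approx(fh_oracle(np.asarray(table)), abs=1e-12)


def test_freeman_halton_zero_margin_row_is_dropped():
    res = freeman_halton([[3, 2], [0, 0], [2, 3]])
    full = freeman_halton([[3, 2], [2, 3]])
    assert res.p_value == pytest.approx(full.p_value, abs=1e-12)


def test_freeman_halton_degenerate_after_dropping():
    assert freeman_halton([[3, 2], [0, 0]]).p_value == 1.0


def test_freeman_halton_budget_guard():
    big = np.full((2, 2), 100)
    with pytest.raises(ValueError, match="Monte-Carlo"):
        freeman_halton(big)


# ---------------------------------------------------------------------------
# two-stage BH FDR


def two_stage_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Step-by-step two-stage BH: stage 1 at q, stage 2 at q*m/m0."""
    p = np.asarray(p, dtype=float)
    m = p.size

    def step_up(level: float) -> np.ndarray:
        order = np.argsort(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= level * i / m:
                k = i
        out = np.zeros(m, dtype=bool)
        out[order[:k]] = True
        return out

    r1 = step_up(q).sum()
    if r1 == 0 or r1 == m:
        return step_up(q)
    return step_up(q * m / (m - r1))


def test_bh_two_stage_all_small_all_rejected():
    rejected, _ = bh_two_stage([0.001] * 10, q=0.10)
    assert rejected.all()


def test_bh_two_stage_all_large_none_rejected():
    rejected, _ = bh_two_stage([0.9] * 10, q=0.10)
    assert not rejected.any()


def test_bh_two_stage_fixed_list_matches_definitional_oracle():
    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
    rejected, adjusted = bh_two_stage(p, q=0.10)
    assert (rejected == two_stage_oracle(p, 0.10)).all()
    assert (adjusted <= 0.10).sum() == rejected.sum()


def test_bh_two_stage_matches_statsmodels():
    multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
    rng = np.random.default_rng(1)
    for _ in range(100):
        p = np.clip(rng.beta(0.3, 1.5, rng.integers(1, 25)), 1e-12, 1.0)
        rejected, adjusted = bh_two_stage(p, q=0.10)
        sm_rej, sm_adj = multipletests(p, alpha=0.10, method="fdr_tsbh")[:2]
        assert (rejected == sm_rej).all()
        assert np.allclose(adjusted, sm_adj)


def test_bh_two_stage_dominates_one_stage_bh():
    rng = np.random.default_rng(2)
    for _ in range(200):
        p = np.clip(rng.uniform(size=rng.integers(1, 20)), 1e-12, 1.0)
        rejected, _ = bh_two_stage(p, q=0.10)
        # classic one-stage BH at q
        m = p.size
        order = np.argsort(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= 0.10 * i / m:
                k = i
        bh = np.zeros(m, dtype=bool)
        bh[order[:k]] = True
        assert (rejected | ~bh).all()  # rejected ⊇ bh


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0,
                              allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=25))
    def test_bh_two_stage_dominance_property(pvals):
        """Two-stage rejections always contain the one-stage BH rejections."""
        p = np.asarray(pvals)
        rejected, adjusted = bh_two_stage(p, q=0.10)
        bh = _one_stage_bh(p, 0.10)
        assert (rejected | ~bh).all()
        assert np.all((adjusted > 0) & (adjusted <= 1))

    def _one_stage_bh(p, q):
        m = p.size
        order = np.argsort(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= q * i / m:
                k = i
        out = np.zeros(m, dtype=bool)
        out[order[:k]] = True
        return out
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_bh_two_stage_monotone_rejections():
    rng = np.random.default_rng(3)
    p = np.clip(rng.uniform(size=15), 1e-12, 1.0)
    rejected, _ = bh_two_stage(p, q=0.10)
    if rejected.any() and (~rejected).any():
        assert p[rejected].max() <= p[~rejected].min()


# ---------------------------------------------------------------------------
# minimum data-points gate


def test_min_datapoints_gate_boundaries():
    values = np.zeros((10, 3), dtype=int)
    values[:5, 0] = 1   # 5 nonzero samples -> kept at k=5
    values[:4, 1] = 1   # 4 nonzero samples -> dropped
    values[0, 2] = 1
    table = make_table(values)
    assert min_datapoints_gate(table, k=5) == ["sp1"]
    assert min_datapoints_gate(table, k=0) == ["sp1", "sp2", "sp3"]
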