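"""Significance machinery: ANOSIM, PERMANOVA, rank tests, the exact
Fisher–Freeman–Halton r×c test, and the two-stage Benjamini-Hochberg FDR.

Permutation p-values use the (b+1)/(m+1) convention, where b counts permuted
statistics at least as extreme as the observed one over m label shuffles;
this never returns 0 and is bounded below by 1/(m+1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diversity import DistanceMatrix
from .io import AbundanceTable

#: global significance threshold, applied inclusively (p ≤ alpha)
ALPHA = 0.05
DEFAULT_FDR_Q = 0.10
DEFAULT_MIN_DATAPOINTS = 5


@dataclass
class TestResult:
    """Uniform return contract for every statistical test in the pipeline."""

    statistic: float
    p_value: float
    n_permutations: int | None = None
    method: str = ""
    notes: str = ""

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p_value <= alpha


def _align_labels(dm: DistanceMatrix, labels) -> np.ndarray:
    """Labels may be a sequence in matrix order or a mapping/Series by sample id."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(labels, dict):
        missing = [s for s in dm.sample_ids if s not in labels]
        if missing:
            raise ValueError(f"labels do not cover samples: {missing}")
        return np.asarray([labels[s] for s in dm.sample_ids])
    arr = np.asarray(labels)
    if arr.shape[0] != dm.n:
        raise ValueError("labels length does not match distance matrix")
    return arr


def _check_groups(labels: np.ndarray) -> list:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2].tolist()
    if small:
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    return uniq.tolist()


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int | None = None) -> TestResult:
    """Analysis of Similarity on a distance matrix.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 distances ranked with ties averaged; R is 0-centered under
    the null and 1 at complete separation. p is estimated by shuffling the
    group labels.
    """
    labels = _align_labels(dm, labels)
    _check_groups(labels)
    n = dm.n
    iu, ju = np.triu_indices(n, 1)
    ranks = stats.rankdata(dm.values[iu, ju])
    denom = (n * (n - 1) / 2) / 2

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return TestResult(r_obs, p, n_perm, "ANOSIM", notes=f"seed={seed}")


def _permanova_f(d2: np.ndarray, labels: np.ndarray, iu, ju) -> float:
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    a = len(uniq)
    ss_total = d2.sum() / n
    ss_within = 0.0
    for g, n_g in zip(uniq, counts):
        mask = (labels[iu] == g) & (labels[ju] == g)
        ss_within += d2[mask].sum() / n_g
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int | None = None) -> TestResult:
    """Permutational multivariate analysis of variance (pseudo-F).

    Sums of squares are computed directly from squared distances
    (SS_total = Σ d²ᵢⱼ / n; SS_within from within-group pairs); on univariate
    Euclidean data the pseudo-F reduces to the classical one-way ANOVA F.
    """
    labels = _align_labels(dm, labels)
    _check_groups(labels)
    n = dm.n
    iu, ju = np.triu_indices(n, 1)
    d2 = dm.values[iu, ju] ** 2
    f_obs = _permanova_f(d2, labels, iu, ju)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(labels), iu, ju) >= f_obs:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return TestResult(f_obs, p, n_perm, "PERMANOVA", notes=f"seed={seed}")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact enumeration when the pooled sample has ≤ 12 values (an exhaustive
    permutation path covers ties); otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    n = pooled.size
    if n <= 12:
        if has_ties:
            # exhaustive permutation null: exact even with ties
            method = stats.PermutationMethod(n_resamples=math.comb(n, x.size) + 1)
            label = "exact-permutation"
        else:
            method = "exact"
            label = "exact"
    else:
        method = "asymptotic"
        label = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    notes = label + (", ties" if has_ties else "")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), None,
                      "Mann-Whitney U", notes=notes)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from the χ² approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, None, "Kruskal-Wallis", notes="all values identical")
    res = stats.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), None, "Kruskal-Wallis")


# ---------------------------------------------------------------------------
# Fisher's exact test with the Freeman-Halton extension to r×c tables


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - gammaln(table + 1).sum()


def _compositions(total: int, bounds: np.ndarray):
    """All ways to write ``total`` as an ordered sum bounded cell-wise."""
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    upper = min(total, bounds[0])
    lower = max(0, total - int(bounds[1:].sum()))
    for v in range(lower, upper + 1):
        for rest in _compositions(total - v, bounds[1:]):
            yield (v,) + rest


def freeman_halton(table, max_n: int = 200, max_cells: int = 12) -> TestResult:
    """Exact p for independence in an r×c contingency table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of tables no more probable than the observed
    one (factor 1+1e-7 guards float comparison). Rows/columns with zero
    margins are dropped first; a table left with a single row or column is
    independent by construction (p = 1).
    """
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need an r×c table with r, c ≥ 2")
    if (T < 0).any():
        raise ValueError("counts must be non-negative")
    T = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
    if T.shape[0] < 2 or T.shape[1] < 2:
        return TestResult(1.0, 1.0, None, "Freeman-Halton",
                          notes="degenerate margins; p = 1")
    N = int(T.sum())
    if N > max_n or T.size > max_cells:
        raise ValueError(
            f"table too large for exact enumeration (N={N}, cells={T.size}); "
            "use the Monte-Carlo fallback flag (not yet implemented)"
        )
    rows, cols = T.sum(axis=1), T.sum(axis=0)
    log_margin_const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(N + 1)
    logp_obs = _log_table_prob(T, log_margin_const)
    threshold = logp_obs + math.log1p(1e-7)

    p = 0.0
    total_prob = 0.0

    def recurse(row_idx: int, remaining_cols: np.ndarray, acc_log: float) -> None:
        nonlocal p, total_prob
        if row_idx == len(rows) - 1:
            logp = log_margin_const + acc_log - gammaln(remaining_cols + 1).sum()
            prob = math.exp(logp)
            total_prob += prob
            if logp <= threshold:
                p += prob
            return
        for comp in _compositions(int(rows[row_idx]), remaining_cols):
            comp_arr = np.asarray(comp)
            recurse(row_idx + 1, remaining_cols - comp_arr,
                    acc_log - gammaln(comp_arr + 1).sum())

    recurse(0, cols.copy(), 0.0)
    if abs(total_prob - 1.0) > 1e-9:
        raise RuntimeError(f"enumeration incomplete: total probability {total_prob}")
    return TestResult(math.exp(logp_obs), min(p, 1.0), None, "Freeman-Halton",
                      notes="statistic = conditional probability of observed table")


# ---------------------------------------------------------------------------
# multiple testing


def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = level * (np.arange(1, m + 1) / m)
    below = p[order] <= thresholds
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0]) + 1
        rejected[order[:k]] = True
    return rejected


def bh_two_stage(p_values, q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage (adaptive) Benjamini-Hochberg step-up at FDR level ``q``.

    Stage 1 is the classic BH step-up at q; its rejection count r₁ estimates
    the number of true nulls (m₀ = m − r₁) and, when 0 < r₁ < m, stage 2
    reruns the step-up at q·m/m₀. Returns (rejected mask, adjusted p-values)
    in input order; a rejection is ``adjusted ≤ q``. Because stage 1 *is* the
    one-stage BH and stage 2 can only widen it, the rejection set dominates
    classic BH at the same q on every input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    stage1 = _bh_reject(p, q)
    r1 = int(stage1.sum())
    # BH-adjusted p-values (monotone step-up adjustment)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    bh_adjusted = np.empty(m)
    bh_adjusted[order] = np.minimum(ranked, 1.0)
    if r1 == 0 or r1 == m:
        return stage1, bh_adjusted
    m0 = m - r1
    rejected = _bh_reject(p, q * m / m0)
    adjusted = np.minimum(bh_adjusted * m0 / m, 1.0)
    return rejected, adjusted


def min_datapoints_gate(table: AbundanceTable, k: int = DEFAULT_MIN_DATAPOINTS) -> list[str]:
    """Species represented by at least ``k`` nonzero observations."""
    nonzero = (table.data > 0).sum(axis=0)
    return nonzero[nonzero >= k].index.tolist()
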