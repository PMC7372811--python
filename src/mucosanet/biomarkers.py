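"""Supervised biomarker discovery.

PLS-DA is fit by NIPALS against a single centered 0/1 class column; variable
importance in projection (VIP) scores summarize each species' contribution to
the discriminating components, normalized so that the squared VIPs sum to the
feature count. Reported VIPs are leave-one-out averages: the model is refit n
times, once per held-out sample, and the per-species mean and SD of the n VIP
vectors are returned — an aggregate far less sensitive to single influential
samples than one global fit.

The LEfSe-style effect size screens species with a Mann-Whitney U test,
controls the survivors with a two-stage Benjamini-Hochberg FDR and a minimum
data-points gate, and scores what remains with a linear-discriminant-derived
magnitude on per-million-scaled relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import AbundanceTable
from .preprocess import NormalizedTable
from .stats import ALPHA, DEFAULT_FDR_Q, DEFAULT_MIN_DATAPOINTS, bh_two_stage, mann_whitney_u, min_datapoints_gate

logger = logging.getLogger(__name__)

NIPALS_MAX_ITER = 500
NIPALS_TOL = 1e-10


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model (NIPALS, single response column)."""

    weights: np.ndarray       # p × A, unit-norm columns
    loadings: np.ndarray      # p × A
    scores: np.ndarray        # n × A, mutually orthogonal
    y_loadings: np.ndarray    # A
    ssy: np.ndarray           # y-variance explained per component
    feature_names: list[str]
    classes: list
    n_components: int


def _as_matrix(X) -> tuple[np.ndarray, list[str], list]:
    if isinstance(X, NormalizedTable):
        return X.values.astype(float), X.species_ids, list(X.data.index)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns), list(X.index)
    X = np.asarray(X, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])], list(range(X.shape[0]))


def _encode_labels(y) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly 2 classes, got {classes}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError(f"each class needs at least 2 samples, got {dict(zip(classes, counts))}")
    return (y == classes[1]).astype(float), classes


def plsda_fit(X, y, n_components: int = 2) -> PLSDAModel:
    """Fit PLS-DA by NIPALS with successive deflation.

    The class vector is encoded as one centered {0, 1} column. Components
    whose weight vector collapses to zero (response fully explained) end the
    extraction early.
    """
    X, names, _ = _as_matrix(X)
    y_bin, classes = _encode_labels(y)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    Xc = X - X.mean(axis=0)
    yc = y_bin - y_bin.mean()

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    C = np.zeros(n_components)
    ssy = np.zeros(n_components)
    used = 0
    for a in range(n_components):
        u = yc.copy()
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-300:
                break
            w_new /= norm
            t = Xc @ w_new
            c = (t @ yc) / (t @ t)
            u_new = yc * c
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            raise RuntimeError(f"NIPALS did not converge after {NIPALS_MAX_ITER} iterations")
        if np.linalg.norm(w) == 0:
            logger.warning("component %d collapsed; stopping at %d component(s)", a + 1, used)
            break
        t = Xc @ w
        tt = t @ t
        if tt < 1e-300:
            break
        c = (t @ yc) / tt
        p_load = Xc.T @ t / tt
        Xc = Xc - np.outer(t, p_load)
        yc = yc - c * t
        W[:, a], P[:, a], T[:, a], C[a] = w, p_load, t, c
        ssy[a] = c**2 * tt
        used += 1
    if used == 0:
        raise RuntimeError("no PLS component could be extracted (X carries no signal)")
    return PLSDAModel(W[:, :used], P[:, :used], T[:, :used], C[:used], ssy[:used],
                      names, classes, used)


def vip_scores(model: PLSDAModel) -> pd.Series:
    """VIPⱼ = √( p · Σₐ SSYₐ wₐⱼ² / Σₐ SSYₐ ); Σⱼ VIPⱼ² = p by construction."""
    p = len(model.feature_names)
    ssy_total = model.ssy.sum()
    if ssy_total == 0:
        vip = np.ones(p)
    else:
        contrib = (model.weights**2) @ model.ssy
        vip = np.sqrt(p * contrib / ssy_total)
    return pd.Series(vip, index=model.feature_names, name="vip")


def loo_mean_vip(X, y, n_components: int = 2) -> pd.DataFrame:
    """Leave-one-out averaged VIP scores.

    Refits the PLS-DA model n times, each omitting one sample, and returns
    the per-species mean and SD of the resulting VIP vectors. A fold whose
    training set loses a class entirely is skipped with a warning.
    """
    Xm, names, _ = _as_matrix(X)
    y = np.asarray(y)
    n = Xm.shape[0]
    if n < 4:
        raise ValueError("leave-one-out averaging requires at least 4 samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 samples so every fold keeps both classes")
    vips = []
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            logger.warning("fold %d lost a class; skipped", i)
            skipped += 1
            continue
        model = plsda_fit(Xm[mask], y[mask], n_components=n_components)
        vips.append(vip_scores(model).to_numpy())
    if skipped:
        logger.warning("%d of %d folds skipped", skipped, n)
    stack = np.vstack(vips)
    return pd.DataFrame(
        {"mean_vip": stack.mean(axis=0), "vip_sd": stack.std(axis=0, ddof=0)},
        index=pd.Index(names, name="species"),
    )


def fold_ratio(table: AbundanceTable, groups) -> pd.DataFrame:
    """Fold ratio of group-mean relative abundances per species.

    FR = higher mean / lower mean ≥ 1. A zero lower mean is floored at half
    the smallest nonzero relative abundance in the table (flagged); species
    with both means zero are excluded (flagged in the log).
    """
    if table.kind != "relative":
        raise ValueError("fold_ratio requires a relative-abundance table")
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    labels = groups.loc[table.sample_ids] if set(table.sample_ids) <= set(groups.index) \
        else pd.Series(np.asarray(groups), index=table.sample_ids)
    uniq = sorted(labels.unique().tolist())
    if len(uniq) != 2:
        raise ValueError(f"fold_ratio requires exactly 2 groups, got {uniq}")
    means = table.data.groupby(labels).mean()
    nonzero = table.values[table.values > 0]
    eps = nonzero.min() / 2 if nonzero.size else np.nan
    rows = []
    for sp in table.species_ids:
        m = {g: means.loc[g, sp] for g in uniq}
        hi = max(uniq, key=lambda g: m[g])
        lo = min(uniq, key=lambda g: m[g])
        if m[hi] == 0:
            logger.info("species %s has zero mean in both groups; excluded from FR report", sp)
            continue
        floored = m[lo] == 0
        fr = m[hi] / (m[lo] if not floored else eps)
        rows.append({"species": sp, "fold_ratio": fr, "high_cohort": hi,
                     "low_cohort": lo, "floored": floored})
    return pd.DataFrame(rows).set_index("species") if rows else pd.DataFrame(
        columns=["fold_ratio", "high_cohort", "low_cohort", "floored"])


def _mwu_per_species(table: AbundanceTable, labels: pd.Series, uniq: list) -> pd.Series:
    pvals = {}
    g1 = labels == uniq[0]
    for sp in table.species_ids:
        col = table.data[sp].to_numpy(dtype=float)
        pvals[sp] = mann_whitney_u(col[g1.to_numpy()], col[~g1.to_numpy()]).p_value
    return pd.Series(pvals, name="mwu_p")


def lefse_like(
    table: AbundanceTable,
    groups,
    alpha: float = ALPHA,
    q: float = DEFAULT_FDR_Q,
    k: int = DEFAULT_MIN_DATAPOINTS,
) -> pd.DataFrame:
    """LEfSe-style biomarker report.

    Gates: (1) per-species Mann-Whitney U p ≤ alpha; (2) two-stage BH FDR at
    q on the gated p-values; (3) at least ``k`` nonzero observations.
    Survivors are scored on relative abundances scaled to 10⁶ per sample:
    the effect size is log₁₀ of the absolute mean of the raw class-mean
    difference and the first-axis LDA-projected difference (floored at 1, so
    effect sizes are non-negative).
    """
    if table.kind != "relative":
        raise ValueError("lefse_like requires a relative-abundance table")
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    labels = groups.loc[table.sample_ids] if set(table.sample_ids) <= set(groups.index) \
        else pd.Series(np.asarray(groups), index=table.sample_ids)
    uniq = sorted(labels.unique().tolist())
    if len(uniq) != 2:
        raise ValueError(f"lefse_like requires exactly 2 groups, got {uniq}")
    columns = ["effect_size", "enriched_cohort", "mwu_p", "mwu_p_adjusted"]

    pvals = _mwu_per_species(table, labels, uniq)
    gate1 = pvals[pvals <= alpha]
    if gate1.empty:
        return pd.DataFrame(columns=columns)
    rejected, adjusted = bh_two_stage(gate1.to_numpy(), q=q)
    gate2 = gate1.index[rejected].tolist()
    adj = pd.Series(adjusted, index=gate1.index)
    gate3 = set(min_datapoints_gate(table, k=k))
    survivors = [sp for sp in gate2 if sp in gate3]
    if not survivors:
        return pd.DataFrame(columns=columns)

    scaled = table.data[survivors].to_numpy(dtype=float) * 1e6
    mask1 = (labels == uniq[0]).to_numpy()
    raw_diff = scaled[mask1].mean(axis=0) - scaled[~mask1].mean(axis=0)
    try:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(scaled, labels.to_numpy())
        w = lda.coef_[0]
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate LDA axis")
        w = w / norm
        proj = scaled @ w
        delta = proj[mask1].mean() - proj[~mask1].mean()
        lda_diff = np.abs(w * delta)
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("LDA scoring failed (%s); using raw differences only", exc)
        lda_diff = np.abs(raw_diff)
    effect = np.log10(np.maximum(1.0, (np.abs(raw_diff) + lda_diff) / 2))
    enriched = np.where(raw_diff > 0, uniq[0], uniq[1])
    report = pd.DataFrame(
        {
            "effect_size": effect,
            "enriched_cohort": enriched,
            "mwu_p": pvals[survivors].to_numpy(),
            "mwu_p_adjusted": adj[survivors].to_numpy(),
        },
        index=pd.Index(survivors, name="species"),
    )
    return report.sort_values("effect_size", ascending=False)


def build_vip_report(
    rel_table: AbundanceTable,
    norm_table: NormalizedTable,
    groups,
    n_components: int = 2,
    alpha: float = ALPHA,
    q: float = DEFAULT_FDR_Q,
) -> pd.DataFrame:
    """Combined VIP report: LOO-mean VIP, fold ratios, MWU significance.

    Species are those of the normalized table (already prevalence-filtered by
    the pipeline); sorted by mean VIP, descending.
    """
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    labels = groups.loc[norm_table.sample_ids] if set(norm_table.sample_ids) <= set(groups.index) \
        else pd.Series(np.asarray(groups), index=norm_table.sample_ids)
    uniq = sorted(labels.unique().tolist())
    vip = loo_mean_vip(norm_table, labels.to_numpy(), n_components=n_components)
    rel = rel_table.select_species(norm_table.species_ids)
    fr = fold_ratio(rel, labels)
    pvals = _mwu_per_species(rel, labels, uniq)
    _, adjusted = bh_two_stage(pvals.to_numpy(), q=q)
    report = vip.join(fr, how="left")
    report["mwu_p"] = pvals
    report["mwu_p_adjusted"] = adjusted
    report["significant"] = report["mwu_p"] <= alpha
    return report.sort_values("mean_vip", ascending=False)
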