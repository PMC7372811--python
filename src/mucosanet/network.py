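"""Co-occurrence network analysis.

Nodes are species (already prevalence-filtered and rank-normalized upstream);
edges are species pairs whose Pearson correlation is significant at the edge
alpha, signed by correlation direction and binned into eight significance
categories (p-value decades from just under 5·10⁻² down to ≤10⁻⁸) that drive
edge thickness in Gephi-style renderings. Communities come from the Blondel
(Louvain) algorithm on |r| edge weights with restart randomization; keystone
species are ranked by betweenness centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedTable
from .stats import ALPHA, TestResult

logger = logging.getLogger(__name__)

#: upper bounds of the eight significance categories (category 1 is the least
#: significant edge class; ≤ 1e-8 is category 8)
CATEGORY_BINS = (5e-2, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def significance_category(p: float, bins=CATEGORY_BINS) -> int:
    """Edge-thickness category 1–8 from the edge p-value (8 = most significant)."""
    if p > bins[0]:
        raise ValueError(f"p={p} is not significant at the edge threshold {bins[0]}")
    for k in range(1, len(bins)):
        if p > bins[k]:
            return k
    return len(bins)


@dataclass
class CommunityResult:
    """Best-of-restarts Louvain partition with its recomputable modularity."""

    partition: dict
    modularity: float
    n_restarts: int
    best_seed: int | None


def pearson_matrix(norm_table: NormalizedTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Pearson r with two-sided p from the t distribution (n−2 df)."""
    n = len(norm_table.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    X = norm_table.values
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    np.fill_diagonal(p, 0.0)
    ids = norm_table.species_ids
    return (pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def build_cooccurrence(
    norm_table: NormalizedTable,
    alpha: float = ALPHA,
    prevalence: pd.Series | None = None,
    mean_abundance: pd.Series | None = None,
) -> nx.Graph:
    """Build the undirected co-occurrence network.

    Edge iff the pairwise Pearson p ≤ ``alpha``; edge attributes r, p, sign,
    category (1–8), weight = |r|. Optional per-species ``prevalence`` and
    ``mean_abundance`` become node attributes for export. Zero-variance
    species are dropped with a warning.
    """
    variances = norm_table.values.std(axis=0)
    keep = [s for s, v in zip(norm_table.species_ids, variances) if v > 0]
    dropped = [s for s in norm_table.species_ids if s not in set(keep)]
    if dropped:
        logger.warning("dropping zero-variance species: %s", dropped)
    if len(keep) < 2:
        raise ValueError("need at least 2 variable species to build a network")
    sub = NormalizedTable(norm_table.data[keep], dropped=dropped)
    r, p = pearson_matrix(sub)

    net = nx.Graph()
    for sp in keep:
        attrs = {}
        if prevalence is not None and sp in prevalence.index:
            attrs["prevalence"] = float(prevalence[sp])
        if mean_abundance is not None and sp in mean_abundance.index:
            attrs["mean_norm_abundance"] = float(mean_abundance[sp])
        net.add_node(sp, **attrs)
    for i, u in enumerate(keep):
        for v in keep[i + 1:]:
            pv = float(p.loc[u, v])
            if pv <= alpha:
                rv = float(r.loc[u, v])
                net.add_edge(u, v, r=rv, p=pv,
                             sign="positive" if rv >= 0 else "negative",
                             # edges admitted by a loose alpha above the top
                             # bin fall in the least-significant category
                             category=significance_category(min(pv, CATEGORY_BINS[0])),
                             weight=abs(rv))
    return net


def louvain_communities(
    net: nx.Graph,
    resolution: float = 1.0,
    n_restarts: int = 10,
    seed: int | None = None,
) -> CommunityResult:
    """Blondel/Louvain community detection on |r| edge weights.

    Runs ``n_restarts`` randomized restarts (randomized node visiting order)
    and returns the partition with the highest modularity Q at the given
    resolution; Q is recomputed from the returned partition.
    """
    if net.number_of_edges() == 0:
        partition = {node: i for i, node in enumerate(net.nodes)}
        return CommunityResult(partition, 0.0, n_restarts, None)
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best_q, best_partition, best_seed = -np.inf, None, None
    for s in restart_seeds:
        comms = nx.community.louvain_communities(
            net, weight="weight", resolution=resolution, seed=int(s)
        )
        q = nx.community.modularity(net, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_partition, best_seed = q, comms, int(s)
    partition = {}
    for cid, members in enumerate(sorted(best_partition, key=lambda c: sorted(c)[0])):
        for node in members:
            partition[node] = cid
    nx.set_node_attributes(net, partition, "community")
    return CommunityResult(partition, float(best_q), n_restarts, best_seed)


def recompute_modularity(net: nx.Graph, partition: dict, resolution: float = 1.0) -> float:
    """Modularity of an explicit partition, from scratch (consistency check)."""
    groups: dict[int, set] = {}
    for node, cid in partition.items():
        groups.setdefault(cid, set()).add(node)
    return float(nx.community.modularity(net, groups.values(), weight="weight",
                                         resolution=resolution))


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree (incident edge count) and unnormalized betweenness per node.

    Betweenness uses unweighted shortest paths (Brandes accumulation); both
    measures are stored as node attributes and returned as a frame.
    """
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=False)
    nx.set_node_attributes(net, degree, "degree")
    nx.set_node_attributes(net, betweenness, "betweenness")
    return pd.DataFrame(
        {"degree": pd.Series(degree), "betweenness": pd.Series(betweenness)}
    ).rename_axis("species")


def keystone_species(net: nx.Graph, top_k: int = 3) -> list[tuple[str, float]]:
    """Top-k nodes by betweenness (ties: degree, then species id).

    If every node has zero betweenness there is no shortest-path structure to
    rank, and the list is empty (flagged in the log).
    """
    frame = centralities(net)
    if frame.empty or frame["betweenness"].max() == 0:
        logger.warning("no node lies on any shortest path; no keystone to report")
        return []
    ranked = frame.reset_index().sort_values(
        by=["betweenness", "degree", "species"], ascending=[False, False, True]
    )
    return [(row.species, float(row.betweenness)) for row in ranked.head(top_k).itertuples()]


def community_separation_test(
    net: nx.Graph,
    partition: dict,
    species_set,
    n_perm: int = 9999,
    seed: int | None = None,
) -> TestResult:
    """Permutation test of topological clustering of a species set.

    Statistic: the maximum number of set members sharing one community. Null:
    random node subsets of the same size. This is a defined stand-in for an
    unspecified upstream procedure and is off by default in reports.
    """
    nodes = list(net.nodes)
    species_set = list(species_set)
    missing = [s for s in species_set if s not in partition]
    if missing:
        raise ValueError(f"species not in the network/partition: {missing}")
    if len(species_set) > len(nodes):
        raise ValueError("species set larger than the node count")
    comm = np.asarray([partition[s] for s in nodes])
    n_comm = comm.max() + 1
    idx = {s: i for i, s in enumerate(nodes)}
    observed = int(np.bincount(comm[[idx[s] for s in species_set]], minlength=n_comm).max())
    rng = np.random.default_rng(seed)
    k = len(species_set)
    b = 0
    for _ in range(n_perm):
        sample = rng.choice(len(nodes), size=k, replace=False)
        if np.bincount(comm[sample], minlength=n_comm).max() >= observed:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return TestResult(float(observed), p, n_perm, "community-separation permutation",
                      notes=f"seed={seed}; stand-in test")
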