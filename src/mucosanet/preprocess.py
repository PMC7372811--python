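"""Matrix conditioning for downstream multivariate analysis.

The stages implemented here mirror the standard conditioning of a 16S
OTU/species table before diversity, ordination and correlation work:

* removal of low-populated species (sequencing noise),
* conversion to relative abundances (uneven library sizes),
* a prevalence filter (species must appear in a minimum fraction of samples,
  independently of abundance),
* pooling of rare taxa into an "Other" category for compositional summaries,
* aggregation to higher taxonomic ranks,
* Good's coverage (sampling completeness),
* a normalize-then-standardize transform that maps every species column to a
  Gaussian-shaped variable with mean 0 and variance 1, so variables with very
  different dynamic ranges become comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, TaxonomyMap, RANKS

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 5
DEFAULT_PREVALENCE = 0.20
DEFAULT_OTHER_CUTOFF = 0.005


@dataclass
class NormalizedTable:
    """Rank-normalized, standardized species matrix.

    Each retained column has mean 0 (±1e-8) and variance 1 (±1e-6);
    zero-variance source columns are excluded and listed in ``dropped``.
    """

    data: pd.DataFrame
    method: str = "van_der_waerden+standardize"
    dropped: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def min_count_filter(table: AbundanceTable, min_reads: int = DEFAULT_MIN_READS) -> AbundanceTable:
    """Drop species whose total count across all samples is ≤ ``min_reads``."""
    if table.kind != "counts":
        raise ValueError("min_count_filter requires a counts table")
    totals = table.data.sum(axis=0)
    keep = totals[totals > min_reads].index.tolist()
    removed = [s for s in table.species_ids if s not in set(keep)]
    if removed:
        logger.info("min_count_filter removed %d species: %s", len(removed), removed)
    if not keep:
        raise ValueError("min_count_filter removed every species")
    return table.select_species(keep)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total."""
    values = table.data.to_numpy(dtype=float)
    rowsums = values.sum(axis=1)
    zero = np.asarray(table.sample_ids)[rowsums == 0].tolist()
    if zero:
        raise ValueError(f"cannot compute relative abundances for zero-sum sample(s): {zero}")
    rel = values / rowsums[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        kind="relative",
    )


def prevalence(table: AbundanceTable) -> pd.Series:
    """Fraction of samples in which each species is present (value > 0)."""
    return (table.data > 0).mean(axis=0)


def prevalence_filter(table: AbundanceTable, threshold: float = DEFAULT_PREVALENCE) -> AbundanceTable:
    """Keep species present in at least ``threshold`` of samples (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    prev = prevalence(table)
    keep = prev[prev >= threshold].index.tolist()
    removed = len(table.species_ids) - len(keep)
    if removed:
        logger.info("prevalence_filter removed %d species below %.0f%% prevalence",
                    removed, 100 * threshold)
    if not keep:
        logger.warning("prevalence_filter removed every species")
    return table.select_species(keep)


def aggregate_taxonomy(table: AbundanceTable, taxmap: TaxonomyMap, level: str) -> AbundanceTable:
    """Sum abundances within each taxon label at the requested rank."""
    labels = taxmap.labels_at(level, table.species_ids)
    grouped = table.data.T.groupby(labels.to_numpy()).sum().T
    grouped.columns = grouped.columns.astype(str)
    return AbundanceTable(grouped, kind=table.kind)


def collapse_other(
    table: AbundanceTable,
    taxmap: TaxonomyMap,
    level: str,
    cutoff: float = DEFAULT_OTHER_CUTOFF,
) -> pd.Series:
    """Cohort-mean composition at ``level`` with rare taxa pooled as "Other".

    Taxa whose cohort-mean relative abundance is below ``cutoff`` are summed
    into a single "Other" row; total mass is conserved.
    """
    if table.kind != "relative":
        raise ValueError("collapse_other requires a relative-abundance table")
    agg = aggregate_taxonomy(table, taxmap, level)
    means = agg.data.mean(axis=0)
    means = means[means > 0]  # absent taxa are not part of the composition
    minor = means[means < cutoff]
    major = means[means >= cutoff].sort_values(ascending=False)
    if len(minor):
        major = pd.concat([major, pd.Series({"Other": minor.sum()})])
    major.name = level
    return major


def goods_coverage(table: AbundanceTable) -> pd.Series:
    """Good's coverage per sample: 1 − singletons / total reads."""
    if table.kind != "counts":
        raise ValueError("goods_coverage requires a counts table")
    values = table.values
    totals = values.sum(axis=1)
    zero = np.asarray(table.sample_ids)[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s): {zero}")
    singletons = (values == 1).sum(axis=1)
    return pd.Series(1.0 - singletons / totals, index=table.data.index, name="goods_coverage")


def rank_normalize_standardize(table: AbundanceTable | pd.DataFrame) -> NormalizedTable:
    """Map each species column to van der Waerden scores, then standardize.

    Ranks r (ties averaged, zeros included) are mapped through the standard
    normal quantile function as Φ⁻¹(r/(n+1)) — a tie-safe transform towards a
    Gaussian-shaped column with no boundary infinities — then centered and
    scaled to mean 0 and variance 1. The transform is monotone in the
    original values within each column, so Spearman correlations between
    columns are preserved.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.data
    n = frame.shape[0]
    if n < 3:
        raise ValueError(f"rank normalization requires at least 3 samples, got {n}")
    values = frame.to_numpy(dtype=float)
    out = {}
    dropped: list[str] = []
    for j, species in enumerate(frame.columns):
        col = values[:, j]
        if np.all(col == col[0]):
            dropped.append(species)
            continue
        scores = stats.norm.ppf(stats.rankdata(col) / (n + 1))
        scores = (scores - scores.mean()) / scores.std(ddof=0)
        out[species] = scores
    if dropped:
        logger.warning("rank_normalize_standardize dropped constant column(s): %s", dropped)
    result = pd.DataFrame(out, index=frame.index)
    return NormalizedTable(result, dropped=dropped)
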