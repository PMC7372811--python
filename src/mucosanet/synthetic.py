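"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates two mucosal community archetypes: a low-diversity
vaginal profile in which a single *Lactobacillus*-like species holds a target
share of the community (defaults to 92%, the middle of the commonly reported
90–95% lactobacilli share), and a polymicrobial endometrial profile with
power-law ranked abundances. On top of the compositional baseline it plants

* between-group log₂ abundance shifts (biomarker species),
* correlated species blocks via a Gaussian copula (network communities),
* abundance-dependent structural zeros (the well-known abundance–occupancy
  relationship), giving a prevalence gradient that makes a ≥20% prevalence
  filter non-trivial,
* uneven sequencing depth (log-normal library sizes, CV 0.3).

Counts are multinomial draws at each sample's depth, so every generated
matrix is a valid integer abundance table whose rows sum to their depths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbundanceTable,
    SampleMetadata,
    TaxonomyMap,
    OUTCOMES,
    write_abundance,
    write_metadata,
    write_taxonomy,
)

PROFILES = ("lactobacillus_dominant", "polymicrobial")

#: log-scale SD of the per-species log-normal abundance perturbation; chosen
#: so a dominant species' cohort-mean share stays inside the 90-95% band that
#: characterizes Lactobacillus-dominant communities at the 0.92 default target
DEFAULT_NOISE_SIGMA = 0.3
#: coefficient of variation of sequencing depth across samples
DEPTH_CV = 0.3

_LINEAGES = [
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Kocuria"),
    ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
]


@dataclass
class SynthConfig:
    """Parameters of one synthetic cohort (one habitat, two outcome groups)."""

    n_samples_per_group: int = 17
    n_species: int = 100
    habitat_profile: str = "lactobacillus_dominant"
    dominance_fraction: float = 0.92
    depth_mean: int = 17696
    dropout: float | np.ndarray = 0.9
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    biomarkers: list[tuple[int, float, str]] = field(default_factory=list)
    group_sizes: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.habitat_profile not in PROFILES:
            raise ValueError(f"habitat_profile must be one of {PROFILES}")
        if not 0 <= self.dominance_fraction < 1:
            raise ValueError("dominance_fraction must lie in [0, 1)")
        if self.n_species < 1 or self.n_samples_per_group < 1 or self.depth_mean < 1:
            raise ValueError("n_species, n_samples_per_group and depth_mean must be positive")
        if self.habitat_profile == "lactobacillus_dominant" and self.n_species < 2:
            raise ValueError(
                "dominant profile needs at least 2 species to carry the remaining mass"
            )
        seen: set[int] = set()
        for members, rho in self.blocks:
            if not 0 <= rho < 1:
                raise ValueError("within_block_rho must lie in [0, 1)")
            members = set(members)
            if members & seen:
                raise ValueError("block species sets must be disjoint")
            if any(not 0 <= i < self.n_species for i in members):
                raise ValueError("block species index out of range")
            seen |= members
        for idx, _effect, group in self.biomarkers:
            if not 0 <= idx < self.n_species:
                raise ValueError(f"biomarker species index {idx} out of range")
            if group not in OUTCOMES:
                raise ValueError(f"enriched_group must be one of {OUTCOMES}")

    @property
    def sizes(self) -> tuple[int, int]:
        if self.group_sizes is not None:
            return self.group_sizes
        return (self.n_samples_per_group, self.n_samples_per_group)

    @property
    def habitat(self) -> str:
        return "vagina" if self.habitat_profile == "lactobacillus_dominant" else "endometrium"


@dataclass
class SyntheticCohort:
    abundance: AbundanceTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    truth: dict
    config: SynthConfig


def profile_shape(config: SynthConfig) -> np.ndarray:
    """Target expected composition of the profile (sums to 1)."""
    m = config.n_species
    if config.habitat_profile == "lactobacillus_dominant":
        ranks = np.arange(1, m, dtype=float)
        tail = 1.0 / ranks
        shape = np.empty(m)
        shape[0] = config.dominance_fraction
        shape[1:] = (1.0 - config.dominance_fraction) * tail / tail.sum()
    else:
        ranks = np.arange(1, m + 1, dtype=float)
        shape = (1.0 / ranks) / (1.0 / ranks).sum()
    return shape


def dropout_probabilities(shape: np.ndarray, dropout) -> np.ndarray:
    """Per-species structural-zero probabilities.

    A scalar ``dropout`` is the probability for the rarest species; it decays
    log-linearly with abundance down to 0 for the most abundant species
    (abundance–occupancy relationship). An array is used verbatim.
    """
    d = np.asarray(dropout, dtype=float)
    if d.ndim == 0:
        dmax = float(d)
        if not 0 <= dmax < 1:
            raise ValueError("dropout must lie in [0, 1)")
        log_s = np.log(shape)
        span = log_s.max() - log_s.min()
        if span == 0:
            probs = np.full(shape.size, dmax / 2)
        else:
            probs = dmax * (log_s.max() - log_s) / span
    else:
        if d.shape != shape.shape:
            raise ValueError("per-species dropout array must have n_species entries")
        if np.any((d < 0) | (d >= 1)):
            raise ValueError("dropout probabilities must lie in [0, 1)")
        probs = d
    return probs


def block_correlation(n_species: int, blocks) -> np.ndarray:
    """Latent correlation matrix with constant within-block correlation."""
    corr = np.eye(n_species)
    for members, rho in blocks:
        idx = np.asarray(sorted(members))
        sub = np.full((idx.size, idx.size), rho)
        np.fill_diagonal(sub, 1.0)
        corr[np.ix_(idx, idx)] = sub
    min_eig = np.linalg.eigvalsh(corr).min()
    if min_eig < -1e-10:
        raise ValueError(f"block correlation matrix is not PSD (min eigenvalue {min_eig:.3g})")
    return corr


def _taxonomy_for(species_ids: list[str]) -> TaxonomyMap:
    rows = []
    for j, sp in enumerate(species_ids):
        lineage = _LINEAGES[0] if j < 3 else _LINEAGES[1 + (j - 3) % (len(_LINEAGES) - 1)]
        rows.append(dict(zip(("phylum", "class", "order", "family", "genus"), lineage),
                         species=sp))
    return TaxonomyMap(pd.DataFrame(rows, index=pd.Index(species_ids, name="species_id")))


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Draw one synthetic cohort. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    m = config.n_species
    n1, n2 = config.sizes
    total = n1 + n2
    outcome = np.array([OUTCOMES[0]] * n1 + [OUTCOMES[1]] * n2)

    shape = profile_shape(config)
    drop_p = dropout_probabilities(shape, config.dropout)
    # pre-dropout baselines compensated so the expected kept mass matches shape
    baseline = shape / (1.0 - drop_p)

    corr = block_correlation(m, config.blocks)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((total, m)) @ chol.T

    log_w = np.log(baseline)[None, :] + config.noise_sigma * latent
    for idx, log2_effect, group in config.biomarkers:
        log_w[outcome == group, idx] += log2_effect * np.log(2.0)

    kept = rng.random((total, m)) >= drop_p[None, :]
    weights = np.exp(log_w) * kept
    # the most abundant species has zero dropout, so no row can be all-zero
    composition = weights / weights.sum(axis=1, keepdims=True)

    sigma_d = np.sqrt(np.log(1.0 + DEPTH_CV**2))
    mu_d = np.log(config.depth_mean) - sigma_d**2 / 2
    depths = np.maximum(1, np.round(rng.lognormal(mu_d, sigma_d, total))).astype(np.int64)
    counts = np.vstack([rng.multinomial(depths[i], composition[i]) for i in range(total)])

    width = len(str(total))
    sample_ids = [f"{config.habitat}_{i + 1:0{width}d}" for i in range(total)]
    species_ids = [f"sp{j:04d}" for j in range(m)]
    abundance = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=species_ids), kind="counts"
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {"habitat": config.habitat, "outcome": outcome},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = {
        "profile": config.habitat_profile,
        "dominant_species": species_ids[int(np.argmax(shape))],
        "biomarkers": [
            {"species": species_ids[i], "log2_effect": eff, "enriched_group": grp}
            for i, eff, grp in config.biomarkers
        ],
        "blocks": [
            {"species": [species_ids[i] for i in sorted(members)], "rho": rho}
            for members, rho in config.blocks
        ],
    }
    return SyntheticCohort(abundance, metadata, _taxonomy_for(species_ids), truth, config)


def planted_truth(cohort: SyntheticCohort) -> dict:
    """Round-trip record of the planted biomarkers and correlation blocks."""
    return cohort.truth


def generate_paired_habitats(
    n_per_habitat: int = 17,
    n_species: int = 100,
    seed: int = 0,
    n_pregnant: int | None = None,
    **overrides,
) -> SyntheticCohort:
    """Two-habitat study cohort: lactobacillus-dominant vagina plus
    polymicrobial endometrium, sharing one species universe.

    ``n_pregnant`` samples per habitat carry the pregnant outcome (defaults to
    the study-like ~12% of the cohort, at least one).
    """
    if n_pregnant is None:
        n_pregnant = max(1, round(n_per_habitat * 4 / 34))
    sizes = (n_pregnant, n_per_habitat - n_pregnant)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    cohorts = [
        generate_cohort(SynthConfig(
            n_species=n_species, habitat_profile=profile,
            group_sizes=sizes, seed=int(s), **overrides,
        ))
        for profile, s in zip(PROFILES, seeds)
    ]
    abundance = AbundanceTable(
        pd.concat([c.abundance.data for c in cohorts]), kind="counts"
    )
    metadata = SampleMetadata(pd.concat([c.metadata.data for c in cohorts]))
    truth = {c.config.habitat: c.truth for c in cohorts}
    combined = SyntheticCohort(abundance, metadata, cohorts[0].taxonomy, truth, cohorts[0].config)
    return combined


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write abundance (TSV + mothur shared), metadata, taxonomy and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance_tsv": out / "abundance.tsv",
        "abundance_shared": out / "abundance.shared",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.json",
    }
    write_abundance(cohort.abundance, paths["abundance_tsv"], format="tsv")
    write_abundance(cohort.abundance, paths["abundance_shared"], format="mothur_shared")
    write_metadata(cohort.metadata, paths["metadata"])
    write_taxonomy(cohort.taxonomy, paths["taxonomy"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths
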