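"""End-to-end orchestration of the study-shaped analysis.

Stage order: low-count filter → relative abundances → alpha diversity (on
counts) → Bray-Curtis → PCoA/HCA → ANOSIM/PERMANOVA → rank normalization →
prevalence filter → LOO-averaged PLS-DA VIP + fold ratios → LEfSe-style
effect sizes → per-cohort co-occurrence network with Louvain communities,
centralities and keystone ranking. Two comparison designs are supported: the
habitat contrast (endometrium vs vagina, outcomes pooled) and the outcome
contrast run separately within each habitat.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import build_vip_report, lefse_like
from .diversity import bray_curtis, hca_complete, observed_otus, pcoa, shannon
from .io import (
    AbundanceTable,
    SampleMetadata,
    TaxonomyMap,
    read_abundance,
    read_metadata,
    read_taxonomy,
    write_network_gexf,
    FLOAT_FMT,
)
from .network import build_cooccurrence, centralities, keystone_species, louvain_communities
from .preprocess import (
    collapse_other,
    goods_coverage,
    min_count_filter,
    prevalence,
    prevalence_filter,
    rank_normalize_standardize,
    to_relative,
)
from .stats import anosim, permanova
from .synthetic import SynthConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

LOW_POWER_N = 5  # groups smaller than this are annotated "low-power"


@dataclass
class RunConfig:
    """Full parameterization of a pipeline run.

    Exactly one of (``abundance_path``, ``synth``) must be set.
    """

    abundance_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    abundance_format: str = "tsv"
    synth: SynthConfig | None = None
    comparison: str = "habitat"  # or "outcome_within_habitat"
    min_reads: int = 5
    prevalence_threshold: float = 0.20
    other_cutoff: float = 0.005
    alpha: float = 0.05
    fdr_q: float = 0.10
    min_datapoints: int = 5
    n_permutations: int = 999
    n_components: int = 2
    edge_alpha: float = 0.05
    resolution: float = 1.0
    n_restarts: int = 10
    top_k_keystones: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.abundance_path is None) == (self.synth is None):
            raise ValueError("set exactly one of abundance_path or synth")
        if self.comparison not in ("habitat", "outcome_within_habitat"):
            raise ValueError("comparison must be 'habitat' or 'outcome_within_habitat'")


@dataclass
class ComparisonReport:
    """All per-comparison results (one label contrast on one sample subset)."""

    name: str
    labels: dict
    anosim: object = None
    permanova: object = None
    ordination: object = None
    linkage: np.ndarray | None = None
    vip_report: pd.DataFrame | None = None
    lefse_report: pd.DataFrame | None = None
    n_species_filtered: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    alpha_diversity: pd.DataFrame
    comparisons: dict[str, ComparisonReport]
    networks: dict[str, dict]
    composition: dict[str, dict[str, pd.Series]]
    manifest: dict


def summarize_composition(table: AbundanceTable, taxmap: TaxonomyMap, level: str,
                          other_cutoff: float = 0.005) -> pd.Series:
    """Cohort-mean composition at a rank, rare taxa pooled as "Other"."""
    return collapse_other(table, taxmap, level, cutoff=other_cutoff)


def _load_inputs(config: RunConfig) -> tuple[AbundanceTable, SampleMetadata, TaxonomyMap]:
    if config.synth is not None:
        cohort = generate_cohort(config.synth)
        return cohort.abundance, cohort.metadata, cohort.taxonomy
    table = read_abundance(config.abundance_path, format=config.abundance_format)
    meta = read_metadata(config.metadata_path)
    taxmap = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    if not meta.covers(table):
        missing = sorted(set(table.sample_ids) - set(meta.sample_ids))
        raise ValueError(f"metadata does not cover samples: {missing}")
    return table, meta, taxmap


def run_pipeline(
    config: RunConfig,
    cohort: SyntheticCohort | None = None,
) -> RunReport:
    """Execute the full analysis; optionally on a pre-built synthetic cohort."""
    if cohort is not None:
        counts, meta, taxmap = cohort.abundance, cohort.metadata, cohort.taxonomy
    else:
        counts, meta, taxmap = _load_inputs(config)

    seed_seq = np.random.SeedSequence(config.seed)

    counts_f = min_count_filter(counts, min_reads=config.min_reads)
    rel = to_relative(counts_f)
    alpha_div = pd.DataFrame({
        "observed_otus": observed_otus(counts_f),
        "shannon": shannon(counts_f),
        "goods_coverage": goods_coverage(counts_f),
        "habitat": meta.habitat().loc[counts_f.sample_ids],
        "outcome": meta.outcome().loc[counts_f.sample_ids],
    })

    # comparison units: (name, sample subset, label series)
    units: list[tuple[str, list[str], pd.Series]] = []
    if config.comparison == "habitat":
        units.append(("habitat", counts_f.sample_ids, meta.habitat()))
    else:
        for habitat in sorted(meta.habitat().unique()):
            samples = [s for s in counts_f.sample_ids if meta.habitat()[s] == habitat]
            units.append((f"outcome_within_{habitat}", samples, meta.outcome()))

    comparisons: dict[str, ComparisonReport] = {}
    networks: dict[str, dict] = {}
    composition: dict[str, dict[str, pd.Series]] = {}

    for name, samples, label_series in units:
        labels = label_series.loc[samples]
        sizes = labels.value_counts().to_dict()
        report = ComparisonReport(name=name, labels=sizes)
        comparisons[name] = report
        if len(sizes) < 2 or min(sizes.values()) < 3:
            report.warnings.append(
                f"comparison skipped: group sizes {sizes} (need >=2 groups of >=3 samples)"
            )
            logger.warning("%s: %s", name, report.warnings[-1])
            continue
        if min(sizes.values()) < LOW_POWER_N:
            report.warnings.append(f"low-power comparison: group sizes {sizes}")
            logger.warning("%s: %s", name, report.warnings[-1])

        rel_u = rel.select_samples(samples)
        dm = bray_curtis(rel_u)
        report.ordination = pcoa(dm)
        report.linkage = hca_complete(dm)
        s1, s2 = (int(s) for s in seed_seq.spawn(1)[0].generate_state(2) % (2**31))
        report.anosim = anosim(dm, labels, n_perm=config.n_permutations, seed=s1)
        report.permanova = permanova(dm, labels, n_perm=config.n_permutations, seed=s2)

        norm = rank_normalize_standardize(rel_u)
        filtered = prevalence_filter(rel_u, threshold=config.prevalence_threshold)
        kept = [s for s in filtered.species_ids if s in set(norm.species_ids)]
        report.n_species_filtered = len(kept)
        if len(kept) >= 2:
            norm_f = type(norm)(norm.data[kept], dropped=norm.dropped)
            report.vip_report = build_vip_report(
                rel_u, norm_f, labels, n_components=config.n_components,
                alpha=config.alpha, q=config.fdr_q,
            )
            report.lefse_report = lefse_like(
                filtered.select_species(kept), labels,
                alpha=config.alpha, q=config.fdr_q, k=config.min_datapoints,
            )
        else:
            report.warnings.append("fewer than 2 species pass the prevalence filter")

        # per-cohort networks and compositional summaries
        for group in sorted(sizes):
            g_samples = [s for s in samples if labels[s] == group]
            key = f"{name}:{group}"
            if taxmap is not None:
                rel_g_all = rel.select_samples(g_samples)
                composition[key] = {
                    level: summarize_composition(rel_g_all, taxmap, level, config.other_cutoff)
                    for level in ("phylum", "family", "species")
                }
            if len(g_samples) < 3:
                networks[key] = {"skipped": f"only {len(g_samples)} samples"}
                continue
            rel_g = rel.select_samples(g_samples)
            filt_g = prevalence_filter(rel_g, threshold=config.prevalence_threshold)
            if filt_g.n_species < 2:
                networks[key] = {"skipped": "fewer than 2 species pass the prevalence filter"}
                continue
            norm_g = rank_normalize_standardize(filt_g)
            if len(norm_g.species_ids) < 2:
                networks[key] = {"skipped": "fewer than 2 variable species"}
                continue
            net = build_cooccurrence(
                norm_g, alpha=config.edge_alpha,
                prevalence=prevalence(rel_g),
                mean_abundance=rel_g.data.mean(axis=0),
            )
            louvain_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            comm = louvain_communities(net, resolution=config.resolution,
                                       n_restarts=config.n_restarts, seed=louvain_seed)
            cent = centralities(net)
            networks[key] = {
                "graph": net,
                "communities": comm,
                "centralities": cent,
                "keystones": keystone_species(net, top_k=config.top_k_keystones),
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "modularity": comm.modularity,
                "n_communities": len(set(comm.partition.values())),
            }

    manifest = {
        "package": "mucosanet",
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
    }
    report = RunReport(alpha_div, comparisons, networks, composition, manifest)
    if config.out_dir:
        _write_report(report, Path(config.out_dir))
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["out_dir"] = None  # output location is not part of the analysis
    if config.synth is not None:
        echo["synth"] = asdict(config.synth)
        dropout = echo["synth"]["dropout"]
        if isinstance(dropout, np.ndarray):
            echo["synth"]["dropout"] = dropout.tolist()
    return echo


def _write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.alpha_diversity.to_csv(out_dir / "alpha_diversity.tsv", sep="\t",
                                  index_label="sample_id", float_format=FLOAT_FMT)
    summary: dict = {"manifest": report.manifest, "comparisons": {}, "networks": {}}
    for name, comp in report.comparisons.items():
        entry: dict = {
            "group_sizes": {str(k): int(v) for k, v in comp.labels.items()},
            "n_species_filtered": comp.n_species_filtered,
            "warnings": comp.warnings,
        }
        for test_name in ("anosim", "permanova"):
            res = getattr(comp, test_name)
            if res is not None:
                entry[test_name] = {"statistic": res.statistic, "p_value": res.p_value,
                                    "n_permutations": res.n_permutations}
        summary["comparisons"][name] = entry
        if comp.ordination is not None:
            comp.ordination.coordinates.to_csv(
                out_dir / f"{name}_pcoa_coordinates.tsv", sep="\t",
                index_label="sample_id", float_format=FLOAT_FMT)
            pd.DataFrame({
                "eigenvalue": comp.ordination.eigenvalues,
            }).to_csv(out_dir / f"{name}_pcoa_eigenvalues.tsv", sep="\t",
                      index_label="axis", float_format=FLOAT_FMT)
        if comp.linkage is not None:
            pd.DataFrame(comp.linkage,
                         columns=["left", "right", "height", "size"]).to_csv(
                out_dir / f"{name}_hca_linkage.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)
        if comp.vip_report is not None:
            comp.vip_report.to_csv(out_dir / f"{name}_vip_report.tsv", sep="\t",
                                   float_format=FLOAT_FMT)
        if comp.lefse_report is not None:
            comp.lefse_report.to_csv(out_dir / f"{name}_lefse_report.tsv", sep="\t",
                                     float_format=FLOAT_FMT)
    for key, net_info in report.networks.items():
        slug = key.replace(":", "_")
        if "graph" in net_info:
            write_network_gexf(net_info["graph"], out_dir / f"{slug}_network.gexf")
            net_info["centralities"].to_csv(out_dir / f"{slug}_centralities.tsv",
                                            sep="\t", float_format=FLOAT_FMT)
            summary["networks"][key] = {
                "n_nodes": net_info["n_nodes"],
                "n_edges": net_info["n_edges"],
                "modularity": net_info["modularity"],
                "n_communities": net_info["n_communities"],
                "keystones": [[sp, bc] for sp, bc in net_info["keystones"]],
            }
        else:
            summary["networks"][key] = net_info
    for key, levels in report.composition.items():
        for level, series in levels.items():
            series.to_csv(out_dir / f"{key.replace(':', '_')}_composition_{level}.tsv",
                          sep="\t", header=["mean_share"], index_label=level,
                          float_format=FLOAT_FMT)
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
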