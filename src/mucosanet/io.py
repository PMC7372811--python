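"""Readers and writers for every external artifact of the pipeline.

Canonical on-disk dialect is UTF-8 TSV with ``#`` comment lines. The mothur
``.shared`` dialect (header ``label\\tGroup\\tnumOtus`` followed by one OTU
column per species) is supported read/write for interoperability with the
upstream OTU-picking toolchain; its ``label`` column carries the OTU-picking
distance cutoff and is ignored on read with a warning. Networks are exchanged
as GEXF 1.2, the native format of Gephi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HABITATS = ("endometrium", "vagina")
OUTCOMES = ("pregnant", "non_pregnant")
RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: significant digits used when writing real-valued matrices
FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


@dataclass
class AbundanceTable:
    """Samples × species abundance matrix.

    ``data`` rows are samples, columns are species. ``kind`` is ``"counts"``
    (non-negative integers) or ``"relative"`` (rows sum to 1).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        dup_s = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_s:
            raise FormatError(f"duplicate sample IDs: {dup_s}")
        dup_c = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_c:
            raise FormatError(f"duplicate species IDs: {dup_c}")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            raise FormatError("negative abundance values are not allowed")
        if self.kind == "counts":
            if values.size and not np.allclose(values, np.round(values)):
                raise FormatError("kind='counts' requires integral values")
            self.data = self.data.round().astype(np.int64)
        else:
            # species-subset tables keep their shares of the full community,
            # so row sums may fall below 1 but can never exceed it
            rowsums = values.sum(axis=1)
            if values.size and np.any(rowsums > 1.0 + 1e-9):
                bad = self.data.index[rowsums > 1.0 + 1e-9].tolist()
                raise FormatError(f"relative rows must sum to at most 1: {bad}")
            if values.size and np.any(rowsums == 0):
                bad = self.data.index[rowsums == 0].tolist()
                raise FormatError(f"all-zero relative rows are forbidden: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def select_species(self, species: list[str]) -> "AbundanceTable":
        return AbundanceTable(self.data[species], kind=self.kind)

    def select_samples(self, samples: list[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[samples], kind=self.kind)


@dataclass
class SampleMetadata:
    """Per-sample habitat and reproductive-outcome labels."""

    data: pd.DataFrame  # index sample_id; columns habitat, outcome

    def __post_init__(self) -> None:
        missing = {"habitat", "outcome"} - set(self.data.columns)
        if missing:
            raise FormatError(f"metadata missing required column(s): {sorted(missing)}")
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate sample IDs in metadata: {dup}")
        bad_h = sorted(set(self.data["habitat"]) - set(HABITATS))
        if bad_h:
            raise FormatError(
                f"unknown habitat label(s) {bad_h}; allowed: {list(HABITATS)}"
            )
        bad_o = sorted(set(self.data["outcome"]) - set(OUTCOMES))
        if bad_o:
            raise FormatError(
                f"unknown outcome label(s) {bad_o}; allowed: {list(OUTCOMES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def habitat(self) -> pd.Series:
        return self.data["habitat"]

    def outcome(self) -> pd.Series:
        return self.data["outcome"]

    def covers(self, table: AbundanceTable) -> bool:
        return set(table.sample_ids) <= set(self.data.index)

    def group_sizes(self, column: str) -> dict[str, int]:
        return self.data[column].value_counts().to_dict()


@dataclass
class TaxonomyMap:
    """species_id → six-rank lineage (phylum..species).

    Absent rank values default to ``"unclassified"``.
    """

    data: pd.DataFrame  # index species_id; columns = RANKS

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate species IDs in taxonomy: {dup}")
        for rank in RANKS:
            if rank not in self.data.columns:
                self.data[rank] = "unclassified"
        self.data = self.data[list(RANKS)].fillna("unclassified")
        self.data = self.data.replace("", "unclassified")

    def lineage(self, species_id: str) -> dict[str, str]:
        return self.data.loc[species_id].to_dict()

    def labels_at(self, level: str, species: list[str]) -> pd.Series:
        if level not in RANKS:
            raise ValueError(f"unknown taxonomic level {level!r}; allowed: {list(RANKS)}")
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise FormatError(f"species missing from taxonomy: {missing}")
        return self.data.loc[species, level]


# ---------------------------------------------------------------------------
# abundance tables


def _read_tsv_frame(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0)
    except pd.errors.ParserError as exc:  # ragged rows: pandas reports the line
        raise FormatError(f"malformed TSV {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_abundance(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read an abundance matrix from ``tsv`` or ``mothur_shared`` dialect.

    Integral matrices are detected as counts; otherwise rows must be relative
    abundances summing to 1.
    """
    if format == "tsv":
        frame = _read_tsv_frame(path)
    elif format == "mothur_shared":
        raw = pd.read_csv(path, sep="\t", comment="#", header=0)
        required = ["label", "Group", "numOtus"]
        missing = [c for c in required if c not in raw.columns]
        if missing:
            raise FormatError(f"mothur shared file missing column(s): {missing}")
        labels = raw["label"].unique().tolist()
        logger.warning("ignoring mothur 'label' column (values: %s)", labels)
        frame = raw.drop(columns=required[:1] + required[2:]).set_index("Group")
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
    else:
        raise ValueError(f"unknown format {format!r}; allowed: tsv, mothur_shared")
    values = frame.to_numpy(dtype=float)
    kind = "counts" if (values.size == 0 or np.allclose(values, np.round(values))) else "relative"
    return AbundanceTable(frame if kind == "relative" else frame.round().astype(np.int64), kind=kind)


def write_abundance(table: AbundanceTable, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        table.data.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)
    elif format == "mothur_shared":
        out = table.data.copy()
        out.insert(0, "label", "userLabel")
        out.insert(1, "Group", table.data.index)
        out.insert(2, "numOtus", table.data.shape[1])
        out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    else:
        raise ValueError(f"unknown format {format!r}; allowed: tsv, mothur_shared")


# ---------------------------------------------------------------------------
# metadata / taxonomy


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in frame.columns:
        raise FormatError("metadata missing required column(s): ['sample_id']")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "species_id" not in frame.columns:
        raise FormatError("taxonomy missing required column(s): ['species_id']")
    frame = frame.set_index("species_id")
    return TaxonomyMap(frame)


def write_taxonomy(taxmap: TaxonomyMap, path: str | Path) -> None:
    taxmap.data.to_csv(path, sep="\t", index_label="species_id")


# ---------------------------------------------------------------------------
# networks (GEXF 1.2, Gephi's exchange format)

_NODE_ATTRS = ("community", "degree", "betweenness", "mean_norm_abundance", "prevalence")
_EDGE_ATTRS = ("r", "p", "sign", "category", "weight")


def write_network_gexf(net: nx.Graph, path: str | Path) -> None:
    """Write a co-occurrence network as GEXF 1.2.

    Node attributes: community, degree, betweenness, mean_norm_abundance,
    prevalence. Edge attributes: r, p, sign ("positive"/"negative"),
    category (1-8), weight = |r|.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network (no nodes)")
    out = nx.Graph()
    for node, attrs in net.nodes(data=True):
        clean = {}
        for key in _NODE_ATTRS:
            if key in attrs:
                val = attrs[key]
                clean[key] = int(val) if key in ("community", "degree") else float(val)
        out.add_node(str(node), **clean)
    for u, v, attrs in net.edges(data=True):
        clean = {}
        for key in _EDGE_ATTRS:
            if key in attrs:
                val = attrs[key]
                if key == "sign":
                    clean[key] = str(val)
                elif key == "category":
                    clean[key] = int(val)
                else:
                    clean[key] = float(val)
        out.add_edge(str(u), str(v), **clean)
    nx.write_gexf(out, path, version="1.2draft")


def read_network_gexf(path: str | Path) -> nx.Graph:
    net = nx.read_gexf(path)
    return nx.Graph(net)
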