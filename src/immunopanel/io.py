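"""Domain types and readers/writers for the file formats the pipeline touches.

The panel world is small and tabular, so everything is carried as pandas
objects wrapped in lightweight validated containers:

* :class:`PanelAnnotation` — probe → gene mapping with probe class
  (endogenous / housekeeping / positive / negative) and the spike-in
  ladder concentration for positive controls.
* :class:`CountMatrix` — non-negative integer counts, probes × samples,
  plus per-sample metadata and a processing ``stage`` tag.
* :class:`GeneSetCollection` — named gene sets (GMT).
* :class:`CellMarkerMap` — cell type → marker gene symbols.
* :class:`PhenotypeTable` — per-sample histopathology / staining endpoints.
* :class:`EdgeList` — undirected gene–gene interactions with a combined
  confidence score in [0, 1].

File formats: RCC (the per-lane sectioned-CSV raw count format of digital
barcode counters), plain counts CSV, GMT, marker-map TSV, phenotype CSV and
edge-list TSV.  Readers validate on ingestion and raise typed errors rather
than silently coercing, with one documented exception: edge scores on the
0–1000 dialect are rescaled to 0–1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PROBE_CLASSES",
    "PanelAnnotation",
    "CountMatrix",
    "GeneSetCollection",
    "CellMarkerMap",
    "PhenotypeTable",
    "EdgeList",
    "read_rcc",
    "write_rcc",
    "read_rcc_set",
    "write_rcc_set",
    "read_gene_sets",
    "write_gene_sets",
    "read_edge_list",
    "write_edge_list",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_metadata_csv",
    "read_phenotypes_csv",
    "read_marker_map",
    "default_marker_map",
    "default_gene_sets",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violates a domain-type invariant."""


PROBE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")

#: RCC CodeClass column spellings → internal probe class
_CODECLASS_MAP = {
    "endogenous": "endogenous",
    "housekeeping": "housekeeping",
    "positive": "positive",
    "negative": "negative",
}

TREATMENTS = ("VEH", "cSiO2")
REGIMENS = ("single", "four_weekly")
TIME_POINTS = ("day1", "W1", "W5", "W9", "W13")
TISSUES = ("lung", "kidney", "spleen")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PanelAnnotation:
    """Probe annotations for a targeted panel.

    ``table`` is indexed by ``probe_id`` with columns ``gene_symbol``,
    ``probe_class`` and ``ladder_concentration`` (fM; NaN except for
    positive controls).  Gene symbols are matched case-sensitively
    throughout the package.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_symbol", "probe_class"}
        if not required.issubset(t.columns):
            raise ValidationError(f"annotation requires columns {sorted(required)}")
        if "ladder_concentration" not in t.columns:
            t = t.copy()
            t["ladder_concentration"] = np.nan
            self.table = t
        if t.index.has_duplicates:
            dupes = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_ids: {dupes}")
        bad = set(t["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe classes: {sorted(bad)}")
        pos = t[t["probe_class"] == "positive"]
        if len(pos) and not (pos["ladder_concentration"] > 0).all():
            raise ValidationError("every positive probe needs ladder_concentration > 0")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def probes_of_class(self, probe_class: str) -> pd.Index:
        if probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {probe_class!r}")
        return self.table.index[self.table["probe_class"] == probe_class]

    def genes_of_class(self, probe_class: str) -> pd.Index:
        return pd.Index(
            self.table.loc[self.probes_of_class(probe_class), "gene_symbol"]
        )

    @property
    def gene_symbols(self) -> pd.Series:
        return self.table["gene_symbol"]

    def require_all_classes(self) -> None:
        """Normalization needs at least one probe of each class."""
        for cls in PROBE_CLASSES:
            if len(self.probes_of_class(cls)) == 0:
                raise ValidationError(f"panel has no {cls} probes")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountMatrix:
    """Probe × sample count matrix with sample metadata and a stage tag."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    stage: str = "raw"

    STAGES = ("raw", "background_subtracted", "normalized")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValidationError("duplicate probe or sample ids")
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise ValidationError(f"samples without metadata: {missing.tolist()}")
        if self.stage == "raw":
            vals = self.counts.to_numpy()
            if (vals < 0).any():
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("raw counts must be integers")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.metadata.loc[ids], self.stage)

    def with_counts(self, counts: pd.DataFrame, stage: str) -> "CountMatrix":
        return CountMatrix(counts, self.metadata, stage)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name → member gene symbols (duplicates removed)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = deduped
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class CellMarkerMap:
    """Cell type → marker gene symbols; multi-marker types get confidence p."""

    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell_type, genes in self.markers.items():
            if not genes:
                raise ValidationError(f"cell type {cell_type!r} has no markers")

    def is_multi_marker(self, cell_type: str) -> bool:
        return len(self.markers[cell_type]) >= 2

    def items(self):
        return self.markers.items()

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, cell_type: str) -> list[str]:
        return self.markers[cell_type]

    def validate_against_panel(self, gene_symbols: Iterable[str]) -> None:
        universe = set(gene_symbols)
        for cell_type, genes in self.markers.items():
            missing = [g for g in genes if g not in universe]
            if missing:
                raise ValidationError(
                    f"markers for {cell_type!r} absent from panel: {missing}"
                )


ORDINAL_ENDPOINTS = (
    "lymphoid_aggregates",
    "ectopic_lymphoid_structures",
    "alveolar_proteinosis",
    "alveolitis",
    "type2_cell_hyperplasia",
    "mucus_cell_metaplasia",
)
PERCENT_ENDPOINTS = ("CD3_pct", "CD45R_pct", "CD21_35_pct")


@dataclass
class PhenotypeTable:
    """Wide per-sample phenotype table: ordinal lesion scores + % staining."""

    table: pd.DataFrame  # index sample_id, columns endpoint names

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample_ids in phenotype table")
        for col in t.columns:
            vals = t[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative values in endpoint {col!r}")
            if col.endswith("_pct") and (vals > 100).any():
                raise ValidationError(f"percent endpoint {col!r} exceeds 100")

    @property
    def endpoints(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class EdgeList:
    """Undirected weighted edges; scores in [0, 1]; no self-loops."""

    edges: pd.DataFrame  # columns gene_a, gene_b, combined_score

    def __post_init__(self) -> None:
        e = self.edges
        required = ["gene_a", "gene_b", "combined_score"]
        if list(e.columns[:3]) != required:
            e = e[required]
        scores = e["combined_score"]
        if ((scores < 0) | (scores > 1)).any():
            raise ValidationError("combined_score must lie in [0, 1]")
        if (e["gene_a"] == e["gene_b"]).any():
            raise ValidationError("self-loops are not allowed")
        self.edges = e.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


# ---------------------------------------------------------------------------
# RCC (sectioned CSV, one lane per file)
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"<(?P<name>\w+)>\n(?P<body>.*?)</(?P=name)>", re.S)


def read_rcc(path: str | Path) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """Parse one RCC lane file.

    Returns ``(code_summary, attributes)`` where ``code_summary`` is a frame
    indexed by probe_id with columns ``gene_symbol``, ``probe_class``,
    ``count``, and ``attributes`` maps section name → key/value dict for the
    non-tabular sections (Header, Lane_Attributes, ...).
    """
    text = Path(path).read_text()
    sections = {m.group("name"): m.group("body") for m in _SECTION_RE.finditer(text)}
    for required in ("Header", "Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise FormatError(f"RCC file {path} is missing the {required} section")

    attributes: dict[str, dict[str, str]] = {}
    for name, body in sections.items():
        if name == "Code_Summary":
            continue
        kv: dict[str, str] = {}
        for line in body.strip().splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition(",")
            kv[key] = value
        attributes[name] = kv

    lines = [ln for ln in sections["Code_Summary"].strip().splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty Code_Summary section")
    header = [h.strip() for h in lines[0].split(",")]
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise FormatError(f"Code_Summary header missing a column: {exc}") from exc
    i_acc = header.index("Accession") if "Accession" in header else None

    rows = []
    for line in lines[1:]:
        fields_ = line.split(",")
        if len(fields_) < len(header):
            raise FormatError(f"short Code_Summary row: {line!r}")
        raw_class = fields_[i_class].strip()
        probe_class = _CODECLASS_MAP.get(raw_class.lower())
        if probe_class is None:
            raise FormatError(f"unknown CodeClass {raw_class!r}")
        raw_count = fields_[i_count].strip()
        try:
            count = int(raw_count)
        except ValueError:
            raise FormatError(f"non-integer count {raw_count!r} for {fields_[i_name]!r}")
        probe_id = fields_[i_acc] if i_acc is not None and fields_[i_acc] else fields_[i_name]
        name = fields_[i_name]
        ladder = np.nan
        if probe_class == "positive":
            # positive-control names carry the spike-in concentration: POS_A(128)
            m = re.match(r"^(.*)\((\d*\.?\d+)\)$", name)
            if m:
                name, ladder = m.group(1), float(m.group(2))
        rows.append((probe_id, name, probe_class, count, ladder))

    summary = pd.DataFrame(
        rows,
        columns=["probe_id", "gene_symbol", "probe_class", "count", "ladder_concentration"],
    ).set_index("probe_id")
    if summary.index.has_duplicates:
        raise FormatError("duplicate probe ids in Code_Summary")
    return summary, attributes


def write_rcc(
    counts: Mapping[str, int] | pd.Series,
    annotation: PanelAnnotation,
    lane_attributes: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write one lane as a sectioned-CSV RCC file (lossless round-trip)."""
    counts = pd.Series(counts)
    if len(counts) == 0:
        raise ValidationError("cannot write an RCC lane with no probes")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if not np.allclose(counts.to_numpy(float), np.round(counts.to_numpy(float))):
        raise ValidationError("counts must be integers")
    missing = counts.index.difference(annotation.probe_ids)
    if len(missing):
        raise ValidationError(f"probes not in annotation: {missing.tolist()}")

    lines = ["<Header>", "FileVersion,3.0", "SoftwareVersion,immunopanel", "</Header>", ""]
    lines.append("<Lane_Attributes>")
    for key, value in lane_attributes.items():
        lines.append(f"{key},{value}")
    lines.append("</Lane_Attributes>")
    lines.append("")
    lines.append("<Code_Summary>")
    lines.append("CodeClass,Name,Accession,Count")
    code_class_out = {
        "endogenous": "Endogenous",
        "housekeeping": "Housekeeping",
        "positive": "Positive",
        "negative": "Negative",
    }
    for probe_id in counts.index:
        row = annotation.table.loc[probe_id]
        name = row["gene_symbol"]
        if row["probe_class"] == "positive" and np.isfinite(row["ladder_concentration"]):
            name = f"{name}({row['ladder_concentration']:g})"
        lines.append(
            f"{code_class_out[row['probe_class']]},{name},"
            f"{probe_id},{int(counts[probe_id])}"
        )
    lines.append("</Code_Summary>")
    Path(path).write_text("\n".join(lines) + "\n")


def write_rcc_set(
    matrix: CountMatrix, annotation: PanelAnnotation, directory: str | Path
) -> list[Path]:
    """Write one RCC file per sample into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for lane_no, sample_id in enumerate(matrix.sample_ids, start=1):
        path = directory / f"{sample_id}.RCC"
        write_rcc(
            matrix.counts[sample_id],
            annotation,
            {"ID": str(lane_no), "SampleID": sample_id},
            path,
        )
        paths.append(path)
    return paths


def read_rcc_set(
    paths: Iterable[str | Path], metadata: pd.DataFrame
) -> tuple[CountMatrix, PanelAnnotation]:
    """Assemble a CountMatrix + PanelAnnotation from a set of lane files.

    Sample ids come from the ``SampleID`` lane attribute (falling back to the
    file stem); all lanes must share one probe universe.
    """
    columns: dict[str, pd.Series] = {}
    annotation_table = None
    for path in sorted(Path(p) for p in paths):
        summary, attrs = read_rcc(path)
        sample_id = attrs.get("Lane_Attributes", {}).get("SampleID") or path.stem
        columns[sample_id] = summary["count"]
        ann = summary[["gene_symbol", "probe_class", "ladder_concentration"]]
        if annotation_table is None:
            annotation_table = ann
        elif not annotation_table.equals(ann.loc[annotation_table.index]):
            raise FormatError(f"lane {path} disagrees with earlier probe annotations")
    if annotation_table is None:
        raise FormatError("no RCC files supplied")
    counts = pd.DataFrame(columns).loc[annotation_table.index, list(metadata.index)]
    annotation = PanelAnnotation(annotation_table.copy())
    return CountMatrix(counts, metadata, stage="raw"), annotation


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields_ = line.rstrip("\n").split("\t")
        if len(fields_) < 3:
            raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
        name = fields_[0]
        members = [g for g in fields_[2:] if g]
        sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *members]) for name, members in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> EdgeList:
    """Read a TSV edge list (gene_a, gene_b, combined_score).

    Scores may be on the native 0–1 scale or the 0–1000 dialect used by
    interaction databases; any file whose maximum score exceeds 1 is treated
    as 0–1000 and divided by 1000.  Self-loops are dropped; duplicate
    undirected edges keep the maximum score.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "combined_score"}
    if not required.issubset(frame.columns):
        raise FormatError(f"edge list requires columns {sorted(required)}")
    scores = frame["combined_score"].astype(float)
    if (scores < 0).any() or (scores > 1000).any():
        raise ValidationError("edge scores outside both [0,1] and [0,1000]")
    if scores.max() > 1:
        scores = scores / 1000.0
    frame = frame.assign(combined_score=scores)
    frame = frame[frame["gene_a"] != frame["gene_b"]]
    lo = frame[["gene_a", "gene_b"]].min(axis=1)
    hi = frame[["gene_a", "gene_b"]].max(axis=1)
    frame = frame.assign(gene_a=lo, gene_b=hi)
    frame = (
        frame.groupby(["gene_a", "gene_b"], as_index=False)["combined_score"]
        .max()
        .sort_values(["gene_a", "gene_b"], kind="stable")
    )
    return EdgeList(frame.reset_index(drop=True))


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    edge_list.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CSV/TSV tables
# ---------------------------------------------------------------------------

def read_annotation_csv(path: str | Path) -> PanelAnnotation:
    """Probe annotation CSV: probe_id, gene_symbol, probe_class[, ladder_concentration]."""
    frame = pd.read_csv(path, index_col=0)
    return PanelAnnotation(frame)


def write_annotation_csv(annotation: PanelAnnotation, path: str | Path) -> None:
    annotation.table.rename_axis("probe_id").to_csv(path)


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    """Counts CSV: probes as rows (first column probe_id), samples as columns."""
    frame = pd.read_csv(path, index_col=0)
    if frame.index.has_duplicates:
        raise FormatError("duplicate probe_ids in counts CSV")
    return frame


def write_counts_csv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("probe_id").to_csv(path)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV with treatment/regimen/time_point/tissue/replicate."""
    meta = pd.read_csv(path, index_col=0)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"treatment", "regimen", "time_point", "tissue", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns {sorted(missing)}")
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample_ids in metadata")
    if meta[sorted(required)].isna().any().any():
        raise ValidationError("metadata has missing values")
    for col, allowed in [
        ("treatment", TREATMENTS),
        ("regimen", REGIMENS),
        ("time_point", TIME_POINTS),
        ("tissue", TISSUES),
    ]:
        bad = set(meta[col]) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} values: {sorted(bad)}")
    return meta


def read_phenotypes_csv(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, index_col=0))


def read_marker_map(path: str | Path) -> CellMarkerMap:
    """Marker map TSV with columns cell_type, gene_symbol (one marker per row)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene_symbol"}.issubset(frame.columns):
        raise FormatError("marker map requires columns cell_type, gene_symbol")
    markers: dict[str, list[str]] = {}
    for cell_type, group in frame.groupby("cell_type", sort=False):
        markers[cell_type] = list(dict.fromkeys(group["gene_symbol"]))
    return CellMarkerMap(markers)


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_marker_map() -> CellMarkerMap:
    """The packaged immune cell-type marker map (mouse gene symbols)."""
    return read_marker_map(_data_path("cell_markers.tsv"))


def default_gene_sets() -> GeneSetCollection:
    """The packaged immune pathway gene sets."""
    return read_gene_sets(_data_path("immune_pathways.gmt"))
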