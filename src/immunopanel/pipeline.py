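"""End-to-end orchestration: simulate/load → normalize → DE → scores →
cells → associate → network → report bundle.

A run is described by a validated :class:`RunConfig` (YAML-loadable).  The
study is split into *analysis units* — (tissue × experiment) groups that
share a background model, normalization and gene-exclusion universe:
``acute1x`` (single instillation, day 1), ``acute4x`` (four weekly
instillations, day 1) and ``chronic`` (four weekly instillations, weeks
1–13).  Contrasts never straddle units.

The report bundle holds, per contrast, the DE table; per unit, the
significance-score table, pathway-Z matrix and cell-score tables; plus the
pathway–phenotype correlation screen (chronic lung), Venn region tables,
network cluster assignments, per-stage counts, and a manifest with the
config hash and seed so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from ._utils import derive_seed
from .association import spearman_screen, venn_overlaps
from .cell_profiling import CellTypeScorer, compare_groups
from .diffexpr import (
    DifferentialExpression,
    build_standard_contrasts,
    sequential_contrasts,
)
from .io import (
    CountMatrix,
    PhenotypeTable,
    ValidationError,
    read_annotation_csv,
    read_counts_csv,
    read_edge_list,
    read_gene_sets,
    read_marker_map,
    read_metadata_csv,
    read_phenotypes_csv,
)
from .network import MarkovClustering, filter_edges
from .normalization import PanelNormalizer
from .scoring import PathwayScorer
from .simulate import (
    SimulationConfig,
    default_design,
    simulate_counts,
    simulate_edge_list,
    simulate_panel,
    simulate_phenotypes,
)

__all__ = ["RunConfig", "SimulateConfig", "InputPaths", "run_pipeline", "report_summary"]

logger = logging.getLogger(__name__)

REQUIRED_TABLES = (
    "de",
    "significance",
    "pathway_z",
    "cell_scores",
    "correlations",
    "venn",
    "clusters",
)


class SimulateConfig(BaseModel):
    """Simulated-study section of the run configuration."""

    n_endogenous: int = 770
    n_housekeeping: int = 40
    n_positive: int = 6
    n_negative: int = 8
    n_sets: int = 8
    n_cell_types: int = 13
    n_per_group: int = 8
    de_fraction: float = Field(0.1, ge=0.0, le=1.0)
    effect_size: float = 2.0
    up_fraction: float = Field(0.8, ge=0.0, le=1.0)
    phenotype_noise_sd: float = 0.3
    responder_fraction: float = Field(3.0 / 8.0, ge=0.0, le=1.0)
    attenuation: float = 0.25


class InputPaths(BaseModel):
    """File-based inputs for a run on real data."""

    counts: str
    metadata: str
    annotation: str
    gene_sets: str
    markers: Optional[str] = None
    phenotypes: Optional[str] = None
    edges: Optional[str] = None


class RunConfig(BaseModel):
    """Validated run configuration; all thresholds are overridable defaults."""

    seed: int
    out_dir: Optional[str] = None
    simulate: Optional[SimulateConfig] = None
    inputs: Optional[InputPaths] = None
    model: str = "log_linear"
    q_threshold: float = Field(0.05, gt=0.0, lt=1.0)
    log2_threshold: float = Field(1.0, ge=0.0)
    rho_threshold: float = Field(0.5, ge=0.0, le=1.0)
    edge_threshold: float = Field(0.7, gt=0.0, le=1.0)
    inflation: float = Field(1.5, gt=1.0)
    cell_permutations: int = 2000

    @field_validator("model")
    @classmethod
    def _check_model(cls, v: str) -> str:
        if v not in ("log_linear", "nb"):
            raise ValueError("model must be 'log_linear' or 'nb'")
        return v

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are: not hashed
        payload = self.model_dump(mode="json", exclude={"out_dir"})
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            return cls.model_validate(yaml.safe_load(handle))


def _experiment_of(meta_row) -> str:
    if meta_row["regimen"] == "single":
        return "acute1x"
    if meta_row["time_point"] == "day1":
        return "acute4x"
    return "chronic"


def _assign_units(metadata: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [
            f"{row.tissue}:{_experiment_of(row._asdict())}"
            for row in metadata.itertuples()
        ],
        index=metadata.index,
        name="analysis_unit",
    )


def _planted_effects(panel, cfg: SimulateConfig, seed: int) -> dict[str, float]:
    import numpy as np

    genes = list(panel.genes_of_class("endogenous"))
    rng = np.random.default_rng(derive_seed(seed, "planted_effects"))
    n_de = int(round(cfg.de_fraction * len(genes)))
    picked = rng.choice(len(genes), size=n_de, replace=False)
    effects = {}
    for idx in picked:
        up = rng.random() < cfg.up_fraction
        effects[genes[idx]] = cfg.effect_size if up else -cfg.effect_size
    return effects


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the report bundle.

    The bundle is a nested dict of pandas tables plus a manifest; if
    ``config.out_dir`` is set the tables are also written as TSV/JSON.
    """
    stage = "inputs"
    counts_log: dict[str, dict] = {}
    try:
        bundle: dict = {"manifest": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.model_dump(mode="json", exclude={"out_dir"}),
        }}

        truth = None
        if config.simulate is not None:
            sim = config.simulate
            panel, gene_sets, marker_map = simulate_panel(
                sim.n_endogenous, sim.n_housekeeping, sim.n_positive,
                sim.n_negative, sim.n_sets, sim.n_cell_types, seed=config.seed,
            )
            design = default_design(sim.n_per_group)
            sim_config = SimulationConfig(
                effects=_planted_effects(panel, sim, config.seed),
                responder_fraction=sim.responder_fraction,
                attenuation=sim.attenuation,
            )
            matrix, truth = simulate_counts(panel, design, sim_config, seed=config.seed)
            phenotypes = simulate_phenotypes(
                design, truth, noise_sd=sim.phenotype_noise_sd, seed=config.seed
            )
            edge_list = None
        elif config.inputs is not None:
            paths = config.inputs
            panel = read_annotation_csv(paths.annotation)
            metadata = read_metadata_csv(paths.metadata)
            counts = read_counts_csv(paths.counts)
            matrix = CountMatrix(counts, metadata, stage="raw")
            gene_sets = read_gene_sets(paths.gene_sets)
            from .io import default_marker_map

            marker_map = (
                read_marker_map(paths.markers) if paths.markers else default_marker_map()
            )
            phenotypes = (
                read_phenotypes_csv(paths.phenotypes) if paths.phenotypes else None
            )
            edge_list = read_edge_list(paths.edges) if paths.edges else None
        else:
            raise ValidationError("config needs either a simulate or an inputs section")

        units = _assign_units(matrix.metadata)
        bundle["de"] = {}
        bundle["significance"] = {}
        bundle["pathway_z"] = {}
        bundle["cell_scores"] = {}
        bundle["cell_comparisons"] = {}
        bundle["qc"] = {}
        normalized_by_unit: dict[str, CountMatrix] = {}
        excluded_by_unit: dict[str, set] = {}

        stage = "normalization"
        for unit in sorted(units.unique()):
            unit_samples = units.index[units == unit]
            unit_matrix = matrix.subset_samples(unit_samples)
            normalizer = PanelNormalizer()
            normalized = normalizer.fit_transform(unit_matrix, panel)
            normalized_by_unit[unit] = normalized
            excluded_by_unit[unit] = normalizer.excluded_genes_
            bundle["qc"][unit] = normalizer.qc_report()
            counts_log[unit] = {
                "n_samples": int(len(unit_samples)),
                "n_genes_excluded_background": len(normalizer.excluded_genes_),
            }

        stage = "differential_expression"
        contrasts = build_standard_contrasts(matrix.metadata)
        contrast_unit = {}
        for contrast in contrasts:
            unit = units[contrast.case[0]]
            contrast_unit[contrast.name] = unit
            de = DifferentialExpression(
                model=config.model,
                q_threshold=config.q_threshold,
                log2_threshold=config.log2_threshold,
            )
            kwargs = {}
            if config.model == "nb":
                normalizer_unit = normalized_by_unit[unit]
                raw_unit = matrix.subset_samples(normalizer_unit.sample_ids)
                offsets = normalizer_unit.counts.sum() / raw_unit.counts.sum()
                kwargs = {"raw": raw_unit, "offsets": offsets}
            de.fit(
                normalized_by_unit[unit],
                contrast,
                annotation=panel,
                exclude_genes=excluded_by_unit[unit],
                **kwargs,
            )
            bundle["de"][contrast.name] = de.results_
            counts_log[contrast.name] = {
                "n_genes_tested": int(len(de.results_)),
                "n_genes_significant": int(de.results_["significant"].sum()),
            }

        lung_weeks = [c for c in bundle["de"] if c.startswith("Lung.W")]
        if len(lung_weeks) >= 2:
            chronic_lung = matrix.subset_samples(
                units.index[units == "lung:chronic"]
            )
            weeks_present = [
                w for w in ("W1", "W5", "W9", "W13")
                if f"Lung.{w}" in bundle["de"]
            ]
            bundle["sequential_de"] = sequential_contrasts(
                normalized_by_unit["lung:chronic"],
                weeks_present,
                annotation=panel,
                model="log_linear",
                exclude_genes=excluded_by_unit["lung:chronic"],
            )

        stage = "scoring"
        for unit, normalized in normalized_by_unit.items():
            scorer = PathwayScorer(gene_sets)
            unit_contrasts = [
                name for name, u in contrast_unit.items() if u == unit
            ]
            blocks = []
            for name in unit_contrasts:
                sig = scorer.score_significance(bundle["de"][name])
                blocks.append(sig.assign(contrast=name).reset_index())
            if blocks:
                bundle["significance"][unit] = pd.concat(blocks, ignore_index=True)
            bundle["pathway_z"][unit] = scorer.transform(
                normalized, panel, excluded_by_unit[unit]
            )

        stage = "cell_profiling"
        for unit, normalized in normalized_by_unit.items():
            cell_scorer = CellTypeScorer(
                marker_map,
                n_permutations=config.cell_permutations,
                random_state=derive_seed(config.seed, "cells", unit),
            )
            scores = cell_scorer.fit_transform(normalized, panel, excluded_by_unit[unit])
            bundle["cell_scores"][unit] = {
                "scores": scores,
                "confidence": cell_scorer.confidence_,
            }
            comparisons = {}
            for name, u in contrast_unit.items():
                if u != unit:
                    continue
                contrast = next(c for c in contrasts if c.name == name)
                comparisons[name] = compare_groups(
                    scores, list(contrast.case), list(contrast.reference)
                )
            bundle["cell_comparisons"][unit] = comparisons

        stage = "association"
        correlations = None
        if phenotypes is not None and "lung:chronic" in bundle["pathway_z"]:
            correlations = spearman_screen(
                bundle["pathway_z"]["lung:chronic"],
                phenotypes,
                rho_threshold=config.rho_threshold,
            )
        bundle["correlations"] = correlations

        venn_tables = {}
        lung_sets = {
            name: set(bundle["de"][name].index[bundle["de"][name]["significant"]])
            for name in bundle["de"]
            if name.startswith("Lung.W")
        }
        if len(lung_sets) >= 2:
            venn_tables["lung_weeks"] = venn_overlaps(lung_sets)
        tissue_sets = {
            name: set(bundle["de"][name].index[bundle["de"][name]["significant"]])
            for name in ("Lung.W13", "Kidney.W13", "Spleen.W13")
            if name in bundle["de"]
        }
        if len(tissue_sets) >= 2:
            venn_tables["tissues_w13"] = venn_overlaps(tissue_sets)
        acute_sets = {
            name: set(bundle["de"][name].index[bundle["de"][name]["significant"]])
            for name in ("Acute.1x", "Acute.4x")
            if name in bundle["de"]
        }
        if len(acute_sets) >= 2:
            venn_tables["acute"] = venn_overlaps(acute_sets)
        bundle["venn"] = venn_tables

        stage = "network"
        all_significant = sorted(
            set().union(*(s for s in lung_sets.values()), *(s for s in tissue_sets.values()))
        ) if (lung_sets or tissue_sets) else []
        if config.simulate is not None and len(all_significant) >= 2:
            edge_list, _ = simulate_edge_list(
                all_significant, n_modules=min(3, len(all_significant)),
                seed=derive_seed(config.seed, "network"),
            )
        clusters_table = None
        network_summary = {"n_nodes": 0, "n_edges": 0, "cluster_sizes": []}
        if edge_list is not None and len(all_significant) >= 2:
            filtered = filter_edges(
                edge_list, threshold=config.edge_threshold,
                gene_universe=set(all_significant),
            )
            if len(filtered):
                mcl_est = MarkovClustering(inflation=config.inflation)
                mcl_est.fit(filtered)
                clusters_table = pd.DataFrame(
                    sorted(mcl_est.labels_.items()),
                    columns=["gene_symbol", "cluster_id"],
                )
                network_summary = {
                    "n_nodes": len(mcl_est.labels_),
                    "n_edges": int(len(filtered)),
                    "cluster_sizes": sorted(
                        (len(c) for c in mcl_est.clusters_), reverse=True
                    ),
                    "n_iterations": mcl_est.n_iter_,
                    "converged": mcl_est.converged_,
                }
        bundle["clusters"] = clusters_table
        bundle["network_summary"] = network_summary
        bundle["counts_log"] = counts_log
        if truth is not None:
            bundle["truth"] = truth

        if config.out_dir:
            _write_bundle(bundle, Path(config.out_dir))
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in bundle["de"].items():
        table.to_csv(out_dir / f"de_{name}.tsv", sep="\t")
    for unit, table in bundle["significance"].items():
        table.to_csv(out_dir / f"significance_{unit.replace(':', '_')}.tsv", sep="\t", index=False)
    for unit, table in bundle["pathway_z"].items():
        table.to_csv(out_dir / f"pathway_z_{unit.replace(':', '_')}.tsv", sep="\t")
    for unit, cell in bundle["cell_scores"].items():
        cell["scores"].to_csv(out_dir / f"cell_scores_{unit.replace(':', '_')}.tsv", sep="\t")
        cell["confidence"].to_csv(out_dir / f"cell_confidence_{unit.replace(':', '_')}.tsv", sep="\t")
    if bundle["correlations"] is not None:
        bundle["correlations"].rho.to_csv(out_dir / "correlations_rho.tsv", sep="\t")
        bundle["correlations"].masked_rho().to_csv(out_dir / "correlations_masked.tsv", sep="\t")
    for name, table in bundle["venn"].items():
        table.to_csv(out_dir / f"venn_{name}.tsv", sep="\t", index=False)
    if bundle["clusters"] is not None:
        bundle["clusters"].to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    manifest = dict(bundle["manifest"])
    manifest["network_summary"] = bundle["network_summary"]
    manifest["counts_log"] = bundle["counts_log"]
    manifest["qc"] = bundle["qc"]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def report_summary(bundle: dict) -> str:
    """Human-readable run summary with deterministic ordering."""
    missing = [
        key for key in REQUIRED_TABLES
        if key not in bundle
    ]
    if missing:
        raise ValidationError(f"incomplete bundle, missing tables: {missing}")

    lines = ["# Run summary", ""]
    lines.append("## Differentially expressed genes per contrast")
    for name in sorted(bundle["de"]):
        n_sig = int(bundle["de"][name]["significant"].sum())
        lines.append(f"- {name}: {n_sig} genes")
    lines.append("")

    lines.append("## Top gene sets by |directed significance score|")
    blocks = [t for t in bundle["significance"].values()]
    if blocks:
        sig = pd.concat(blocks, ignore_index=True).dropna(subset=["directed_score"])
        sig = sig.assign(abs_score=sig["directed_score"].abs())
        sig = sig.sort_values(
            ["abs_score", "gene_set"], ascending=[False, True], kind="stable"
        ).head(10)
        for row in sig.itertuples():
            lines.append(
                f"- {row.gene_set} [{row.contrast}]: directed {row.directed_score:+.2f}"
                f" (global {row.global_score:.2f})"
            )
    lines.append("")

    lines.append("## Significant pathway-phenotype correlations")
    corr = bundle["correlations"]
    if corr is None or not corr.significant.any().any():
        lines.append("- none")
    else:
        cells = []
        for pathway in corr.rho.index:
            for endpoint in corr.rho.columns:
                if corr.significant.loc[pathway, endpoint]:
                    cells.append((pathway, endpoint, corr.rho.loc[pathway, endpoint]))
        cells.sort(key=lambda c: (-abs(c[2]), c[0], c[1]))
        for pathway, endpoint, rho in cells[:15]:
            lines.append(f"- {pathway} vs {endpoint}: rho {rho:+.2f}")
    lines.append("")

    lines.append("## Network clusters")
    summary = bundle["network_summary"]
    lines.append(
        f"- {summary['n_nodes']} nodes, {summary['n_edges']} edges, "
        f"cluster sizes {summary['cluster_sizes']}"
    )
    return "\n".join(lines) + "\n"
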