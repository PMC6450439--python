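"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a targeted immune panel experiment: a
770-endogenous / 40-housekeeping / 6-positive-control / 8-negative-control
panel, negative-binomial endogenous counts with treatment × time × tissue
effects, a strong/low responder mixture among singly-instilled treated
animals, stable housekeeping genes (plus a few planted unstable ones),
a geometric positive-control spike-in ladder, Poisson negative-control
background, and phenotype endpoints driven by a latent disease-severity
variable.  Every downstream stage can therefore be tested against known
ground truth without any external download.

Conventions
-----------
* NB parameterization: mean ``mu`` and dispersion ``alpha`` with
  ``var = mu + alpha * mu**2``.
* Effects are log2 fold changes applied to cSiO2 samples; low responders
  get the effect attenuated by ``attenuation`` (default 0.25x).
* Latent severity is 0 for vehicle samples and increases with time point
  for treated samples; phenotypes are monotone transforms of severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .io import (
    ORDINAL_ENDPOINTS,
    PERCENT_ENDPOINTS,
    CellMarkerMap,
    CountMatrix,
    EdgeList,
    GeneSetCollection,
    PanelAnnotation,
    PhenotypeTable,
    ValidationError,
    default_marker_map,
    validate_metadata,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "DEFAULT_LADDER_FM",
    "simulate_panel",
    "simulate_counts",
    "simulate_phenotypes",
    "simulate_edge_list",
    "default_design",
    "build_design",
]

#: 4-fold positive-control ladder (fM), highest first.
DEFAULT_LADDER_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

_TIME_INDEX = {"day1": 0, "W1": 1, "W5": 2, "W9": 3, "W13": 4}


@dataclass
class SimulationConfig:
    """Tunable study conditions for the count simulator.

    Defaults mirror the emulated study design: panel-scale baseline means
    (log2-normal, mean 7, sd 2 on the log2 scale), NB dispersion around 0.1,
    a 3/8 strong-responder fraction among single-instillation treated
    samples with 0.25x effect attenuation for low responders, Poisson(10)
    negative-control background, a 150 counts/fM positive ladder response,
    and mild log-normal lane-to-lane scale variation (sd 0.1 on log scale).
    """

    effects: dict[str, float] = field(default_factory=dict)  # gene -> log2 FC
    #: restrict effects to these time points (None = all time points)
    effect_time_points: tuple[str, ...] | None = None
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    dispersion_shape: float = 4.0
    dispersion_scale: float = 0.025  # gamma mean = shape*scale = 0.1
    responder_fraction: float = 3.0 / 8.0
    attenuation: float = 0.25
    lane_scale_sd: float = 0.1
    background_mean: float = 10.0
    counts_per_fm: float = 150.0
    housekeeping_dispersion: float = 0.005
    n_unstable_housekeeping: int = 2
    unstable_log2_sd: float = 1.0
    severity_per_step: float = 1.0


@dataclass
class SimulationTruth:
    """Ground truth planted by the simulator."""

    effects: pd.Series  # per endogenous gene, log2 units (0 when not DE)
    baseline_mean: pd.Series  # per gene, counts
    dispersion: pd.Series  # per gene NB alpha
    responder: pd.Series  # per sample: "high" / "low"
    severity: pd.Series  # per sample latent severity
    unstable_housekeeping: set[str] = field(default_factory=set)
    lane_scale: pd.Series | None = None

    @property
    def de_genes(self) -> set[str]:
        return set(self.effects.index[self.effects != 0])


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def simulate_panel(
    n_endogenous: int = 770,
    n_housekeeping: int = 40,
    n_positive: int = 6,
    n_negative: int = 8,
    n_sets: int = 8,
    n_cell_types: int = 13,
    seed: int = 0,
    markers_per_type: int = 2,
) -> tuple[PanelAnnotation, GeneSetCollection, CellMarkerMap]:
    """Generate a panel annotation, overlapping gene sets and a marker map.

    Positive probes carry a strictly decreasing geometric ladder of spike-in
    concentrations.  When the panel is large enough the packaged immune
    cell-type markers are embedded verbatim among the endogenous genes, so
    cell profiling runs unchanged on simulated panels; otherwise generic
    disjoint markers are assigned.
    """
    if min(n_endogenous, n_housekeeping, n_positive, n_sets, n_cell_types) < 1:
        raise ValidationError("all panel sizes must be >= 1")
    if n_negative < 2:
        raise ValidationError("need at least 2 negative probes")

    rng = np.random.default_rng(derive_seed(seed, "panel"))

    packaged = default_marker_map()
    packaged_types = list(packaged)[:n_cell_types]
    packaged_markers = [g for ct in packaged_types for g in packaged[ct]]
    use_packaged = (
        n_cell_types <= len(packaged.markers)
        and len(packaged_markers) <= n_endogenous
    )

    if use_packaged:
        marker_genes = packaged_markers
        marker_map = CellMarkerMap({ct: list(packaged[ct]) for ct in packaged_types})
    else:
        if n_cell_types * markers_per_type > n_endogenous:
            raise ValidationError(
                "n_cell_types x markers_per_type exceeds the endogenous gene count"
            )
        marker_genes = [
            f"Marker{i + 1:03d}" for i in range(n_cell_types * markers_per_type)
        ]
        marker_map = CellMarkerMap(
            {
                f"CellType{c + 1:02d}": marker_genes[
                    c * markers_per_type : (c + 1) * markers_per_type
                ]
                for c in range(n_cell_types)
            }
        )

    n_generic = n_endogenous - len(marker_genes)
    endo_genes = marker_genes + [f"Gene{i + 1:04d}" for i in range(n_generic)]
    hk_genes = [f"Hk{i + 1:02d}" for i in range(n_housekeeping)]

    rows = []
    for g in endo_genes:
        rows.append((f"ENDO_{g}", g, "endogenous", np.nan))
    for g in hk_genes:
        rows.append((f"HK_{g}", g, "housekeeping", np.nan))
    for i in range(n_positive):
        conc = (
            DEFAULT_LADDER_FM[i]
            if i < len(DEFAULT_LADDER_FM)
            else DEFAULT_LADDER_FM[-1] / 4 ** (i - len(DEFAULT_LADDER_FM) + 1)
        )
        rows.append((f"POS_{chr(65 + i)}", f"POS_{chr(65 + i)}", "positive", conc))
    for i in range(n_negative):
        rows.append((f"NEG_{chr(65 + i)}", f"NEG_{chr(65 + i)}", "negative", np.nan))

    annotation = PanelAnnotation(
        pd.DataFrame(
            rows, columns=["probe_id", "gene_symbol", "probe_class", "ladder_concentration"]
        ).set_index("probe_id")
    )

    # gene sets: contiguous blocks over a shuffled gene order, consecutive
    # blocks overlapping by ~20% so genes may belong to multiple sets
    shuffled = list(endo_genes)
    rng.shuffle(shuffled)
    block = max(1, n_endogenous // n_sets)
    overlap = max(0, block // 5)
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        start = max(0, s * block - overlap)
        stop = min(n_endogenous, (s + 1) * block)
        members = shuffled[start:stop] or shuffled[-block:]
        sets[f"Set{s + 1:02d}"] = members
    gene_sets = GeneSetCollection(sets)

    return annotation, gene_sets, marker_map


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------

def build_design(
    groups: list[tuple[str, str, str, str, int]]
) -> pd.DataFrame:
    """Build a metadata frame from (treatment, regimen, time, tissue, n) specs."""
    rows = []
    for treatment, regimen, time_point, tissue, n in groups:
        for rep in range(1, n + 1):
            sid = f"{tissue}_{treatment}_{regimen}_{time_point}_{rep:02d}"
            rows.append((sid, treatment, regimen, time_point, tissue, rep))
    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "treatment", "regimen", "time_point", "tissue", "replicate"],
    ).set_index("sample_id")
    return validate_metadata(meta)


def default_design(n_per_group: int = 8) -> pd.DataFrame:
    """The emulated study layout.

    Acute arm: single or four-weekly instillation, lung sampled 1 day after
    the final dose.  Chronic arm: four-weekly instillation, lung sampled at
    1, 5, 9 and 13 weeks, kidney and spleen at 13 weeks; each treated group
    has a dosing/time/tissue-matched vehicle group.
    """
    n = n_per_group
    groups: list[tuple[str, str, str, str, int]] = []
    for treatment in ("VEH", "cSiO2"):
        groups.append((treatment, "single", "day1", "lung", n))
        groups.append((treatment, "four_weekly", "day1", "lung", n))
        for week in ("W1", "W5", "W9", "W13"):
            groups.append((treatment, "four_weekly", week, "lung", n))
        groups.append((treatment, "four_weekly", "W13", "kidney", n))
        groups.append((treatment, "four_weekly", "W13", "spleen", n))
    return build_design(groups)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha*mu^2, via gamma-Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_mask = alpha <= 1e-12
    if poisson_mask.any():
        out[poisson_mask] = rng.poisson(mu[poisson_mask])
    nb = ~poisson_mask
    if nb.any():
        shape = 1.0 / alpha[nb]
        lam = rng.gamma(shape, alpha[nb] * mu[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_counts(
    panel: PanelAnnotation,
    design: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a raw probe × sample count matrix with planted ground truth.

    Endogenous counts are NB with mean
    ``lane_scale * baseline * 2**(effect * responder_multiplier)`` for
    treated samples (vehicle samples sit at baseline); housekeeping genes
    carry no treatment effect, except the planted unstable ones which get
    extra per-lane log-normal noise; negative probes are Poisson background;
    positive probes scale linearly with ladder concentration × lane scale.
    """
    config = config or SimulationConfig()
    if config.responder_fraction < 0 or config.responder_fraction > 1:
        raise ValidationError("responder_fraction must lie in [0, 1]")
    validate_metadata(design)
    # independent streams per component so configuration of one component
    # (e.g. the responder mixture) cannot shift the draws of another
    rng = np.random.default_rng(derive_seed(seed, "counts", "genes"))
    rng_resp = np.random.default_rng(derive_seed(seed, "counts", "responders"))
    rng_endo = np.random.default_rng(derive_seed(seed, "counts", "endogenous"))
    rng_hk = np.random.default_rng(derive_seed(seed, "counts", "housekeeping"))
    rng_ctrl = np.random.default_rng(derive_seed(seed, "counts", "controls"))

    endo_probes = panel.probes_of_class("endogenous")
    hk_probes = panel.probes_of_class("housekeeping")
    pos_probes = panel.probes_of_class("positive")
    neg_probes = panel.probes_of_class("negative")
    endo_genes = panel.table.loc[endo_probes, "gene_symbol"]
    hk_genes = panel.table.loc[hk_probes, "gene_symbol"]

    unknown = set(config.effects) - set(endo_genes)
    if unknown:
        raise ValidationError(f"effects refer to genes not in the panel: {sorted(unknown)}")

    n_samples = len(design)
    baseline = 2.0 ** rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=len(endo_genes)
    )
    dispersion = rng.gamma(
        config.dispersion_shape, config.dispersion_scale, size=len(endo_genes)
    )
    if (baseline <= 0).any() or (dispersion <= 0).any():
        raise ValidationError("baseline means and dispersions must be positive")

    effects = pd.Series(0.0, index=pd.Index(endo_genes.values, name="gene_symbol"))
    for gene, eff in config.effects.items():
        effects[gene] = float(eff)

    lane_scale = np.exp(rng.normal(0.0, config.lane_scale_sd, size=n_samples))

    # responder mixture: only single-instillation treated samples are a
    # high/low mix; repeated-instillation treated samples respond uniformly
    treated = (design["treatment"] == "cSiO2").to_numpy()
    single = (design["regimen"] == "single").to_numpy()
    responder = np.where(treated, "high", "low").astype(object)
    mix_idx = np.flatnonzero(treated & single)
    if len(mix_idx):
        n_high = int(round(config.responder_fraction * len(mix_idx)))
        high_pick = rng_resp.choice(mix_idx, size=n_high, replace=False)
        responder[mix_idx] = "low"
        responder[high_pick] = "high"
    responder = pd.Series(responder, index=design.index, name="responder")
    # vehicle samples carry no effect; label them low for bookkeeping
    responder[~treated] = "low"

    effect_mult = np.where(
        treated,
        np.where(responder.to_numpy() == "high", 1.0, config.attenuation),
        0.0,
    )
    if config.effect_time_points is not None:
        effect_mult = effect_mult * design["time_point"].isin(
            config.effect_time_points
        ).to_numpy(float)

    time_idx = design["time_point"].map(_TIME_INDEX).to_numpy()
    severity = np.where(
        treated,
        config.severity_per_step
        * (time_idx + 1)
        * np.where(responder.to_numpy() == "high", 1.0, config.attenuation),
        0.0,
    )

    counts = np.zeros((len(panel), n_samples), dtype=np.int64)
    probe_pos = {p: i for i, p in enumerate(panel.probe_ids)}

    # endogenous
    endo_rows = np.array([probe_pos[p] for p in endo_probes])
    mu = (
        baseline[:, None]
        * 2.0 ** (effects.to_numpy()[:, None] * effect_mult[None, :])
        * lane_scale[None, :]
    )
    counts[endo_rows, :] = _nb_draw(rng_endo, mu, dispersion[:, None])

    # housekeeping: stable baseline, no treatment effect; planted unstable
    # genes get extra multiplicative log-normal noise per lane
    hk_rows = np.array([probe_pos[p] for p in hk_probes])
    hk_baseline = 2.0 ** rng_hk.normal(8.0, 0.5, size=len(hk_probes))
    n_unstable = min(config.n_unstable_housekeeping, len(hk_probes))
    unstable_pick = rng_hk.choice(len(hk_probes), size=n_unstable, replace=False)
    hk_mu = hk_baseline[:, None] * lane_scale[None, :]
    if n_unstable:
        noise = 2.0 ** rng_hk.normal(
            0.0, config.unstable_log2_sd, size=(n_unstable, n_samples)
        )
        hk_mu[unstable_pick, :] *= noise
    counts[hk_rows, :] = _nb_draw(
        rng_hk, hk_mu, np.full((len(hk_probes), 1), config.housekeeping_dispersion)
    )
    unstable_housekeeping = set(hk_genes.iloc[unstable_pick])

    # positive ladder: linear in concentration x lane scale
    if len(pos_probes):
        pos_rows = np.array([probe_pos[p] for p in pos_probes])
        conc = panel.table.loc[pos_probes, "ladder_concentration"].to_numpy(float)
        pos_mu = config.counts_per_fm * conc[:, None] * lane_scale[None, :]
        counts[pos_rows, :] = rng_ctrl.poisson(pos_mu)

    # negative background
    if len(neg_probes):
        neg_rows = np.array([probe_pos[p] for p in neg_probes])
        counts[neg_rows, :] = rng_ctrl.poisson(
            config.background_mean, size=(len(neg_probes), n_samples)
        )

    matrix = CountMatrix(
        pd.DataFrame(counts, index=panel.probe_ids, columns=design.index),
        design,
        stage="raw",
    )
    truth = SimulationTruth(
        effects=effects,
        baseline_mean=pd.Series(baseline, index=effects.index),
        dispersion=pd.Series(dispersion, index=effects.index),
        responder=responder,
        severity=pd.Series(severity, index=design.index, name="severity"),
        unstable_housekeeping=unstable_housekeeping,
        lane_scale=pd.Series(lane_scale, index=design.index, name="lane_scale"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    design: pd.DataFrame,
    truth: SimulationTruth,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> PhenotypeTable:
    """Phenotype endpoints as monotone transforms of latent severity.

    Ordinal lesion scores are a discretized linear ramp in severity (clipped
    to 0..4); percent-positive staining endpoints are a logistic transform
    of severity scaled to 0–100.  ``noise_sd`` adds Gaussian noise on the
    latent scale before the transform.
    """
    missing = design.index.difference(truth.severity.index)
    if len(missing):
        raise ValidationError(f"no latent severity for samples: {missing.tolist()}")
    rng = np.random.default_rng(derive_seed(seed, "phenotypes"))
    severity = truth.severity.loc[design.index].to_numpy(float)
    max_sev = max(severity.max(), 1e-12)

    data: dict[str, np.ndarray] = {}
    for i, name in enumerate(ORDINAL_ENDPOINTS):
        latent = severity + rng.normal(0.0, noise_sd, size=len(severity))
        # floor() so zero severity maps to score 0
        score = np.clip(np.floor(latent * 4.0 / max_sev), 0, 4)
        data[name] = score
    for name in PERCENT_ENDPOINTS:
        latent = severity + rng.normal(0.0, noise_sd, size=len(severity))
        pct = 100.0 / (1.0 + np.exp(-(latent - max_sev / 2.0)))
        data[name] = np.clip(pct, 0.0, 100.0)
    return PhenotypeTable(pd.DataFrame(data, index=design.index))


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def simulate_edge_list(
    gene_symbols: list[str],
    n_modules: int = 3,
    within_score: tuple[float, float] = (0.75, 0.95),
    between_score: tuple[float, float] = (0.2, 0.5),
    between_density: float = 0.1,
    seed: int = 0,
) -> tuple[EdgeList, list[set[str]]]:
    """Planted-module interaction graph.

    Genes are split into ``n_modules`` equal-ish modules; all within-module
    pairs get scores from ``within_score`` (>= 0.7 by default) and a
    ``between_density`` fraction of cross-module pairs get scores from
    ``between_score`` (< 0.7 by default), so the canonical >=0.7 filter
    separates the planted modules exactly.  Returns the edge list and the
    planted module memberships.
    """
    if n_modules < 1:
        raise ValidationError("n_modules must be >= 1")
    if len(gene_symbols) < n_modules:
        raise ValidationError("fewer genes than modules")
    rng = np.random.default_rng(derive_seed(seed, "edges"))
    genes = list(gene_symbols)
    assignments = np.sort(np.arange(len(genes)) % n_modules)
    modules = [set() for _ in range(n_modules)]
    for g, m in zip(genes, assignments):
        modules[m].add(g)

    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if assignments[i] == assignments[j]:
                rows.append((a, b, rng.uniform(*within_score)))
            elif rng.random() < between_density:
                rows.append((a, b, rng.uniform(*between_score)))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
    return EdgeList(edges), modules
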