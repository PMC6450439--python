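"""Background handling, control normalization and geNorm reference selection.

The QC/normalization chain for digital-barcode panel counts:

1. **Background model** — pool the negative-control probe counts across all
   lanes; the exclusion threshold is ``mean + 2·sd`` (sample sd, n−1).
2. **Background subtraction** — subtract the mean background from every
   endogenous and housekeeping count, flooring at zero.
3. **Low-expression flagging** — a gene whose mean raw count across the
   analysis unit's samples falls strictly below the threshold is excluded
   from differential expression and scoring.
4. **Positive-control normalization** — per-lane factor equal to the grand
   arithmetic mean of lane geometric means of the spike-in positive probes,
   divided by the lane's own geometric mean.
5. **geNorm housekeeping selection** — stability measure M (mean pairwise
   sd of log2 ratios), iterative removal of the least stable gene, and the
   pairwise-variation V statistic to pick how many references to keep.
6. **Housekeeping normalization** — same geometric-mean factor construction
   over the selected reference genes, computed on the positive-normalized
   counts, so lane geometric means of the selected references end up equal.

:class:`PanelNormalizer` wraps the chain as a scikit-learn style
fit/transform estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import safe_log2
from .io import CountMatrix, PanelAnnotation, ValidationError

__all__ = [
    "BackgroundModel",
    "StabilityResult",
    "NormalizationFactors",
    "fit_background",
    "subtract_background",
    "flag_low_expression",
    "positive_control_factors",
    "genorm_stability",
    "normalize",
    "PanelNormalizer",
]

logger = logging.getLogger(__name__)


@dataclass
class BackgroundModel:
    """Pooled negative-control background: mean, sd and 2σ threshold."""

    mean_background: float
    sd_background: float
    sigma_multiplier: float = 2.0
    excluded_genes: set[str] = field(default_factory=set)

    @property
    def threshold(self) -> float:
        return self.mean_background + self.sigma_multiplier * self.sd_background


@dataclass
class StabilityResult:
    """geNorm output: per-gene M, removal order, V statistics, selection."""

    m_values: pd.Series  # initial stability M per candidate gene
    removal_order: list[str]  # least stable first
    v_values: pd.Series  # V_{k,k+1} indexed by k
    selected: list[str]  # chosen reference genes, most stable first
    ranked: list[str]  # all candidates, most stable first


@dataclass
class NormalizationFactors:
    positive: pd.Series  # per-sample positive-control factor
    housekeeping: pd.Series  # per-sample housekeeping factor

    def __post_init__(self) -> None:
        for factors in (self.positive, self.housekeeping):
            if (factors <= 0).any():
                raise ValidationError("normalization factors must be positive")

    @property
    def combined(self) -> pd.Series:
        return self.positive * self.housekeeping


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def fit_background(
    negative_counts: pd.DataFrame | np.ndarray, sigma_multiplier: float = 2.0
) -> BackgroundModel:
    """Fit the background model from negative-probe counts pooled over lanes.

    ``negative_counts`` is the negative probes × samples block of the raw
    matrix (or any array of pooled negative observations).
    """
    values = np.asarray(negative_counts, dtype=float).ravel()
    if values.size < 2:
        raise ValidationError("need at least 2 negative-probe observations")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return BackgroundModel(mean, sd, sigma_multiplier)


def subtract_background(
    matrix: CountMatrix, annotation: PanelAnnotation, background: BackgroundModel
) -> CountMatrix:
    """Subtract mean background from endogenous/housekeeping counts, floor 0.

    Positive and negative control probes are left untouched.
    """
    if matrix.stage != "raw":
        raise ValidationError(f"expected stage 'raw', got {matrix.stage!r}")
    counts = matrix.counts.astype(float).copy()
    target = annotation.probes_of_class("endogenous").union(
        annotation.probes_of_class("housekeeping"), sort=False
    )
    target = counts.index.intersection(target)
    counts.loc[target] = (counts.loc[target] - background.mean_background).clip(lower=0)
    return matrix.with_counts(counts, stage="background_subtracted")


def flag_low_expression(
    matrix: CountMatrix, annotation: PanelAnnotation, background: BackgroundModel
) -> set[str]:
    """Genes whose mean raw count across the unit's samples is below 2σ.

    The comparison is strict (<), so a gene sitting exactly on the threshold
    is retained.  Returns gene symbols of excluded endogenous genes.
    """
    endo = annotation.probes_of_class("endogenous")
    endo = matrix.counts.index.intersection(endo)
    means = matrix.counts.loc[endo].mean(axis=1)
    excluded_probes = means.index[means < background.threshold]
    return set(annotation.table.loc[excluded_probes, "gene_symbol"])


# ---------------------------------------------------------------------------
# factors
# ---------------------------------------------------------------------------

def _lane_factors(block: pd.DataFrame, what: str) -> pd.Series:
    """Grand mean of lane geometric means over each lane's geometric mean."""
    values = block.to_numpy(float)
    if (values <= 0).any() and what == "positive":
        raise ValidationError("zero positive-control count: geometric mean undefined")
    if (values <= 0).any():
        logger.warning("zero %s counts; applying the +0.5 pseudocount rule", what)
    lane_geomeans = 2.0 ** safe_log2(values).mean(axis=0)
    factors = lane_geomeans.mean() / lane_geomeans
    return pd.Series(factors, index=block.columns)


def positive_control_factors(
    matrix: CountMatrix, annotation: PanelAnnotation
) -> pd.Series:
    """Per-lane positive-control normalization factors."""
    pos = matrix.counts.index.intersection(annotation.probes_of_class("positive"))
    if len(pos) == 0:
        raise ValidationError("no positive-control probes in the matrix")
    return _lane_factors(matrix.counts.loc[pos], "positive")


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _stability_m(log_expr: pd.DataFrame) -> pd.Series:
    """geNorm M: mean over other genes of sd of pairwise log2 ratios.

    ``log_expr`` is genes × samples on the log2 scale.
    """
    genes = log_expr.index
    values = log_expr.to_numpy(float)
    n = len(genes)
    m = np.zeros(n)
    for j in range(n):
        diffs = values[j][None, :] - values  # all pairwise log-ratios
        sds = np.std(np.delete(diffs, j, axis=0), axis=1, ddof=1)
        m[j] = sds.mean()
    return pd.Series(m, index=genes)


def genorm_stability(
    log_expr: pd.DataFrame, v_cutoff: float = 0.15, min_selected: int = 3
) -> StabilityResult:
    """Rank housekeeping candidates by geNorm stability and choose a set.

    ``log_expr`` is candidate genes × samples, log2 scale.  The least stable
    gene (highest M, ties broken lexicographically by gene symbol) is
    removed iteratively until two remain.  Pairwise variation
    ``V_{k,k+1}`` — the sd across samples of the log2 ratio of geometric-mean
    normalization factors built from the top k vs top k+1 genes — selects
    the smallest ``k >= min_selected`` with V below ``v_cutoff`` (falling
    back to the k with minimal V).
    """
    if len(log_expr) < 3:
        raise ValidationError("geNorm needs at least 3 candidate genes")
    if log_expr.shape[1] < 2:
        raise ValidationError("geNorm needs at least 2 samples")

    m_initial = _stability_m(log_expr)
    removal_order: list[str] = []
    remaining = log_expr.copy()
    while len(remaining) > 2:
        m = _stability_m(remaining)
        # highest M removed first; lexicographic tie-break for determinism
        worst = sorted(m.index[m == m.max()])[0]
        removal_order.append(worst)
        remaining = remaining.drop(index=worst)
    # final two are mutually indistinguishable by M; order lexicographically
    ranked = sorted(remaining.index) + removal_order[::-1]

    n = len(log_expr)
    v_values = {}
    for k in range(2, n):
        top_k = ranked[:k]
        top_k1 = ranked[: k + 1]
        nf_k = log_expr.loc[top_k].mean(axis=0)
        nf_k1 = log_expr.loc[top_k1].mean(axis=0)
        v_values[k] = float(np.std(nf_k - nf_k1, ddof=1))
    v_series = pd.Series(v_values, name="V")

    selected_k = None
    for k in sorted(v_series.index):
        if k >= min_selected and v_series[k] < v_cutoff:
            selected_k = k
            break
    if selected_k is None:
        eligible = v_series[v_series.index >= min_selected]
        pool = eligible if len(eligible) else v_series
        selected_k = int(pool.idxmin())
    selected = ranked[:selected_k]

    return StabilityResult(
        m_values=m_initial,
        removal_order=removal_order,
        v_values=v_series,
        selected=selected,
        ranked=ranked,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    matrix: CountMatrix,
    annotation: PanelAnnotation,
    selected_housekeeping: list[str],
    factors_out: dict | None = None,
) -> CountMatrix:
    """Positive-control then housekeeping normalization of subtracted counts.

    Lane counts are multiplied by the positive-control factor, then by the
    housekeeping factor computed from the selected reference genes on the
    positive-normalized counts.  After this the per-lane geometric means of
    the selected housekeeping genes are equal across lanes.
    """
    if matrix.stage != "background_subtracted":
        raise ValidationError(
            f"expected stage 'background_subtracted', got {matrix.stage!r}"
        )
    if not selected_housekeeping:
        raise ValidationError("selected housekeeping set is empty")

    pos_factors = positive_control_factors(matrix, annotation)
    counts = matrix.counts.mul(pos_factors, axis=1)

    hk_table = annotation.table[annotation.table["probe_class"] == "housekeeping"]
    hk_probes = hk_table.index[hk_table["gene_symbol"].isin(selected_housekeeping)]
    missing = set(selected_housekeeping) - set(hk_table["gene_symbol"])
    if missing:
        raise ValidationError(f"not housekeeping genes in this panel: {sorted(missing)}")
    hk_factors = _lane_factors(counts.loc[hk_probes], "housekeeping")
    counts = counts.mul(hk_factors, axis=1)

    if factors_out is not None:
        factors_out["factors"] = NormalizationFactors(pos_factors, hk_factors)
    return matrix.with_counts(counts, stage="normalized")


class PanelNormalizer(BaseEstimator):
    """Fit/transform wrapper around the full QC + normalization chain.

    Parameters
    ----------
    sigma_multiplier : float, default 2.0
        Multiplier on the pooled negative-control sd for the exclusion
        threshold.
    v_cutoff : float, default 0.15
        geNorm pairwise-variation cutoff for choosing the reference count.
    min_housekeeping : int, default 3
        Smallest admissible number of selected reference genes.

    Attributes (after :meth:`fit`)
    ------------------------------
    background_ : BackgroundModel
    stability_ : StabilityResult
    selected_housekeeping_ : list of gene symbols
    excluded_genes_ : set of low-expression gene symbols
    factors_ : NormalizationFactors (after :meth:`transform`)
    """

    def __init__(
        self,
        sigma_multiplier: float = 2.0,
        v_cutoff: float = 0.15,
        min_housekeeping: int = 3,
    ):
        self.sigma_multiplier = sigma_multiplier
        self.v_cutoff = v_cutoff
        self.min_housekeeping = min_housekeeping

    def fit(self, matrix: CountMatrix, annotation: PanelAnnotation) -> "PanelNormalizer":
        neg = matrix.counts.loc[
            matrix.counts.index.intersection(annotation.probes_of_class("negative"))
        ]
        self.background_ = fit_background(neg, self.sigma_multiplier)
        self.excluded_genes_ = flag_low_expression(matrix, annotation, self.background_)
        self.background_.excluded_genes = self.excluded_genes_

        subtracted = subtract_background(matrix, annotation, self.background_)
        pos_factors = positive_control_factors(subtracted, annotation)
        hk_probes = annotation.probes_of_class("housekeeping")
        hk_block = subtracted.counts.loc[hk_probes].mul(pos_factors, axis=1)
        hk_log = pd.DataFrame(
            safe_log2(hk_block.to_numpy()),
            index=annotation.table.loc[hk_probes, "gene_symbol"].to_numpy(),
            columns=hk_block.columns,
        )
        self.stability_ = genorm_stability(
            hk_log, v_cutoff=self.v_cutoff, min_selected=self.min_housekeeping
        )
        self.selected_housekeeping_ = list(self.stability_.selected)
        self._annotation = annotation
        return self

    def transform(self, matrix: CountMatrix) -> CountMatrix:
        if not hasattr(self, "background_"):
            raise ValidationError("PanelNormalizer is not fitted")
        subtracted = subtract_background(matrix, self._annotation, self.background_)
        out: dict = {}
        normalized = normalize(
            subtracted, self._annotation, self.selected_housekeeping_, factors_out=out
        )
        self.factors_ = out["factors"]
        return normalized

    def fit_transform(
        self, matrix: CountMatrix, annotation: PanelAnnotation
    ) -> CountMatrix:
        return self.fit(matrix, annotation).transform(matrix)

    def qc_report(self) -> dict:
        """JSON-serializable QC summary of the fitted normalization."""
        return {
            "background": {
                "mean": self.background_.mean_background,
                "sd": self.background_.sd_background,
                "threshold": self.background_.threshold,
            },
            "excluded_genes": sorted(self.excluded_genes_),
            "housekeeping": {
                "m_values": self.stability_.m_values.round(6).to_dict(),
                "removal_order": self.stability_.removal_order,
                "v_values": {str(k): round(v, 6) for k, v in self.stability_.v_values.items()},
                "selected": self.selected_housekeeping_,
            },
        }
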