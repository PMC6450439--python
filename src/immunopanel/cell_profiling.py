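"""Marker-gene immune cell-type scores, confidence p-values, group tests.

A cell type's per-sample score is the mean log2 normalized expression of
its marker genes — a *relative* abundance proxy: scores may be compared
within a cell type across groups, never across cell types, so outputs are
laid out one table per cell type.

For types with >= 2 markers a confidence p-value tests whether the markers
co-vary across samples (mean pairwise Pearson correlation > 0 under a
seeded permutation null that shuffles each marker's samples
independently).  All cell types are reported regardless of confidence.
Group comparisons use the two-sided Wilcoxon rank-sum test, exact for
small samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import derive_seed, safe_log2
from .io import CellMarkerMap, CountMatrix, PanelAnnotation, ValidationError

__all__ = [
    "cell_score",
    "marker_confidence",
    "wilcoxon_rank_sum",
    "compare_groups",
    "CellTypeScorer",
]

logger = logging.getLogger(__name__)


def _mean_pairwise_correlation(values: np.ndarray) -> float:
    """Mean Pearson correlation over all marker pairs (markers × samples)."""
    z = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    if (norms > 0).sum() < 2:
        return float("nan")
    norms[norms == 0] = np.nan
    z = z / norms[:, None]
    corr = z @ z.T
    iu = np.triu_indices(len(values), k=1)
    return float(np.nanmean(corr[iu]))


def marker_confidence(
    log_expr: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided permutation p for positive average marker co-expression.

    ``log_expr`` is markers × samples (log2 scale).  Each permutation
    shuffles every marker's sample order independently, destroying
    cross-marker correlation while preserving marginals; the p-value is
    ``(1 + #{perm stat >= observed}) / (n_permutations + 1)``.
    """
    if len(log_expr) < 2:
        raise ValidationError("marker confidence needs >= 2 markers")
    if log_expr.shape[1] < 4:
        raise ValidationError("marker confidence needs >= 4 samples")
    values = log_expr.to_numpy(float)
    observed = _mean_pairwise_correlation(values)
    if np.isnan(observed):
        return 1.0

    rng = np.random.default_rng(derive_seed(seed, "marker_confidence"))
    n_markers, n_samples = values.shape
    # pre-z-score once; permuting rows of the z-scored matrix is equivalent
    z = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    if (norms == 0).any():
        z = z[norms > 0]
        n_markers = len(z)
        if n_markers < 2:
            return 1.0
        norms = norms[norms > 0]
    z = z / norms[:, None]

    iu = np.triu_indices(n_markers, k=1)
    hits = 0
    chunk = max(1, min(n_permutations, 2_000_000 // (n_markers * n_samples)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # independent row permutations via argsort of random keys
        order = np.argsort(rng.random((b, n_markers, n_samples)), axis=2)
        perm = np.take_along_axis(
            np.broadcast_to(z, (b, n_markers, n_samples)), order, axis=2
        )
        gram = perm @ perm.transpose(0, 2, 1)
        stat = gram[:, iu[0], iu[1]].mean(axis=1)
        hits += int(np.sum(stat >= observed - 1e-12))
        done += b
    return (1 + hits) / (n_permutations + 1)


def cell_score(
    matrix: CountMatrix,
    annotation: PanelAnnotation,
    marker_map: CellMarkerMap,
    exclude_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Samples × cell types score matrix (mean log2 marker expression)."""
    if matrix.stage != "normalized":
        raise ValidationError("cell scores expect normalized counts")
    endo = matrix.counts.index.intersection(annotation.probes_of_class("endogenous"))
    log_expr = pd.DataFrame(
        safe_log2(matrix.counts.loc[endo].to_numpy()),
        index=annotation.table.loc[endo, "gene_symbol"].to_numpy(),
        columns=matrix.counts.columns,
    )
    exclude_genes = exclude_genes or set()

    scores = {}
    for cell_type, markers in marker_map.items():
        usable = [g for g in markers if g in log_expr.index and g not in exclude_genes]
        if not usable:
            logger.warning("all markers excluded for %r; score missing", cell_type)
            scores[cell_type] = pd.Series(np.nan, index=log_expr.columns)
            continue
        scores[cell_type] = log_expr.loc[usable].mean(axis=0)
    return pd.DataFrame(scores).rename_axis("sample_id")


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> float:
    """Two-sided rank-sum p: exact enumeration for small n, else normal
    approximation with continuity correction.  All-tied data gives p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need >= 2 samples per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def compare_groups(
    scores: pd.DataFrame,
    case_samples: list[str],
    reference_samples: list[str],
) -> pd.DataFrame:
    """Per-cell-type Wilcoxon comparison of case vs reference scores.

    Returns one row per cell type with the two-sided p, the direction
    (sign of the median difference) and the group sizes.
    """
    rows = {}
    for cell_type in scores.columns:
        x = scores.loc[case_samples, cell_type].dropna()
        y = scores.loc[reference_samples, cell_type].dropna()
        if len(x) < 2 or len(y) < 2:
            rows[cell_type] = (np.nan, 0, len(x), len(y))
            continue
        p = wilcoxon_rank_sum(x, y)
        direction = int(np.sign(np.median(x) - np.median(y)))
        rows[cell_type] = (p, direction, len(x), len(y))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["p", "direction", "n_case", "n_reference"]
    ).rename_axis("cell_type")


class CellTypeScorer(BaseEstimator):
    """Estimator wrapper: scores + marker-confidence p-values.

    Parameters
    ----------
    marker_map : CellMarkerMap
    n_permutations : int, default 10000
        Permutations for the multi-marker confidence test.
    random_state : int, default 0

    Attributes
    ----------
    scores_ : DataFrame, samples × cell types.
    confidence_ : Series of confidence p per multi-marker cell type
        (single-marker types are absent, not NaN).
    """

    def __init__(
        self,
        marker_map: CellMarkerMap,
        n_permutations: int = 10_000,
        random_state: int = 0,
    ):
        self.marker_map = marker_map
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit_transform(
        self,
        matrix: CountMatrix,
        annotation: PanelAnnotation,
        exclude_genes: set[str] | None = None,
    ) -> pd.DataFrame:
        self.scores_ = cell_score(matrix, annotation, self.marker_map, exclude_genes)

        endo = matrix.counts.index.intersection(annotation.probes_of_class("endogenous"))
        log_expr = pd.DataFrame(
            safe_log2(matrix.counts.loc[endo].to_numpy()),
            index=annotation.table.loc[endo, "gene_symbol"].to_numpy(),
            columns=matrix.counts.columns,
        )
        confidence = {}
        for cell_type, markers in self.marker_map.items():
            usable = [g for g in markers if g in log_expr.index]
            if len(usable) < 2:
                continue  # confidence defined for multi-marker types only
            confidence[cell_type] = marker_confidence(
                log_expr.loc[usable],
                n_permutations=self.n_permutations,
                seed=self.random_state,
            )
        self.confidence_ = pd.Series(confidence, name="confidence_p", dtype=float)
        return self.scores_
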