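"""Pathway–phenotype correlation screen and multivariate summaries.

* :func:`spearman_screen` — Spearman ρ of per-sample pathway Z-scores
  against each phenotype endpoint; a correlation is called significant when
  ρ > 0.5 or ρ < −0.5 *and* p < 0.05 (both conditions required).
  Non-significant cells are masked in the export, constant endpoints give
  an undefined (masked) ρ.
* :func:`hierarchical_cluster` — agglomerative clustering with Euclidean
  distance and average (UPGMA) linkage, with a deterministic leaf order.
* :func:`pca_summary` — PC1/PC2 sample coordinates with per-group 95%
  confidence ellipses from the bivariate normal quantile.
* :func:`venn_overlaps` — exact region cardinalities for 2–5 named sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import PhenotypeTable, ValidationError

__all__ = [
    "CorrelationResult",
    "spearman_screen",
    "hierarchical_cluster",
    "pca_summary",
    "venn_overlaps",
]

RHO_THRESHOLD = 0.5
P_THRESHOLD = 0.05


@dataclass
class CorrelationResult:
    """Pathway × endpoint Spearman screen with the joint significance rule."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame

    def masked_rho(self) -> pd.DataFrame:
        """ρ with non-significant cells blanked (NaN), the figure convention."""
        return self.rho.where(self.significant)


def spearman_screen(
    pathway_scores: pd.DataFrame,
    phenotypes: PhenotypeTable,
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> CorrelationResult:
    """Spearman ρ of each pathway's per-sample Z-score vs each endpoint.

    ``pathway_scores`` is sets × samples.  Pairing is on the sample ids
    common to both tables; each pathway × endpoint cell needs >= 4 paired
    samples.  Average ranks handle ties; p is the two-sided t
    approximation.
    """
    shared = pathway_scores.columns.intersection(phenotypes.table.index)
    if len(shared) < 4:
        raise ValidationError("need >= 4 paired samples for the Spearman screen")
    scores = pathway_scores[shared]
    pheno = phenotypes.table.loc[shared]

    rho = pd.DataFrame(index=scores.index, columns=pheno.columns, dtype=float)
    p = pd.DataFrame(index=scores.index, columns=pheno.columns, dtype=float)
    for endpoint in pheno.columns:
        y = pheno[endpoint].to_numpy(float)
        if np.all(y == y[0]):
            continue  # constant endpoint: rho undefined, left masked
        for pathway in scores.index:
            x = scores.loc[pathway].to_numpy(float)
            if np.all(x == x[0]):
                continue
            res = stats.spearmanr(x, y)
            rho.loc[pathway, endpoint] = res.statistic
            p.loc[pathway, endpoint] = res.pvalue
    significant = (rho.abs() > rho_threshold) & (p < p_threshold)
    significant = significant.fillna(False)
    return CorrelationResult(rho=rho, p=p, significant=significant)


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: int = 0
) -> tuple[np.ndarray, list]:
    """UPGMA (average linkage, Euclidean) over rows (axis=0) or columns.

    Returns the scipy linkage matrix and the ordered leaf labels.  Raises
    on NaN entries, naming the offending rows/columns.
    """
    data = matrix if axis == 0 else matrix.T
    if len(data) < 2:
        raise ValidationError("need >= 2 items to cluster")
    values = data.to_numpy(float)
    if np.isnan(values).any():
        bad = data.index[np.isnan(values).any(axis=1)].tolist()
        raise ValidationError(f"NaN entries in items: {bad}")
    linkage = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [data.index[i] for i in leaves]


def pca_summary(
    matrix: pd.DataFrame,
    grouping: pd.Series | None = None,
    scale: bool = True,
    confidence: float = 0.95,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """PC1/PC2 coordinates with variance explained and group ellipses.

    ``matrix`` is samples × variables.  Columns are centered and (by
    default) scaled to unit variance; constant columns are dropped.  The
    component sign is oriented so the mean loading is positive.  Ellipses
    are parameterized by each group's 2-D coordinate covariance at the
    bivariate-normal ``confidence`` quantile: center, semi-axes, angle
    (radians).
    """
    if len(matrix) < 3:
        raise ValidationError("PCA summary needs >= 3 samples")
    if matrix.shape[1] < 2:
        raise ValidationError("PCA summary needs >= 2 variables")
    values = matrix.to_numpy(float)
    values = values - values.mean(axis=0, keepdims=True)
    if scale:
        sd = values.std(axis=0, ddof=1)
        keep = sd > 0
        values = values[:, keep] / sd[keep]
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    n_pc = min(2, len(s))
    coords = u[:, :n_pc] * s[:n_pc]
    for j in range(n_pc):
        orient = np.sign(vt[j].mean())
        if orient == 0:
            orient = 1.0
        coords[:, j] *= orient
    explained = s**2 / np.sum(s**2)
    coord_frame = pd.DataFrame(
        coords, index=matrix.index, columns=[f"PC{i + 1}" for i in range(n_pc)]
    )
    explained_series = pd.Series(
        explained[:n_pc], index=coord_frame.columns, name="variance_explained"
    )

    ellipses: dict = {}
    if grouping is not None and n_pc == 2:
        quantile = stats.chi2.ppf(confidence, df=2)
        for group, members in coord_frame.groupby(grouping.loc[matrix.index]):
            if len(members) < 3:
                continue
            cov = np.cov(members.to_numpy().T)
            eigvals, eigvecs = np.linalg.eigh(cov)
            order = np.argsort(eigvals)[::-1]
            eigvals, eigvecs = eigvals[order], eigvecs[:, order]
            ellipses[group] = {
                "center": members.mean(axis=0).tolist(),
                "semi_axes": np.sqrt(np.maximum(eigvals, 0) * quantile).tolist(),
                "angle": float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])),
                "n": len(members),
            }
    return coord_frame, explained_series, ellipses


def venn_overlaps(named_sets: dict[str, set]) -> pd.DataFrame:
    """Exact cardinality (and members) of every intersection region.

    Supports 2–5 sets.  Regions are encoded by membership flags; the region
    cardinalities sum to the size of the union.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValidationError("need >= 2 sets for overlaps")
    if len(names) > 5:
        raise ValidationError("more than 5 sets is unsupported")
    sets = {name: set(named_sets[name]) for name in names}

    rows = []
    for flags in itertools.product([True, False], repeat=len(names)):
        if not any(flags):
            continue
        members = None
        for name, flag in zip(names, flags):
            if flag:
                members = sets[name] if members is None else members & sets[name]
        for name, flag in zip(names, flags):
            if not flag:
                members = members - sets[name]
        rows.append(
            {
                **{name: flag for name, flag in zip(names, flags)},
                "count": len(members),
                "members": sorted(members),
            }
        )
    return pd.DataFrame(rows)
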