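"""Gene-set significance scores and per-sample pathway Z-scores.

For a set of G genes with per-gene differential-expression t statistics:

* global significance = sqrt( mean(t_i^2) ) — cumulative evidence that the
  set's genes move, regardless of direction;
* directed significance = sign(s)·sqrt(|s|) with s = mean(sign(t_i)·t_i^2)
  — reduces to ±global when all t share a sign and to 0 under perfect
  cancellation, so a near-zero directed score with a large global score
  flags a set with strong but opposing regulation.

The per-sample pathway score is the first principal component of the set
genes' normalized log2 expression: genes are Z-scaled across samples,
PC1 sample scores are extracted and Z-scaled again, and the component sign
is oriented so the mean gene loading is positive (higher score = higher
average pathway expression).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import safe_log2
from .io import CountMatrix, GeneSetCollection, PanelAnnotation, ValidationError

__all__ = [
    "global_significance",
    "directed_significance",
    "pathway_z",
    "PathwayScorer",
    "score_all_sets",
]

logger = logging.getLogger(__name__)


def global_significance(t_values) -> float:
    """Root-mean-square of the set's t statistics."""
    t = np.asarray(t_values, dtype=float)
    if t.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(t**2)))


def directed_significance(t_values) -> float:
    """Signed root of the signed mean of signed squared t statistics."""
    t = np.asarray(t_values, dtype=float)
    if t.size == 0:
        return float("nan")
    s = np.mean(np.sign(t) * t**2)
    return float(np.sign(s) * np.sqrt(abs(s)))


def _zscale(values: np.ndarray, axis: int, ddof: int = 1) -> np.ndarray:
    mean = values.mean(axis=axis, keepdims=True)
    sd = values.std(axis=axis, ddof=ddof, keepdims=True)
    return (values - mean) / sd


def pathway_z(log_expr: pd.DataFrame) -> pd.Series | None:
    """Per-sample pathway score: Z-scaled PC1 of Z-scaled member expression.

    ``log_expr`` is set genes × samples on the log2 scale.  Zero-variance
    genes are dropped (logged); returns None when no gene varies.  The PC1
    sign is oriented so the mean gene loading is positive.
    """
    if log_expr.shape[1] < 3:
        raise ValidationError("pathway scores need at least 3 samples")
    values = log_expr.to_numpy(float)
    sds = values.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.any():
        return None
    if not keep.all():
        dropped = list(log_expr.index[~keep])
        logger.info("dropping zero-variance pathway genes: %s", dropped)
        values = values[keep]

    z = _zscale(values, axis=1)  # genes x samples, each gene mean 0 sd 1
    # PC1 of the samples-by-genes matrix
    u, s, vt = np.linalg.svd(z.T - z.T.mean(axis=0, keepdims=True), full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    orient = np.sign(loadings.mean()) or np.sign(loadings[np.argmax(np.abs(loadings))]) or 1.0
    scores = scores * orient
    scores = _zscale(scores, axis=0)
    return pd.Series(scores, index=log_expr.columns, name="pathway_z")


class PathwayScorer(BaseEstimator):
    """Scores every gene set against DE results and normalized expression.

    Parameters
    ----------
    gene_sets : GeneSetCollection
        Named sets of gene symbols; a gene belonging to several sets is
        scored independently in each.

    Attributes
    ----------
    significance_ : DataFrame (set × {global_score, directed_score, n_genes})
        per contrast, after :meth:`score_significance`.
    pathway_z_ : DataFrame (set × samples), after :meth:`transform`.
    """

    def __init__(self, gene_sets: GeneSetCollection):
        self.gene_sets = gene_sets

    def score_significance(self, de_results: pd.DataFrame) -> pd.DataFrame:
        """Global/directed significance per set from a per-gene DE table."""
        rows = {}
        for name, members in self.gene_sets.items():
            t = de_results.loc[de_results.index.intersection(members), "t"]
            t = t[np.isfinite(t)]
            if len(t) == 0:
                logger.warning("gene set %r has no scored panel genes", name)
                rows[name] = (np.nan, np.nan, 0)
                continue
            rows[name] = (global_significance(t), directed_significance(t), len(t))
        self.significance_ = pd.DataFrame.from_dict(
            rows, orient="index", columns=["global_score", "directed_score", "n_genes"]
        ).rename_axis("gene_set")
        return self.significance_

    def transform(
        self,
        matrix: CountMatrix,
        annotation: PanelAnnotation,
        exclude_genes: set[str] | None = None,
    ) -> pd.DataFrame:
        """Per-sample pathway Z matrix (sets × samples)."""
        if matrix.stage != "normalized":
            raise ValidationError("pathway scores expect normalized counts")
        endo = matrix.counts.index.intersection(annotation.probes_of_class("endogenous"))
        log_expr = pd.DataFrame(
            safe_log2(matrix.counts.loc[endo].to_numpy()),
            index=annotation.table.loc[endo, "gene_symbol"].to_numpy(),
            columns=matrix.counts.columns,
        )
        if exclude_genes:
            log_expr = log_expr.loc[[g for g in log_expr.index if g not in exclude_genes]]

        rows = {}
        for name, members in self.gene_sets.items():
            block = log_expr.loc[log_expr.index.intersection(members)]
            if block.empty:
                logger.warning("gene set %r has no panel genes; skipped", name)
                continue
            z = pathway_z(block)
            if z is None:
                logger.warning("gene set %r has no varying genes; skipped", name)
                continue
            rows[name] = z
        self.pathway_z_ = pd.DataFrame(rows).T.rename_axis("gene_set")
        return self.pathway_z_


def score_all_sets(
    de_results: dict[str, pd.DataFrame],
    matrix: CountMatrix,
    annotation: PanelAnnotation,
    gene_sets: GeneSetCollection,
    exclude_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significance scores per set × contrast, and pathway Z per set × sample.

    ``de_results`` maps contrast name → per-gene DE table.  Returns a tidy
    significance frame (one row per set per contrast) and the sets × samples
    pathway-Z matrix.
    """
    scorer = PathwayScorer(gene_sets)
    blocks = []
    for contrast_name, table in de_results.items():
        sig = scorer.score_significance(table).assign(contrast=contrast_name)
        blocks.append(sig.reset_index())
    significance = pd.concat(blocks, ignore_index=True)[
        ["contrast", "gene_set", "global_score", "directed_score", "n_genes"]
    ]
    pathway_scores = scorer.transform(matrix, annotation, exclude_genes)
    return significance, pathway_scores
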