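"""Per-gene differential expression with BH adjustment and joint calling.

Each named contrast compares a case sample set (treated) against a matched
reference set (vehicle, or the earlier time point for sequential
comparisons).  Two per-gene models are available:

* ``log_linear`` (default) — ordinary least squares of log2 normalized
  counts on a case indicator; the coefficient is the log2 group difference
  and its Wald t equals the pooled-variance two-sample t (df = n − 2).
  Vectorized in closed form across genes.
* ``nb`` — a simplified negative-binomial GLM on raw counts with a log
  link, a case indicator and a log normalization-factor offset; dispersion
  per gene by method of moments.  Falls back to ``log_linear`` per gene on
  non-convergence (recorded in ``model_used``).

P values are BH-adjusted within each contrast, and a gene is called
significant when ``q < 0.05`` and ``|log2 ratio| > 1`` (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._utils import safe_log2
from .io import CountMatrix, PanelAnnotation, ValidationError

__all__ = [
    "Contrast",
    "build_standard_contrasts",
    "log2_ratio",
    "per_sample_log2_ratio",
    "fit_log_linear",
    "fit_simplified_nb",
    "bh_adjust",
    "call_de",
    "DifferentialExpression",
    "differential_expression",
    "sequential_contrasts",
]

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.05
LOG2_THRESHOLD = 1.0


@dataclass(frozen=True)
class Contrast:
    """A named case-vs-reference comparison."""

    name: str
    case: tuple[str, ...]
    reference: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.case) & set(self.reference):
            raise ValidationError(f"contrast {self.name}: case and reference overlap")
        if len(self.case) < 2 or len(self.reference) < 2:
            raise ValidationError(f"contrast {self.name}: need >=2 samples per side")

    def swapped(self) -> "Contrast":
        return Contrast(f"{self.name}.swapped", self.reference, self.case)


def build_standard_contrasts(metadata: pd.DataFrame) -> list[Contrast]:
    """Treated-vs-matched-vehicle contrasts from sample metadata.

    Acute contrasts (``Acute.1x``, ``Acute.4x``) pair each day-1 lung
    treated group with its dosing-matched vehicle; chronic contrasts
    (``Lung.W1`` … ``Spleen.W13``) pair each tissue × week treated group
    with its time- and tissue-matched vehicle.
    """
    contrasts = []

    def _group(treatment, regimen, time_point, tissue):
        mask = (
            (metadata["treatment"] == treatment)
            & (metadata["regimen"] == regimen)
            & (metadata["time_point"] == time_point)
            & (metadata["tissue"] == tissue)
        )
        return tuple(metadata.index[mask])

    acute = [("Acute.1x", "single"), ("Acute.4x", "four_weekly")]
    for name, regimen in acute:
        case = _group("cSiO2", regimen, "day1", "lung")
        ref = _group("VEH", regimen, "day1", "lung")
        if len(case) >= 2 and len(ref) >= 2:
            contrasts.append(Contrast(name, case, ref))

    for tissue in ("lung", "kidney", "spleen"):
        for week in ("W1", "W5", "W9", "W13"):
            case = _group("cSiO2", "four_weekly", week, tissue)
            ref = _group("VEH", "four_weekly", week, tissue)
            if len(case) >= 2 and len(ref) >= 2:
                contrasts.append(Contrast(f"{tissue.capitalize()}.{week}", case, ref))
    return contrasts


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def log2_ratio(counts: pd.DataFrame, contrast: Contrast) -> pd.Series:
    """Per-gene log2 of case mean over reference mean (pseudocount rule)."""
    if not len(contrast.case) or not len(contrast.reference):
        raise ValidationError("empty contrast side")
    case_mean = counts[list(contrast.case)].mean(axis=1)
    ref_mean = counts[list(contrast.reference)].mean(axis=1)
    return pd.Series(
        safe_log2(case_mean.to_numpy()) - safe_log2(ref_mean.to_numpy()),
        index=counts.index,
        name=f"log2_ratio[{contrast.name}]",
    )


def per_sample_log2_ratio(counts: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-sample log2 ratio vs the reference mean (heatmap export)."""
    ref_mean = safe_log2(counts[list(contrast.reference)].mean(axis=1).to_numpy())
    block = safe_log2(counts[list(contrast.case)].to_numpy())
    return pd.DataFrame(
        block - ref_mean[:, None], index=counts.index, columns=list(contrast.case)
    )


# ---------------------------------------------------------------------------
# per-gene models
# ---------------------------------------------------------------------------

def _log_linear_stats(
    log_case: np.ndarray, log_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS-on-indicator t statistics for genes × samples blocks.

    Equivalent to OLS of log2 expression on an intercept plus case
    indicator: the coefficient is the difference of group means and the
    Wald t is the pooled-variance two-sample t with n − 2 df.
    """
    n1, n0 = log_case.shape[1], log_ref.shape[1]
    est = log_case.mean(axis=1) - log_ref.mean(axis=1)
    ss = log_case.var(axis=1, ddof=1) * (n1 - 1) + log_ref.var(axis=1, ddof=1) * (n0 - 1)
    df = n1 + n0 - 2
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.where(est == 0, 0.0, np.inf * np.sign(est)))
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df)
    )
    p = np.where((se == 0) & (est == 0), 1.0, p)
    return est, t, p


def fit_log_linear(
    counts: pd.DataFrame, contrast: Contrast
) -> pd.DataFrame:
    """OLS of log2(normalized count) on a case indicator, per gene.

    Returns a frame with ``estimate`` (log2 units), ``t``, ``p`` and a
    ``degenerate`` flag for genes with zero residual variance.
    """
    log_case = safe_log2(counts[list(contrast.case)].to_numpy())
    log_ref = safe_log2(counts[list(contrast.reference)].to_numpy())
    est, t, p = _log_linear_stats(log_case, log_ref)
    degenerate = np.isinf(t)
    return pd.DataFrame(
        {"estimate": est, "t": t, "p": p, "degenerate": degenerate},
        index=counts.index,
    )


def _moment_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha, floored at 1e-8."""
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = ((y - mu) ** 2 - mu) / mu**2
    alpha = float(np.nanmean(contrib))
    return max(alpha, 1e-8)


def fit_simplified_nb(
    raw_counts: pd.DataFrame,
    contrast: Contrast,
    offsets: pd.Series,
) -> pd.DataFrame:
    """Simplified NB regression per gene on raw counts with a log offset.

    ``offsets`` carries the per-lane combined normalization factor ``f_s``
    (counts are normalized by multiplication with ``f_s``), entering the
    model as ``offset = -log(f_s)``.  The case-indicator Wald statistic is
    reported as ``t``; estimates are converted to log2 units.  Genes whose
    GLM fails to converge fall back to the log-linear model.
    """
    import statsmodels.api as sm

    samples = list(contrast.case) + list(contrast.reference)
    y_all = raw_counts[samples].to_numpy(float)
    x = np.column_stack(
        [np.ones(len(samples)), np.r_[np.ones(len(contrast.case)), np.zeros(len(contrast.reference))]]
    )
    offset = -np.log(offsets.loc[samples].to_numpy(float))

    fallback = fit_log_linear(raw_counts.mul(offsets, axis=1), contrast)
    rows = []
    for i in range(y_all.shape[0]):
        y = y_all[i]
        try:
            poisson = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
            alpha = _moment_dispersion(y, poisson.mu)
            model = sm.GLM(
                y, x, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(maxiter=100)
            if not np.all(np.isfinite(model.bse)) or model.bse[1] == 0:
                raise ValueError("degenerate standard error")
            est = model.params[1] / np.log(2.0)
            t = model.params[1] / model.bse[1]
            p = 2.0 * stats.norm.sf(abs(t))
            rows.append((est, t, p, False, "simplified_nb"))
        except Exception:  # noqa: BLE001 - any GLM failure falls back
            fb = fallback.iloc[i]
            rows.append((fb["estimate"], fb["t"], fb["p"], bool(fb["degenerate"]), "log_linear"))
    return pd.DataFrame(
        rows,
        columns=["estimate", "t", "p", "degenerate", "model_used"],
        index=raw_counts.index,
    )


# ---------------------------------------------------------------------------
# multiplicity and calling
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    q: pd.Series | np.ndarray,
    log2_ratios: pd.Series | np.ndarray,
    q_threshold: float = Q_THRESHOLD,
    log2_threshold: float = LOG2_THRESHOLD,
) -> np.ndarray:
    """The joint calling rule: q < 0.05 AND |log2 ratio| > 1, both strict."""
    q = np.asarray(q, dtype=float)
    lr = np.asarray(log2_ratios, dtype=float)
    return (q < q_threshold) & (np.abs(lr) > log2_threshold)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class DifferentialExpression(BaseEstimator):
    """Per-gene differential expression for one contrast.

    Parameters
    ----------
    model : {"log_linear", "nb"}, default "log_linear"
        Per-gene model.  The choice is explicit and global per run; the
        model actually used per gene is recorded in ``model_used`` (the NB
        fit can fall back to log-linear on non-convergence).
    q_threshold, log2_threshold : float
        The joint calling rule thresholds (strict inequalities).

    Attributes
    ----------
    results_ : DataFrame with columns ``log2_ratio``, ``t``, ``p``, ``q``,
        ``significant``, ``model_used`` indexed by gene symbol.
    """

    def __init__(
        self,
        model: str = "log_linear",
        q_threshold: float = Q_THRESHOLD,
        log2_threshold: float = LOG2_THRESHOLD,
    ):
        self.model = model
        self.q_threshold = q_threshold
        self.log2_threshold = log2_threshold

    def fit(
        self,
        matrix: CountMatrix,
        contrast: Contrast,
        annotation: PanelAnnotation | None = None,
        exclude_genes: set[str] | None = None,
        raw: CountMatrix | None = None,
        offsets: pd.Series | None = None,
    ) -> "DifferentialExpression":
        if self.model not in ("log_linear", "nb"):
            raise ValidationError(f"unknown model {self.model!r}")
        if matrix.stage != "normalized":
            raise ValidationError("differential expression expects normalized counts")

        counts = matrix.counts
        if annotation is not None:
            endo = matrix.counts.index.intersection(
                annotation.probes_of_class("endogenous")
            )
            counts = counts.loc[endo]
            counts = counts.set_axis(
                annotation.table.loc[endo, "gene_symbol"].to_numpy(), axis=0
            )
        if exclude_genes:
            counts = counts.loc[[g for g in counts.index if g not in exclude_genes]]

        ratios = log2_ratio(counts, contrast)
        if self.model == "nb":
            if raw is None or offsets is None:
                raise ValidationError("nb model needs raw counts and offsets")
            raw_counts = raw.counts
            if annotation is not None:
                endo_raw = raw_counts.index.intersection(
                    annotation.probes_of_class("endogenous")
                )
                raw_counts = raw_counts.loc[endo_raw].set_axis(
                    annotation.table.loc[endo_raw, "gene_symbol"].to_numpy(), axis=0
                )
            raw_counts = raw_counts.loc[counts.index]
            fits = fit_simplified_nb(raw_counts, contrast, offsets)
        else:
            fits = fit_log_linear(counts, contrast)
            fits["model_used"] = "log_linear"

        q = bh_adjust(fits["p"].to_numpy())
        significant = call_de(q, ratios, self.q_threshold, self.log2_threshold)
        self.results_ = pd.DataFrame(
            {
                "log2_ratio": ratios,
                "t": fits["t"],
                "p": fits["p"],
                "q": q,
                "significant": significant,
                "model_used": fits["model_used"],
            },
            index=counts.index,
        ).rename_axis("gene_symbol")
        self.contrast_ = contrast
        return self

    @property
    def significant_genes_(self) -> list[str]:
        return list(self.results_.index[self.results_["significant"]])


def differential_expression(
    matrix: CountMatrix,
    contrast: Contrast,
    annotation: PanelAnnotation | None = None,
    model: str = "log_linear",
    exclude_genes: set[str] | None = None,
    raw: CountMatrix | None = None,
    offsets: pd.Series | None = None,
) -> pd.DataFrame:
    """Functional wrapper: one DE table for one contrast."""
    de = DifferentialExpression(model=model)
    de.fit(matrix, contrast, annotation, exclude_genes, raw, offsets)
    return de.results_


def sequential_contrasts(
    matrix: CountMatrix,
    time_points: list[str],
    treatment: str = "cSiO2",
    tissue: str = "lung",
    annotation: PanelAnnotation | None = None,
    model: str = "log_linear",
    exclude_genes: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Within-treatment consecutive time-point comparisons (later vs earlier)."""
    meta = matrix.metadata
    known = set(meta["time_point"])
    unknown = [t for t in time_points if t not in known]
    if unknown:
        raise ValidationError(f"unknown time points: {unknown}")
    if len(time_points) < 2:
        raise ValidationError("need at least two time points for sequential contrasts")

    results = {}
    for earlier, later in zip(time_points, time_points[1:]):
        def _samples(tp):
            mask = (
                (meta["treatment"] == treatment)
                & (meta["time_point"] == tp)
                & (meta["tissue"] == tissue)
            )
            return tuple(meta.index[mask])

        contrast = Contrast(f"{later}-vs-{earlier}", _samples(later), _samples(earlier))
        results[contrast.name] = differential_expression(
            matrix, contrast, annotation, model=model, exclude_genes=exclude_genes
        )
    return results
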