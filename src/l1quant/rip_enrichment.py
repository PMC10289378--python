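"""RNA co-IP enrichment analysis.

Given a feature × sample raw count matrix with sample roles (TOTAL tissue
RNA, gradient-pool INPUT, beads-only BO background, and the ORF1p IP), this
module normalises library depth by the median-of-ratios method, tests IP
enrichment per feature against each reference role with a negative-binomial
Wald test, adjusts p-values by Benjamini–Hochberg within each contrast, and
classifies features into bound/unbound categories.  Repeat-element loci can
be collapsed to their subfamilies before testing, and ordinary
least-squares regressions quantify how binding relates to expression level
and transcript length.

The NB test is a deliberately transparent re-implementation (method-of-
moments dispersion, Wald z on the log2 ratio of shrunk group means) rather
than a wrapper around a full GLM framework: results are statistically
comparable but not feature-for-feature identical to DESeq2/EBSeq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_bound",
    "collapse_repeats",
    "association_regression",
    "NBTestResult",
    "RegressionResult",
]

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample normalisation factors.

    For every feature with nonzero counts in all samples, each sample's
    counts are divided by the feature's geometric mean across samples; the
    factor is the per-sample median of those ratios.

    Raises
    ------
    ValueError
        If no feature is nonzero in every sample (a pseudo-reference over
        nonzero entries would be the standard fallback; supply deeper data
        or pre-filter instead).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] == 1:
        return np.ones(1)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "consider a pseudo-reference fallback over nonzero entries"
        )
    ref = x[allpos]
    log_gm = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_gm)
    return np.median(ratios, axis=0)


@dataclass
class NBTestResult:
    """Per-feature Wald-test output for one contrast (arrays, aligned)."""

    log2_fold_change: np.ndarray
    standard_error: np.ndarray
    p_value: np.ndarray
    tested: np.ndarray  # False where the feature was zero in all samples

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2FoldChange": self.log2_fold_change,
                "lfcSE": self.standard_error,
                "pvalue": self.p_value,
                "tested": self.tested,
            },
            index=index,
        )


def nb_wald_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors_a: np.ndarray,
    size_factors_b: np.ndarray,
) -> NBTestResult:
    """Negative-binomial Wald test of group A vs group B per feature.

    Counts are normalised by the supplied size factors; each group's mean
    gets a 0.5 pseudo-count before the log2 ratio (group A over group B).
    The NB dispersion ``alpha`` (variance = mu + alpha*mu^2) is estimated by
    method of moments on the normalised counts pooled across both groups;
    because a per-feature moment estimate from a handful of replicates is
    too noisy to referee a Wald z, it is moderated by flooring at the
    median moment estimate across all features (information sharing in the
    spirit of DESeq2's dispersion shrinkage, conservative for
    below-median features) and finally floored at 1e-8.  The standard
    error of the log2 ratio follows from
    the delta method, and ``z = log2FC/SE`` is referred to the standard
    normal, two-sided.

    Features with zero counts in every sample are flagged untested
    (log2FC = 0, p = 1).
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float)) / np.asarray(size_factors_a, dtype=float)
    b = np.atleast_2d(np.asarray(counts_b, dtype=float)) / np.asarray(size_factors_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("groups must share the feature axis")
    n_a, n_b = a.shape[1], b.shape[1]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2(mean_a + _PSEUDOCOUNT) - np.log2(mean_b + _PSEUDOCOUNT)

    # method-of-moments dispersion pooled over both groups:
    # E[(s^2 - mu)/mu^2] = alpha for NB(mu, alpha)
    disp = np.zeros(a.shape[0])
    denom = 0
    for g, n in ((a, n_a), (b, n_b)):
        if n >= 2:
            mu = g.mean(axis=1)
            s2 = g.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                est = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
            disp += est
            denom += 1
    disp = disp / max(denom, 1)
    if disp.size > 1:
        disp = np.maximum(disp, np.median(disp))
    disp = np.maximum(disp, _DISPERSION_FLOOR)

    mu_a = mean_a + _PSEUDOCOUNT
    mu_b = mean_b + _PSEUDOCOUNT
    var_mean_a = (mu_a + disp * mu_a**2) / n_a
    var_mean_b = (mu_b + disp * mu_b**2) / n_b
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_mean_a / (mu_a**2 * ln2sq) + var_mean_b / (mu_b**2 * ln2sq))
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    untested = np.asarray(a.sum(axis=1) + b.sum(axis=1) == 0)
    lfc = np.where(untested, 0.0, lfc)
    p = np.where(untested, 1.0, p)
    return NBTestResult(lfc, se, p, ~untested)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_bound(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.Series:
    """Bound-mRNA categories from the three IP contrasts.

    ``results`` must carry per-contrast columns ``lfc_bo``/``padj_bo``,
    ``lfc_input``/``padj_input`` and ``lfc_total``/``padj_total`` (IP over
    BO, INPUT, TOTAL respectively).  A feature is **bound** when enriched
    (log2FC > threshold and padj < threshold) over both BO and INPUT.
    Bound features additionally enriched over the TOTAL are
    ``bound_enriched``; bound features significantly depleted relative to
    TOTAL (mirrored thresholds) are ``bound_depleted``; remaining bound
    features are ``bound_not_enriched``.  Everything else is ``unbound``.
    """
    need = [f"{k}_{c}" for c in ("bo", "input", "total") for k in ("lfc", "padj")]
    missing = [c for c in need if c not in results.columns]
    if missing:
        raise ValueError(f"missing contrast columns: {missing}")

    def enriched(c: str) -> pd.Series:
        return (results[f"lfc_{c}"] > lfc_threshold) & (results[f"padj_{c}"] < padj_threshold)

    bound = enriched("bo") & enriched("input")
    depleted_total = (results["lfc_total"] < -lfc_threshold) & (
        results["padj_total"] < padj_threshold
    )
    cat = pd.Series("unbound", index=results.index, dtype=object)
    cat[bound] = "bound_not_enriched"
    cat[bound & enriched("total")] = "bound_enriched"
    cat[bound & depleted_total] = "bound_depleted"
    return cat


def collapse_repeats(
    counts: pd.DataFrame,
    feature_class: pd.Series,
    subfamily: pd.Series,
) -> pd.DataFrame:
    """Sum repeat-locus counts into their subfamilies; genes pass through.

    ``feature_class`` marks each feature ``gene`` or ``repeat_locus``;
    every repeat locus must map to exactly one subfamily name.  Column
    (per-sample) totals are conserved.
    """
    fc = feature_class.reindex(counts.index)
    is_rep = fc == "repeat_locus"
    sub = subfamily.reindex(counts.index)
    unmapped = counts.index[is_rep & (sub.isna() | (sub == ""))]
    if len(unmapped):
        raise ValueError(f"repeat loci without subfamily mapping: {list(unmapped)}")
    genes = counts.loc[~is_rep]
    reps = counts.loc[is_rep]
    if reps.empty:
        return counts.copy()
    collapsed = reps.groupby(sub.loc[is_rep]).sum()
    collapsed.index.name = counts.index.name
    return pd.concat([genes, collapsed])


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def association_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with R² (squared Pearson r) and the slope's p-value.

    Used for the binding-vs-expression and binding-vs-length relationships
    (both axes on log2 scale upstream).  Non-finite pairs are dropped; at
    least 2 finite pairs and nonzero x-variance are required, and a
    two-point fit warns that R² = 1 holds by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least 2 finite (x, y) pairs")
    if x.size == 2:
        warnings.warn("two-point regression is exact by construction", stacklevel=2)
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
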