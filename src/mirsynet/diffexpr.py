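"""Two-group differential-expression screen for log2 microarray intensities.

The default test is a moderated t-statistic in the limma style: per-probe
residual variances are shrunk toward a pooled prior estimated by empirical
Bayes (moment matching of an F-distribution on the log variances), which
stabilises inference when each group has only a few dozen arrays.  A plain
Welch unequal-variance t-test is available as a dependency-light fallback.

Probes pass the screen when p < 0.05, |log2 fold change| >= 0.8 and
Benjamini-Hochberg FDR < 0.05 (the boundary conventions are strict ``<``
for the p-value and FDR and ``>=`` for the fold change).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix

__all__ = [
    "preprocess",
    "differential_test",
    "bh_adjust",
    "filter_demirs",
    "screen_demirs",
]

P_THRESHOLD = 0.05
LFC_THRESHOLD = 0.8
FDR_THRESHOLD = 0.05


def preprocess(matrix: ExpressionMatrix, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Missing-value screening: drop gappy rows, impute the rest.

    Rows whose fraction of missing cells exceeds ``max_missing_frac`` are
    removed; remaining missing cells are imputed with the row median.  The
    returned matrix contains no missing values.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must lie in [0, 1)")
    values = matrix.values
    frac = values.isna().mean(axis=1)
    kept = values.loc[frac <= max_missing_frac]
    if kept.empty:
        raise ValueError("missing-value screening removed every row")
    if kept.isna().to_numpy().any():
        medians = kept.median(axis=1)
        kept = kept.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    return ExpressionMatrix(kept, matrix.groups)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/trigamma."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to the observed residual variances.

    Returns (prior_df, prior_var).  Works on log variances: if z = log(s2)
    then E[z] and Var[z] are known functions of the prior through digamma/
    trigamma, which gives closed-form moment equations solvable with a
    trigamma inverse.  Rows with zero variance carry no information about
    the prior and are excluded from the moments.
    """
    ok = s2 > 0
    if not ok.any():
        return math.inf, 1e-8
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    e_var -= float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        prior_df = 2.0 * _trigamma_inverse(e_var)
        prior_var = math.exp(
            e_mean + float(special.digamma(prior_df / 2.0)) - math.log(prior_df / 2.0)
        )
    else:
        prior_df = math.inf
        prior_var = math.exp(e_mean)
    return prior_df, prior_var


def _group_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    if matrix.groups is None:
        raise ValueError("differential test requires group labels")
    case = matrix.values[matrix.case_samples].to_numpy()
    control = matrix.values[matrix.control_samples].to_numpy()
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if np.isnan(case).any() or np.isnan(control).any():
        raise ValueError("matrix contains missing values; run preprocess first")
    return case, control


def differential_test(matrix: ExpressionMatrix, method: str = "moderated_t") -> pd.DataFrame:
    """Per-miRNA two-sided test of case vs control means.

    Returns a DataFrame indexed by miRNA id with columns ``log2fc``
    (case mean minus control mean, data assumed already log2) and
    ``p_value``.  Rows that are constant and identical in both groups get
    log2fc 0 and p 1 by contract.
    """
    case, control = _group_arrays(matrix)
    n1, n2 = case.shape[1], control.shape[1]
    lfc = case.mean(axis=1) - control.mean(axis=1)

    if method == "welch_t":
        res = stats.ttest_ind(case, control, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = ~np.isfinite(p)
        # zero variance in both groups: p=1 when means agree, else 0
        p[degenerate & (np.abs(lfc) <= 1e-12)] = 1.0
        p[degenerate & (np.abs(lfc) > 1e-12)] = 0.0
    elif method == "moderated_t":
        df_resid = float(n1 + n2 - 2)
        ss = case.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / df_resid
        prior_df, prior_var = _fit_variance_prior(s2, df_resid)
        if math.isinf(prior_df):
            s2_post = np.full_like(s2, prior_var)
        else:
            s2_post = (prior_df * prior_var + df_resid * s2) / (prior_df + df_resid)
        # total df capped at the pooled residual df across all probes
        df_total = min(df_resid + prior_df, df_resid * len(s2))
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        raise ValueError(f"unknown method {method!r}; use 'welch_t' or 'moderated_t'")

    lfc = np.where(np.abs(lfc) <= 1e-12, 0.0, lfc)
    return pd.DataFrame(
        {"log2fc": lfc, "p_value": np.clip(p, 0.0, 1.0)}, index=matrix.values.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment to FDR.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def filter_demirs(
    results: pd.DataFrame,
    p_thr: float = P_THRESHOLD,
    lfc_thr: float = LFC_THRESHOLD,
    fdr_thr: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Flag differentially expressed miRNAs at the joint thresholds.

    ``results`` needs columns log2fc, p_value and fdr.  Adds ``direction``
    (up/down by the sign of log2fc) and ``passes``; kept iff
    p < p_thr AND |log2fc| >= lfc_thr AND fdr < fdr_thr.
    """
    if results.empty:
        raise ValueError("results table is empty")
    for col in ("log2fc", "p_value", "fdr"):
        if col not in results.columns:
            raise ValueError(f"results table lacks column {col!r}")
    out = results.copy()
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["passes"] = (
        (out["p_value"] < p_thr)
        & (out["log2fc"].abs() >= lfc_thr)
        & (out["fdr"] < fdr_thr)
    )
    return out


def screen_demirs(
    matrix: ExpressionMatrix,
    method: str = "moderated_t",
    max_missing_frac: float = 0.2,
    p_thr: float = P_THRESHOLD,
    lfc_thr: float = LFC_THRESHOLD,
    fdr_thr: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Convenience wrapper: preprocess, test, BH-adjust and threshold."""
    clean = preprocess(matrix, max_missing_frac)
    results = differential_test(clean, method=method)
    results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    return filter_demirs(results, p_thr=p_thr, lfc_thr=lfc_thr, fdr_thr=fdr_thr)
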