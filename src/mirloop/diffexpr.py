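"""Quantile normalization, (moderated) t differential expression and DEM selection.

The moderated t follows the empirical-Bayes treatment standard for
microarray data: per-feature pooled variances s^2 with d residual degrees
of freedom are shrunk toward a prior (d0, s0^2) estimated by moment
matching on log sample variances, giving

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and a t statistic on d0 + d degrees of freedom. When the moment fit
degenerates (the residual log-variance spread is no larger than the
sampling noise trigamma(d/2)), the estimator falls back to the ordinary
pooled t (prior df 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, SampleSheet, ValidationError

RESULT_COLUMNS = ("log2fc", "t_stat", "df", "p_value", "adj_p")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) to share one value distribution.

    The reference distribution is the vector of per-rank row means of the
    column-sorted matrix; each column's values are replaced by the
    reference value of their rank, ties receiving the mean of the
    reference values across their tied rank span. Within-column rank
    order is preserved, so any strictly increasing per-sample distortion
    is undone.
    """
    X = m.values
    if X.shape[1] < 1:
        raise ValidationError("matrix must have at least one column")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        sorter = np.argsort(col, kind="mergesort")
        sorted_vals = col[sorter]
        assigned = ref.copy()
        # average the reference over each tied span
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_vals[end] != sorted_vals[start]:
                if end - start > 1:
                    assigned[start:end] = ref[start:end].mean()
                start = end
        out[sorter, j] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing target)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Works on e = log(s^2) - digamma(d/2) + log(d/2); under the scaled-F
    model mean(e) = log(s0^2) + digamma(d0/2) - log(d0/2) and
    var(e) = trigamma(d0/2) + trigamma(d/2). Returns (0, mean(s^2)) when
    the fit degenerates.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(s2.mean()) if s2.size else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = e.var(ddof=1) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return 0.0, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def differential_expression(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    method: str = "moderated_t",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature case-vs-control test on a normalized log2 matrix.

    Returns a DataFrame indexed by feature id with columns
    ``log2fc, t_stat, df, p_value, adj_p`` (adj_p by Benjamini-Hochberg
    over all features). ``method`` is ``moderated_t`` (empirical-Bayes
    shrunken variance) or ``welch_t``. ``prior_df`` overrides the
    estimated prior degrees of freedom of the moderated t (0 recovers the
    ordinary pooled t).
    """
    if method not in {"moderated_t", "welch_t"}:
        raise ValidationError(f"unknown method: {method!r}")
    case_ids, ctrl_ids = sheet.case_ids, sheet.control_ids
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValidationError("each group needs at least 2 samples")

    A = m.subset_samples(case_ids).values
    B = m.subset_samples(ctrl_ids).values
    n1, n0 = A.shape[1], B.shape[1]
    mean_diff = A.mean(axis=1) - B.mean(axis=1)

    if method == "welch_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        v1, v0 = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
        se2 = v1 / n1 + v0 / n0
        df = np.where(
            se2 > 0,
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1) + 1e-300),
            n1 + n0 - 2,
        )
        degenerate = se2 == 0
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate & (mean_diff == 0), 1.0, p)
        p = np.where(degenerate & (mean_diff != 0), 0.0, p)
    else:
        d = n1 + n0 - 2.0
        s2 = ((n1 - 1) * A.var(axis=1, ddof=1) + (n0 - 1) * B.var(axis=1, ddof=1)) / d
        if prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, d)
        else:
            d0 = float(prior_df)
            _, s0_sq = fit_variance_prior(s2, d) if d0 > 0 else (0.0, 0.0)
        if np.isinf(d0):
            s_tilde2 = np.full_like(s2, s0_sq)
            df = np.full_like(s2, np.inf)
        else:
            s_tilde2 = (d0 * s0_sq + d * s2) / (d0 + d)
            df = np.full_like(s2, d0 + d)
        se = np.sqrt(s_tilde2 * (1.0 / n1 + 1.0 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        degenerate = se == 0
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate & (mean_diff == 0), 1.0, p)
        p = np.where(degenerate & (mean_diff != 0), 0.0, p)

    p = np.clip(p, 0.0, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": mean_diff,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "adj_p": adj_p,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )


def select_dems(
    result: pd.DataFrame,
    lfc_min: float = 1.0,
    adjp_max: float = 0.01,
    top_k: int | None = None,
) -> list[str]:
    """Filter and rank one cohort's differential-expression result.

    Keeps features with ``|log2fc| >= lfc_min`` and ``adj_p < adjp_max``,
    sorted by ascending adj_p (ties by descending |log2fc|, then id), and
    truncated to ``top_k`` when given.
    """
    if lfc_min <= 0:
        raise ValidationError("lfc_min must be > 0")
    kept = result[(result["log2fc"].abs() >= lfc_min) & (result["adj_p"] < adjp_max)]
    order = kept.assign(_abs=kept["log2fc"].abs(), _id=kept.index).sort_values(
        by=["adj_p", "_abs", "_id"], ascending=[True, False, True], kind="mergesort"
    )
    ids = list(order.index)
    if top_k is not None:
        if top_k < 1:
            raise ValidationError("top_k must be >= 1")
        ids = ids[:top_k]
    return ids


def select_and_intersect_dems(
    results_per_cohort: list[pd.DataFrame],
    lfc_min: float = 1.0,
    adjp_max: float = 0.01,
    top_k: int = 500,
) -> tuple[list[list[str]], set[str]]:
    """Per-cohort DEM lists (filtered, ranked, truncated) and their intersection."""
    if not results_per_cohort:
        raise ValidationError("no cohort results supplied")
    lists = [select_dems(r, lfc_min, adjp_max, top_k) for r in results_per_cohort]
    intersection = set(lists[0])
    for ids in lists[1:]:
        intersection &= set(ids)
    return lists, intersection
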