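"""Single-marker ROC analysis and multi-marker logistic-regression panels.

AUC is the Mann-Whitney rank statistic with half credit for ties, with the
Hanley-McNeil closed-form standard error and a normal 95% CI clipped to
[0, 1]. The operating point maximizes the Youden index J = sensitivity +
specificity - 1 over midpoints between adjacent distinct scores (plus the
two infinite endpoints). Panels are binomial logistic regressions fit by
iteratively reweighted least squares; perfect separation is reported with
a flag and finite-iteration coefficients rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .model import ValidationError


class SingularDesignError(ValueError):
    """The panel design matrix is rank deficient (e.g. collinear members)."""


@dataclass
class RocResult:
    auc: float
    se_auc: float
    ci95: tuple[float, float]
    youden_j: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_case: int
    n_control: int
    orientation: str  # "case_high": positive when score >= cutoff
    ci_method: str = "hanley-mcneil"


def hanley_mcneil_se(auc: float, n_case: int, n_control: int) -> float:
    """Closed-form SE of the empirical AUC (Hanley & McNeil)."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_case - 1) * (q1 - a * a)
        + (n_control - 1) * (q2 - a * a)
    ) / (n_case * n_control)
    return float(np.sqrt(max(var, 0.0)))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (cases-higher orientation) with half credit for ties."""
    ranks = stats.rankdata(scores, method="average")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_analysis(scores, labels) -> RocResult:
    """Empirical ROC of one marker; orientation is fixed so AUC >= 0.5.

    ``labels`` is truthy for cases. When controls score higher the sign of
    the scores is flipped internally (``orientation`` records it) and the
    reported cutoff refers to the original scale with the rule
    "positive when score <= cutoff".
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")

    auc = rank_auc(scores, labels)
    orientation = "case_high"
    working = scores
    if auc < 0.5:
        orientation = "case_low"
        working = -scores
        auc = 1.0 - auc

    # candidate thresholds: midpoints between adjacent distinct scores, +-inf
    distinct = np.unique(working)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.array([])
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    case_scores = working[labels]
    ctrl_scores = working[~labels]
    best_j, best_cut, best_sens, best_spec = -np.inf, -np.inf, 1.0, 0.0
    for cut in thresholds:  # ascending: ties keep the lower cutoff
        sens = float((case_scores >= cut).mean())
        spec = float((ctrl_scores < cut).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut, best_sens, best_spec = j, cut, sens, spec

    se = hanley_mcneil_se(auc, n1, n0)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    cutoff = best_cut if orientation == "case_high" else -best_cut
    return RocResult(
        auc=auc,
        se_auc=se,
        ci95=ci,
        youden_j=best_j,
        cutoff=float(cutoff),
        sensitivity=best_sens,
        specificity=best_spec,
        n_case=n1,
        n_control=n0,
        orientation=orientation,
    )


@dataclass
class PanelModel:
    member_ids: list[str]
    coefficients: pd.Series  # intercept + one slope per member, log-odds units
    fitted_scores: np.ndarray  # per-sample case probability
    roc: RocResult
    converged: bool
    separation: bool
    n_iter: int = 0


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, int]:
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ Xw, X.T @ (w * z))
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("singular design matrix in IRLS") from exc
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    return beta, converged, it


def fit_panel(
    matrix, labels, max_iter: int = 100, tol: float = 1e-8
) -> PanelModel:
    """Fit a binomial logistic panel over the given markers.

    ``matrix`` is an ExpressionMatrix (features = panel members, columns =
    samples) or an equivalently shaped DataFrame; ``labels`` is truthy per
    sample for cases. The panel score is the fitted case probability and
    its ROC is computed by :func:`roc_analysis` (in-sample, mirroring a
    per-dataset fit-and-evaluate design).
    """
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    members = list(data.index)
    if len(members) < 2:
        raise ValidationError("a panel needs at least 2 members")
    X = data.to_numpy(dtype=float).T  # samples x members
    y = np.asarray(labels, dtype=float)
    if len(y) != X.shape[0]:
        raise ValidationError("label count does not match sample count")
    if np.any(X.std(axis=0) == 0):
        const = [members[i] for i in np.where(X.std(axis=0) == 0)[0]]
        raise ValidationError(f"constant-valued member(s): {const}")

    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("collinear panel members (rank-deficient design)")

    beta, converged, n_iter = _irls_logistic(design, y, max_iter, tol)
    prob = expit(design @ beta)
    # perfect separation: fitted probabilities pinned to the labels
    resid = np.abs(y - prob)
    separation = bool(np.all(resid < 1e-6)) or (
        not converged and np.max(np.abs(beta)) > 30.0
    )
    prob = np.clip(prob, 1e-12, 1.0 - 1e-12)
    coef = pd.Series(beta, index=["intercept", *members])
    roc = roc_analysis(prob, np.asarray(labels, dtype=bool))
    return PanelModel(
        member_ids=members,
        coefficients=coef,
        fitted_scores=prob,
        roc=roc,
        converged=converged,
        separation=separation,
        n_iter=n_iter,
    )
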