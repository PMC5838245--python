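"""Outcome labeling and classification: remission criteria, equivalent-dose
conversion, ROI-mask construction, hierarchical logistic regression with
likelihood-ratio and Wald tests, ROC analysis, leave-one-out cross-validation,
and specificity (added-value) regressions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .core import DataError, GeometryError, StatsError
from .geometry import sphere_mask

REMISSION_CUTOFF = 7        # week-8 HRSD17 <= 7
ELIGIBILITY_MIN = 16        # baseline HRSD17 >= 16

DOSE_FACTORS = {"escitalopram": 7.5, "sertraline": 1.5, "venlafaxine": 1.0}


def label_remission(hrsd17_week8, hrsd17_baseline=None):
    """Label a patient from HRSD17 scores.

    Returns ``(label, eligible)`` where label is 'remitter' iff the week-8
    score is <= 7, and eligible is False when the baseline score is below the
    entry criterion (>= 16).
    """
    if hrsd17_week8 is None or (isinstance(hrsd17_week8, float)
                                and np.isnan(hrsd17_week8)):
        raise DataError("missing week-8 HRSD17 score; cannot label outcome")
    label = "remitter" if hrsd17_week8 <= REMISSION_CUTOFF else "nonremitter"
    eligible = True
    if hrsd17_baseline is not None and np.isfinite(hrsd17_baseline):
        eligible = hrsd17_baseline >= ELIGIBILITY_MIN
    return label, eligible


def percent_reduction(hrsd17_baseline, hrsd17_week8) -> float:
    return (hrsd17_baseline - hrsd17_week8) / hrsd17_baseline * 100.0


def equivalent_dose(drug: str, dose_mg: float) -> float:
    """Venlafaxine-equivalent dose (7.5x escitalopram, 1.5x sertraline)."""
    if dose_mg <= 0:
        raise DataError("dose must be positive")
    try:
        return dose_mg * DOSE_FACTORS[drug]
    except KeyError:
        raise DataError(f"unknown drug {drug!r}") from None


def sample_flow(n_scanned: int, n_excess_movement: int, n_incomplete: int) -> int:
    """Retained count after the stated exclusions."""
    retained = n_scanned - n_excess_movement - n_incomplete
    if retained < 0:
        raise DataError("exclusions exceed scanned count")
    return retained


def build_roi_mask(source_map: np.ndarray, shape, affine,
                   center_mm=(-2.0, 50.0, -6.0), radius_mm: float = 10.0):
    """Intersection of a supplied binary map with a world-space sphere.

    Returns ``(mask, voxel_count)``; an empty intersection is a geometry
    error.
    """
    source = np.asarray(source_map).astype(bool)
    if source.shape != tuple(shape):
        raise GeometryError("source map is not on the target grid")
    mask = source & sphere_mask(shape, affine, center_mm, radius_mm)
    count = int(mask.sum())
    if count == 0:
        raise GeometryError("ROI mask intersection is empty")
    return mask, count


# ---------------------------------------------------------------------------
# logistic regression (IRLS) with explicit likelihoods
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    deviance: float
    converged: bool
    separated: bool
    n_iter: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.coef)

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se


def _log_likelihood(y, eta) -> float:
    # numerically stable: -log(1 + exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least
    squares. ``X`` must include its intercept column. Complete separation is
    detected (perfect prediction with diverging coefficients) and flagged
    rather than silently iterated to overflow."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError("X/y shapes incompatible")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise StatsError("outcome must contain both classes coded 0/1")
    n, p = X.shape
    if n < p + 1:
        raise StatsError("too few observations for the logistic model")
    beta = np.zeros(p)
    converged = separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        if np.max(np.abs(eta)) > 30 and np.all((mu > 0.5) == (y > 0.5)):
            separated = True
            break
        W = np.clip(w, 1e-10, None)
        XtWX = (X * W[:, None]).T @ X
        grad = X.T @ (y - mu)
        # pinv tolerates rank deficiency (zero or collinear predictors):
        # the fit then lands on the minimum-norm solution
        step = np.linalg.pinv(XtWX) @ grad
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    W = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X * W[:, None]).T @ X
    cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    llf = _log_likelihood(y, eta)
    return LogisticFit(coef=beta, se=se, loglik=llf, deviance=-2.0 * llf,
                       converged=converged, separated=separated, n_iter=it)


def standardize(x, mean=None, sd=None):
    """Mean-center and scale by SD; returns ``(scaled, mean, sd)``."""
    x = np.asarray(x, dtype=float)
    mean = float(x.mean()) if mean is None else mean
    sd = float(x.std(ddof=1)) if sd is None else sd
    if sd <= 0:
        raise StatsError("cannot standardize a constant predictor")
    return (x - mean) / sd, mean, sd


def fit_logistic_with_lr(y, covariates, fc=None):
    """Hierarchical logistic models: covariates-only vs covariates + extra
    predictors (e.g., standardized connectivity).

    Returns a dict with both fits, the likelihood-ratio chi-square (deviance
    difference), its df, p, and per-coefficient Wald z statistics of the full
    model. Separation in either model is propagated as a flag.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise StatsError("need n >= 10 for the hierarchical logistic model")
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.size:
        cov = cov.T
    X0 = np.column_stack([np.ones(y.size), cov])
    fit0 = fit_logistic(X0, y)
    if fc is None:
        return {"fit_reduced": fit0, "fit_full": fit0, "lr_chi2": 0.0,
                "lr_df": 0, "lr_p": 1.0, "wald_z": fit0.wald_z,
                "separated": fit0.separated}
    add = np.atleast_2d(np.asarray(fc, dtype=float))
    if add.shape[0] != y.size:
        add = add.T
    X1 = np.column_stack([X0, add])
    fit1 = fit_logistic(X1, y)
    lr = max(fit0.deviance - fit1.deviance, 0.0)
    df = add.shape[1]
    return {
        "fit_reduced": fit0,
        "fit_full": fit1,
        "lr_chi2": float(lr),
        "lr_df": int(df),
        "lr_p": float(stats.chi2.sf(lr, df)) if df else 1.0,
        "wald_z": fit1.wald_z,
        "separated": fit0.separated or fit1.separated,
    }


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    rule: str
    degenerate: bool = False


def _operating_point(scores, y, threshold):
    pred = scores >= threshold
    tp = np.sum(pred & (y == 1))
    tn = np.sum(~pred & (y == 0))
    sens = tp / max(np.sum(y == 1), 1)
    spec = tn / max(np.sum(y == 0), 1)
    acc = (tp + tn) / y.size
    return float(acc), float(sens), float(spec)


def roc_analysis(scores, outcomes, threshold_rule: str = "youden") -> RocCurve:
    """Full-threshold ROC with trapezoidal AUC and an operating point chosen
    by ``threshold_rule`` ('youden' maximizes sensitivity + specificity - 1;
    'fixed-0.5' classifies at score >= 0.5)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.unique(y).size < 2:
        raise StatsError("both outcome classes required for ROC")
    degenerate = np.allclose(scores, scores[0])
    if degenerate:
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        thresholds = np.array([np.inf, scores[0]])
        roc_auc = 0.5
    else:
        fpr, tpr, thresholds = _roc_curve(y, scores)
        roc_auc = float(_auc(fpr, tpr))
    if threshold_rule == "youden":
        j = tpr - fpr
        best = int(np.argmax(j))
        thr = float(thresholds[best])
        if not np.isfinite(thr):
            thr = float(scores.max()) + 1.0
    elif threshold_rule == "fixed-0.5":
        thr = 0.5
    else:
        raise DataError(f"unknown threshold rule {threshold_rule!r}")
    acc, sens, spec = _operating_point(scores, y, thr)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(roc_auc),
                    threshold=thr, accuracy=acc, sensitivity=sens,
                    specificity=spec, rule=threshold_rule, degenerate=degenerate)


def loocv_predict(y, covariates, fc=None, threshold_rule: str = "fixed-0.5"):
    """Leave-one-out cross-validated remission scores.

    For every subject, the logistic model (including the mean/SD used to
    standardize the connectivity predictor) is estimated on the remaining
    n - 1 subjects and applied to the held-out one. Returns
    ``(scores, RocCurve, flags)``: ``scores`` are the held-out predicted
    probabilities; folds whose training outcome is single-class yield NaN
    scores and a flag.

    The cross-validated ROC/AUC is computed on fold-normalized scores (the
    percentile of the held-out linear predictor within the training-fold
    linear predictors). Raw leave-one-out probabilities carry a systematic
    class-imbalance artifact — holding out a positive leaves a
    negative-heavy training set, deflating that subject's score — which
    drives the null AUC well below 0.5; percentile scoring removes the
    fold-specific shift while preserving within-fold ordering. The
    operating-point accuracy under ``'fixed-0.5'`` still uses the raw
    probabilities at the 0.5 threshold.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise StatsError("need n >= 10 for LOOCV")
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    fc_arr = None if fc is None else np.asarray(fc, dtype=float)
    scores = np.full(n, np.nan)
    rank_scores = np.full(n, np.nan)
    flags = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if np.unique(y[tr]).size < 2:
            flags.append(i)
            continue
        X_tr = [np.ones(n - 1), *cov[tr].T]
        X_te = [1.0, *cov[i]]
        if fc_arr is not None:
            fc_tr, m, s = standardize(fc_arr[tr])
            X_tr.append(fc_tr)
            X_te.append((fc_arr[i] - m) / s)
        fit = fit_logistic(np.column_stack(X_tr), y[tr])
        lin_tr = np.column_stack(X_tr) @ fit.coef
        lin_te = float(np.asarray(X_te, dtype=float) @ fit.coef)
        scores[i] = float(expit(lin_te))
        rank_scores[i] = (np.sum(lin_tr < lin_te)
                          + 0.5 * np.sum(lin_tr == lin_te)) / (n - 1)
    ok = np.isfinite(scores)
    curve = roc_analysis(rank_scores[ok], y[ok], threshold_rule="youden")
    if threshold_rule == "fixed-0.5":
        acc, sens, spec = _operating_point(scores[ok], y[ok], 0.5)
        curve = RocCurve(fpr=curve.fpr, tpr=curve.tpr,
                         thresholds=curve.thresholds, auc=curve.auc,
                         threshold=0.5, accuracy=acc, sensitivity=sens,
                         specificity=spec, rule="fixed-0.5",
                         degenerate=curve.degenerate)
    elif threshold_rule != "youden":
        raise DataError(f"unknown threshold rule {threshold_rule!r}")
    return scores, curve, flags


def specificity_checks(fc, table: pd.DataFrame, characteristics,
                       outcome_col: str = "remitter") -> pd.DataFrame:
    """Per baseline characteristic: (a) linear regression of connectivity on
    the characteristic, (b) LR test of connectivity added to a logistic model
    of remission on that characteristic. Constant characteristics are skipped
    with a note."""
    fc = np.asarray(fc, dtype=float)
    y = table[outcome_col].to_numpy(dtype=float)
    rows = []
    for c in characteristics:
        x = table[c].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            rows.append({"characteristic": c, "skipped": True,
                         "note": "constant characteristic"})
            continue
        lin = stats.linregress(x, fc)
        fc_std, _, _ = standardize(fc)
        res = fit_logistic_with_lr(y, x[:, None], fc_std[:, None])
        rows.append({
            "characteristic": c, "skipped": False, "note": "",
            "slope": float(lin.slope), "slope_p": float(lin.pvalue),
            "fc_lr_chi2": res["lr_chi2"], "fc_lr_p": res["lr_p"],
            "separated": res["separated"],
        })
    return pd.DataFrame(rows)
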