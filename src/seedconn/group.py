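"""Group-level inference on Fisher-z maps: voxel-wise outcome contrasts with
covariates, permutation cluster-extent FWE correction (Freedman–Lane),
cluster value extraction, planned comparisons vs controls, paired pre/post
tests, and summary-statistic t tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import DataError, StatsError


@dataclass(frozen=True)
class GroupModelSpec:
    """Outcome model for the voxel-wise prediction analysis.

    ``outcome`` is ``'remission'`` (binary factor, contrast = remitter minus
    non-remitter) or ``'percent_reduction'`` (continuous regressor). With
    ``drug_interaction`` the model adds drug main effects and the
    outcome-by-drug interaction, and the statistic is the interaction F.
    """

    outcome: str = "remission"
    covariates: tuple = ("age", "duration_mdd", "hrsd17_baseline")
    drug_interaction: bool = False


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    cluster_forming_p: float = 0.001
    fwe_alpha: float = 0.001
    connectivity_scheme: str = "corner"   # 'face' or 'corner' (26-neighbor)
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.cluster_forming_p < 1 and 0 < self.fwe_alpha < 1):
            raise DataError("probability thresholds must lie in (0, 1)")
        if self.n_permutations < 100:
            raise DataError("need at least 100 permutations")
        if self.connectivity_scheme not in ("face", "corner"):
            raise DataError("connectivity_scheme must be 'face' or 'corner'")

    def structure(self) -> np.ndarray:
        if self.connectivity_scheme == "face":
            return ndimage.generate_binary_structure(3, 1)
        return np.ones((3, 3, 3), dtype=bool)


@dataclass
class StatMap:
    values: np.ndarray          # flattened over voxels
    kind: str                   # 't' or 'F'
    df: int
    df_num: int = 1


@dataclass
class ClusterResult:
    """One supra-threshold cluster with its permutation FWE p."""

    mask: np.ndarray            # boolean, 3D
    extent: int
    peak_stat: float
    peak_ijk: tuple
    fwe_p: float
    retained: bool
    subject_values: np.ndarray | None = None


def _outcome_vector(table: pd.DataFrame, model: GroupModelSpec) -> np.ndarray:
    if model.outcome == "remission":
        return table["remitter"].to_numpy(dtype=float)
    if model.outcome == "percent_reduction":
        base = table["hrsd17_baseline"].to_numpy(dtype=float)
        week8 = table["hrsd17_week8"].to_numpy(dtype=float)
        return (base - week8) / base * 100.0
    raise DataError(f"unknown outcome {model.outcome!r}")


def _covariate_block(table: pd.DataFrame, model: GroupModelSpec) -> np.ndarray:
    cols = []
    for c in model.covariates:
        v = table[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise DataError(f"covariate {c!r} has missing values")
        cols.append(v - v.mean())
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def _drug_dummies(table: pd.DataFrame):
    drugs = sorted(table["drug"].unique())
    if len(drugs) < 2:
        raise DataError("drug interaction model needs >= 2 drug arms")
    ref = drugs[0]
    dummies = np.column_stack([
        (table["drug"] == d).to_numpy(dtype=float) for d in drugs[1:]
    ])
    return dummies, [d for d in drugs[1:]], ref


def build_designs(table: pd.DataFrame, model: GroupModelSpec):
    """Return ``(X_full, X_reduced, kind, interest_index_or_q)``.

    For the general model the reduced design drops the outcome column
    (Freedman–Lane nuisance model); for the interaction model it drops the
    outcome-by-drug columns.
    """
    n = len(table)
    y = _outcome_vector(table, model)
    cov = _covariate_block(table, model)
    intercept = np.ones((n, 1))
    if not model.drug_interaction:
        X_full = np.hstack([intercept, y[:, None], cov])
        X_red = np.hstack([intercept, cov])
        return X_full, X_red, "t", 1
    dummies, _, _ = _drug_dummies(table)
    inter = y[:, None] * dummies
    X_red = np.hstack([intercept, y[:, None], dummies, cov])
    X_full = np.hstack([X_red, inter])
    return X_full, X_red, "F", inter.shape[1]


def _check_rank(X: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError(f"rank-deficient {what} design matrix")


class _StatEngine:
    """Precomputed OLS machinery for repeated evaluation on permuted data."""

    def __init__(self, X_full, X_red, kind, interest):
        _check_rank(X_full, "full")
        self.X_full = X_full
        self.X_red = X_red
        self.kind = kind
        self.n, p = X_full.shape
        self.df = self.n - p
        if self.df < 1:
            raise StatsError("no residual degrees of freedom")
        self.pinv_full = np.linalg.pinv(X_full)
        if kind == "t":
            self.j = interest
            self.cvc = np.linalg.inv(X_full.T @ X_full)[interest, interest]
            self.df_num = 1
        else:
            self.q = interest
            self.pinv_red = np.linalg.pinv(X_red)
            self.df_num = interest

    def stat_map(self, Y: np.ndarray) -> np.ndarray:
        """Y is (n_subjects, n_voxels)."""
        B = self.pinv_full @ Y
        rss = np.sum((Y - self.X_full @ B) ** 2, axis=0)
        if self.kind == "t":
            sigma2 = rss / self.df
            denom = np.sqrt(np.maximum(sigma2 * self.cvc, 1e-300))
            return B[self.j] / denom
        B0 = self.pinv_red @ Y
        rss0 = np.sum((Y - self.X_red @ B0) ** 2, axis=0)
        return ((rss0 - rss) / self.q) / np.maximum(rss / self.df, 1e-300)

    def forming_threshold(self, p: float) -> float:
        if self.kind == "t":
            return float(stats.t.isf(p, self.df))
        return float(stats.f.isf(p, self.df_num, self.df))


def _stack_zmaps(zmaps) -> np.ndarray:
    arrs = [z.data if hasattr(z, "data") else np.asarray(z) for z in zmaps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise DataError("z maps lie on different grids")
    return np.stack([a.ravel() for a in arrs]), shape


def voxelwise_group_contrast(zmaps, table: pd.DataFrame,
                             model: GroupModelSpec = GroupModelSpec()):
    """Fit z ~ outcome + covariates (+ drug + outcome x drug) at every voxel.

    Returns ``(StatMap, shape3d)``: the remitter-minus-non-remitter t map, or
    the interaction F map when ``model.drug_interaction`` is set.
    """
    Y, shape = _stack_zmaps(zmaps)
    if len(table) != Y.shape[0]:
        raise DataError("phenotype table does not match number of z maps")
    X_full, X_red, kind, interest = build_designs(table, model)
    engine = _StatEngine(X_full, X_red, kind, interest)
    values = engine.stat_map(Y)
    return StatMap(values=values, kind=kind, df=engine.df,
                   df_num=engine.df_num), shape


def label_clusters(stat_3d: np.ndarray, threshold: float,
                   structure: np.ndarray):
    """Contiguous supra-threshold components (one-sided: stat > threshold).

    Returns ``(labels, extents)`` with extents indexed from label 1.
    """
    labels, n = ndimage.label(stat_3d > threshold, structure=structure)
    if n == 0:
        return labels, np.zeros(0, dtype=int)
    extents = np.bincount(labels.ravel())[1:]
    return labels, extents


def permutation_cluster_fwe(zmaps, table: pd.DataFrame,
                            model: GroupModelSpec = GroupModelSpec(),
                            config: PermutationConfig = PermutationConfig()):
    """Cluster-extent FWE inference by sign-free Freedman–Lane permutation.

    The nuisance-only (reduced) model is fitted once; permuted datasets are
    ``fitted + residuals[perm]`` and refitted under the full model. The null
    distribution is the maximum supra-threshold cluster extent per
    permutation; cluster FWE p = (1 + #{perm max >= extent}) / (n_perm + 1).

    Returns ``(StatMap, clusters, max_null_extents)``; subjects are sorted by
    ``subject_id`` internally so results do not depend on input order.
    """
    if "subject_id" in table.columns:
        order = np.argsort(table["subject_id"].to_numpy())
        table = table.iloc[order].reset_index(drop=True)
        zmaps = [zmaps[i] for i in order]
    Y, shape = _stack_zmaps(zmaps)
    if len(table) != Y.shape[0]:
        raise DataError("phenotype table does not match number of z maps")
    X_full, X_red, kind, interest = build_designs(table, model)
    engine = _StatEngine(X_full, X_red, kind, interest)
    structure = config.structure()
    threshold = engine.forming_threshold(config.cluster_forming_p)

    observed = engine.stat_map(Y)
    labels, extents = label_clusters(observed.reshape(shape), threshold, structure)

    # Freedman-Lane: permute reduced-model residuals, keep nuisance fit.
    pinv_red = np.linalg.pinv(X_red)
    fitted0 = X_red @ (pinv_red @ Y)
    resid0 = Y - fitted0
    rng = np.random.default_rng(config.rng_seed)
    n = Y.shape[0]
    max_null = np.zeros(config.n_permutations)
    for b in range(config.n_permutations):
        perm = rng.permutation(n)
        stat_b = engine.stat_map(fitted0 + resid0[perm])
        _, ext_b = label_clusters(stat_b.reshape(shape), threshold, structure)
        max_null[b] = ext_b.max() if ext_b.size else 0

    clusters = []
    stat_3d = observed.reshape(shape)
    for lab, extent in enumerate(extents, start=1):
        mask = labels == lab
        flat = np.where(mask.ravel(), observed, -np.inf)
        peak_flat = int(np.argmax(flat))  # ties: smallest linear index
        fwe_p = float((1 + np.sum(max_null >= extent))
                      / (config.n_permutations + 1))
        clusters.append(ClusterResult(
            mask=mask,
            extent=int(extent),
            peak_stat=float(stat_3d.ravel()[peak_flat]),
            peak_ijk=tuple(int(v) for v in np.unravel_index(peak_flat, shape)),
            fwe_p=fwe_p,
            retained=fwe_p <= config.fwe_alpha,
        ))
    clusters.sort(key=lambda c: (-c.extent, c.peak_ijk))
    return StatMap(values=observed, kind=kind, df=engine.df,
                   df_num=engine.df_num), clusters, max_null


def extract_cluster_values(cluster_mask: np.ndarray, zmaps) -> np.ndarray:
    """Per-subject mean z over the cluster voxels."""
    mask = cluster_mask.mask if isinstance(cluster_mask, ClusterResult) else cluster_mask
    if not mask.any():
        raise DataError("empty cluster")
    flat = mask.ravel()
    out = []
    for z in zmaps:
        if z is None:
            out.append(np.nan)  # missing session flagged, not dropped
            continue
        arr = z.data if hasattr(z, "data") else np.asarray(z)
        out.append(float(arr.ravel()[flat].mean()))
    return np.asarray(out)


def planned_group_comparison(values, is_case, age=None):
    """Dummy-coded regression of extracted connectivity on group membership
    (case vs control) with optional age covariate.

    Cohen's d is computed from the adjusted contrast as t * sqrt(1/n1 + 1/n2).
    Returns a dict with estimate, t, two-sided p, d, and group sizes.
    """
    values = np.asarray(values, dtype=float)
    case = np.asarray(is_case, dtype=float)
    n1, n2 = int(case.sum()), int((1 - case).sum())
    if n1 < 3 or n2 < 3:
        raise StatsError("each group needs >= 3 subjects")
    cols = [np.ones_like(values), case]
    if age is not None:
        a = np.asarray(age, dtype=float)
        cols.append(a - a.mean())
    X = np.column_stack(cols)
    _check_rank(X, "comparison")
    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    df = len(values) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    if sigma2 <= 0:
        raise StatsError("degenerate residual variance")
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = float(beta[1] / se)
    p = 2 * float(stats.t.sf(abs(t), df))
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    return {"estimate": float(beta[1]), "t": t, "p": p, "d": float(d),
            "df": df, "n1": n1, "n2": n2}


def paired_change_test(values_pre, values_post):
    """One-sample t on post-minus-pre differences."""
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.shape != post.shape:
        raise DataError("pre/post arrays differ in length")
    ok = np.isfinite(pre) & np.isfinite(post)
    d = post[ok] - pre[ok]
    if d.size < 3:
        raise StatsError("need >= 3 complete pairs")
    if np.allclose(d, 0):
        return {"t": 0.0, "p": 1.0, "mean_change": 0.0, "n": int(d.size)}
    res = stats.ttest_1samp(d, 0.0)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "mean_change": float(d.mean()), "n": int(d.size)}


def summary_two_sample_t(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample t from summary statistics, direction
    group 2 minus group 1. Returns ``(t, df, two_sided_p)``."""
    if n1 < 2 or n2 < 2:
        raise StatsError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise StatsError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean2 - mean1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2 * float(stats.t.sf(abs(t), df))
    return float(t), int(df), p
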