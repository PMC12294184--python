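"""Cohort statistics for the radiographic parameters.

Covers the analysis layer applied to per-patient measurement tables:

* observer reliability via the intraclass correlation coefficient (ICC),
  computed from the two-way ANOVA mean-squares decomposition;
* dispersion screening via DBSCAN on standardized features;
* overall group separation (patients with vs without a disease-causing
  variant, DCV) via PERMANOVA on Euclidean distances of z-scored features,
  with Benjamini–Hochberg false-discovery-rate correction across parameters
  and per-parameter Mann–Whitney U tests;
* a bootstrap-validated prediction harness: repeated class-balanced 70/30
  train/test splits of a random-forest or logistic-regression model scored
  by held-out ROC AUC, with per-feature importance distributions.

Permutation p-values are exact (full enumeration of label assignments)
whenever the number of distinct assignments does not exceed the requested
permutation count, and Monte-Carlo with the +1 correction otherwise, so a
reported p is never exactly zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "icc",
    "mann_whitney",
    "permanova",
    "PermanovaResult",
    "fdr_adjust",
    "dbscan_disperse",
    "suggest_eps",
    "bootstrap_validate",
    "ModelReport",
    "zscore",
]

#: largest combined sample size for which the Mann–Whitney p-value is
#: computed by exhaustive enumeration of group assignments
EXACT_MW_LIMIT = 16


def zscore(X) -> np.ndarray:
    """Column-wise z-scoring (population SD); constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc(matrix, form: str = "icc2") -> float:
    """Intraclass correlation coefficient of a subjects × raters matrix.

    Single-measure forms, from the ANOVA mean squares:

    * ``icc1`` — one-way random effects, absolute agreement;
    * ``icc2`` — two-way random effects, absolute agreement (default: the
      appropriate form when both observers and occasions are regarded as
      random samples);
    * ``icc3`` — two-way mixed effects, consistency.

    Returns NaN when the matrix has no variance at all (agreement is then
    undefined).
    """
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("ratings matrix must be at least 2 subjects x 2 raters")
    if not np.isfinite(Y).all():
        raise ValueError("ratings matrix contains missing or non-finite cells")
    n, k = Y.shape
    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    if ss_total == 0:
        return float("nan")
    ss_rows = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))

    form = form.lower()
    if form == "icc1":
        denom = msr + (k - 1) * msw
        return float((msr - msw) / denom) if denom != 0 else float("nan")
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        return float((msr - mse) / denom) if denom != 0 else float("nan")
    if form == "icc3":
        denom = msr + (k - 1) * mse
        return float((msr - mse) / denom) if denom != 0 else float("nan")
    raise ValueError(f"unknown ICC form {form!r}")


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _u_from_rank_sum(rank_sum: float, nx: int) -> float:
    return rank_sum - nx * (nx + 1) / 2.0


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann–Whitney U (of the first sample) with a two-sided p-value.

    For combined sample sizes up to ``EXACT_MW_LIMIT`` the p-value is exact:
    every assignment of the pooled mid-ranks to the two groups is
    enumerated and, using the symmetry of the null distribution of U about
    ``nx·ny/2`` (which holds under mid-rank ties as well), the two-sided
    p is the probability of a U at least as extreme in either tail.
    Larger samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    n = nx + ny
    if n > EXACT_MW_LIMIT:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u_obs = _u_from_rank_sum(float(ranks[:nx].sum()), nx)

    # exhaustive null distribution of U over all C(n, nx) assignments
    us = np.array([
        _u_from_rank_sum(float(ranks[list(idx)].sum()), nx)
        for idx in combinations(range(n), nx)
    ])
    total = len(us)
    mid = nx * ny / 2.0
    lo = min(u_obs, 2 * mid - u_obs)
    hi = max(u_obs, 2 * mid - u_obs)
    eps = 1e-9
    p = (np.count_nonzero(us <= lo + eps) + np.count_nonzero(us >= hi - eps)) / total
    return float(u_obs), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _within_ss(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a batch of label masks.

    *masks* is (batch, groups, n) boolean; returns (batch,) arrays of
    sum_g (sum_{i<j in g} d2_ij) / n_g.
    """
    m = masks.astype(float)
    # per group: m_g D2 m_g^T counts each ordered pair once -> /2
    quad = np.einsum("bgi,ij,bgj->bg", m, d2, m) / 2.0
    return (quad / sizes[None, :]).sum(axis=1)


def permanova(X, labels, n_perm: int = 9999, seed: int = 0,
              standardize: bool = True) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances of (optionally z-scored)
    features.

    The pseudo-F statistic is computed from the pairwise distance matrix:
    ``SS_total = Σ_{i<j} d²_ij / n``, ``SS_within = Σ_g Σ_{i<j∈g} d²_ij /
    n_g``, ``F = (SS_between/(k−1)) / (SS_within/(n−k))``.  When the number
    of distinct label assignments is at most *n_perm* the permutation null
    is enumerated exhaustively and ``p = #{F_perm ≥ F_obs}/N`` (the identity
    assignment included); otherwise *n_perm* random label permutations are
    drawn with *seed* and ``p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = len(labels)
    if X.shape[0] != n:
        raise ValueError("features and labels length mismatch")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(inv)
    if sizes.min() < 2:
        raise ValueError("each group needs at least 2 subjects")

    if standardize:
        X = zscore(X)
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_stat(within: np.ndarray) -> np.ndarray:
        between = ss_total - within
        return (between / (k - 1)) / (within / (n - k))

    obs_mask = np.stack([inv == g for g in range(k)])[None]
    f_obs = float(f_stat(_within_ss(d2, obs_mask, sizes))[0])

    n_distinct = _n_assignments(sizes)
    eps = 1e-12 * max(abs(f_obs), 1.0)
    if n_distinct <= n_perm:
        masks = _enumerate_masks(inv, sizes)
        f_perm = f_stat(_within_ss(d2, masks, sizes))
        p = float(np.count_nonzero(f_perm >= f_obs - eps) / len(f_perm))
        return PermanovaResult(f_obs, p, int(n_distinct), True)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    masks = np.stack([inv[perms] == g for g in range(k)], axis=1)
    f_perm = f_stat(_within_ss(d2, masks, sizes))
    p = float((1 + np.count_nonzero(f_perm >= f_obs - eps)) / (1 + n_perm))
    return PermanovaResult(f_obs, p, n_perm, False)


def _n_assignments(sizes: np.ndarray) -> int:
    n = int(sizes.sum())
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _enumerate_masks(inv: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """All distinct assignments of subjects to groups with the given sizes,
    as (N, groups, n) boolean masks."""
    n = len(inv)
    k = len(sizes)
    out = []

    def rec(remaining: tuple, assignment: dict, g: int):
        if g == k - 1:
            masks = np.zeros((k, n), dtype=bool)
            for gi, members in assignment.items():
                masks[gi, list(members)] = True
            masks[k - 1, list(remaining)] = True
            out.append(masks)
            return
        for members in combinations(remaining, int(sizes[g])):
            rest = tuple(i for i in remaining if i not in members)
            assignment[g] = members
            rec(rest, assignment, g + 1)
        assignment.pop(g, None)

    rec(tuple(range(n)), {}, 0)
    return np.stack(out)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

def suggest_eps(X, min_pts: int = 4, standardize: bool = True) -> float:
    """Heuristic DBSCAN radius: the elbow (maximum curvature) of the sorted
    k-distance curve with k = min_pts - 1."""
    X = np.asarray(X, dtype=float)
    if standardize:
        X = zscore(X)
    from sklearn.neighbors import NearestNeighbors

    k = max(min_pts - 1, 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    kd = np.sort(dist[:, k])
    if len(kd) < 3:
        return float(kd[-1])
    curv = np.diff(kd, 2)
    return float(kd[int(np.argmax(curv)) + 1])


def dbscan_disperse(X, eps: float | None = None, min_pts: int = 4,
                    standardize: bool = True) -> np.ndarray:
    """DBSCAN cluster labels on (optionally z-scored) features; noise
    points are labelled -1.  When *eps* is omitted it is taken from the
    k-distance elbow."""
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    X = np.asarray(X, dtype=float)
    if standardize:
        X = zscore(X)
    if eps is None:
        eps = suggest_eps(X, min_pts=min_pts, standardize=False)
    if eps <= 0:
        raise ValueError("eps must be positive")
    from sklearn.cluster import DBSCAN

    return DBSCAN(eps=eps, min_samples=min_pts).fit(X).labels_


# ---------------------------------------------------------------------------
# bootstrap-validated prediction
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Result of the repeated balanced-split validation harness."""

    model: str
    aucs: np.ndarray            # one held-out AUC per iteration
    importances: pd.DataFrame   # iterations × features
    feature_names: list

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def auc_iqr(self) -> tuple[float, float]:
        return (float(np.percentile(self.aucs, 25)),
                float(np.percentile(self.aucs, 75)))

    @property
    def median_importances(self) -> pd.Series:
        return self.importances.median(axis=0)

    def importance_ranking(self) -> list:
        """Feature names ordered from most to least influential (by median
        importance across iterations)."""
        return list(self.median_importances.sort_values(ascending=False).index)


def _make_model(model: str, seed: int, n_estimators: int):
    if model == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if model == "lr":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        return Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(C=np.inf, max_iter=2000)),  # unpenalized
        ])
    raise ValueError(f"unknown model {model!r} (expected 'rf' or 'lr')")


def _importance(model_name: str, fitted, n_features: int) -> np.ndarray:
    if model_name == "rf":
        return fitted.feature_importances_
    return np.abs(fitted.named_steps["lr"].coef_.ravel())


def bootstrap_validate(X, y, model: str = "rf", n_iter: int = 50,
                       train_frac: float = 0.70, seed: int = 0,
                       n_estimators: int = 500,
                       feature_names: list | None = None) -> ModelReport:
    """Repeatedly down-sample the majority class, split the balanced data
    into stratified train (``train_frac``) and test parts, fit the model
    and score the held-out ROC AUC.

    Importances are the impurity-based feature importances for the random
    forest and absolute coefficients on standardized features for the
    logistic regression.  Iterations whose test split ends up single-class
    are redrawn.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("both classes need at least 2 members")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]

    rng = np.random.default_rng(seed)
    n_min = counts.min()
    idx_by_class = [np.flatnonzero(y_idx == c) for c in (0, 1)]

    aucs, imps = [], []
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_iter):
            for _attempt in range(100):
                it_seed = int(rng.integers(0, 2**31 - 1))
                # balance by down-sampling the majority class
                keep = np.concatenate([
                    np.random.default_rng(it_seed + c).choice(
                        idx_by_class[c], size=n_min, replace=False)
                    for c in (0, 1)
                ])
                Xb, yb = X[keep], y_idx[keep]
                Xtr, Xte, ytr, yte = train_test_split(
                    Xb, yb, train_size=train_frac, stratify=yb,
                    random_state=it_seed % (2**32 - 1))
                if len(np.unique(yte)) == 2:
                    break
            else:  # pragma: no cover - stratified splits always two-class
                raise RuntimeError("could not draw a two-class test split")
            clf = _make_model(model, it_seed, n_estimators)
            clf.fit(Xtr, ytr)
            score = clf.predict_proba(Xte)[:, 1]
            aucs.append(roc_auc_score(yte, score))
            imps.append(_importance(model, clf, X.shape[1]))

    return ModelReport(
        model=model,
        aucs=np.asarray(aucs, dtype=float),
        importances=pd.DataFrame(imps, columns=feature_names),
        feature_names=list(feature_names),
    )
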