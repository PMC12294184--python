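"""Cohort statistics: ICC, Mann–Whitney, PERMANOVA, FDR, DBSCAN and the
bootstrap validation harness, each checked against an independent oracle."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enamelmetrics import (
    bootstrap_validate,
    dbscan_disperse,
    fdr_adjust,
    icc,
    mann_whitney,
    permanova,
)
from enamelmetrics.stats import zscore


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mw_oracle(x, y):
    """Exact two-sided Mann–Whitney p by direct pairwise-count enumeration."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)

    def u_of(idx):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        xs, ys = pooled[sel], pooled[~sel]
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    us = np.array([u_of(idx) for idx in combinations(range(n), nx)])
    u_obs = u_of(range(nx))
    mid = nx * (n - nx) / 2.0
    lo, hi = min(u_obs, 2 * mid - u_obs), max(u_obs, 2 * mid - u_obs)
    p = (np.sum(us <= lo + 1e-9) + np.sum(us >= hi - 1e-9)) / len(us)
    return u_obs, min(p, 1.0)


def permanova_oracle(X, labels):
    """Exhaustive PERMANOVA p via the feature-space ANOVA decomposition
    (equivalent to the distance formulation only for Euclidean distances)."""
    X = zscore(np.asarray(X, float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(labels), len(uniq)
    sizes = [int((labels == g).sum()) for g in uniq]

    def f_of(lab):
        grand = X.mean(axis=0)
        ssw = sum(((X[lab == g] - X[lab == g].mean(axis=0)) ** 2).sum() for g in uniq)
        sst = ((X - grand) ** 2).sum()
        ssb = sst - ssw
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_of(labels)
    fs = []
    # enumerate distinct assignments for the two-group case
    assert k == 2
    for idx in combinations(range(n), sizes[0]):
        lab = np.full(n, uniq[1], dtype=labels.dtype)
        lab[list(idx)] = uniq[0]
        fs.append(f_of(lab))
    fs = np.array(fs)
    p = np.mean(fs >= f_obs - 1e-9 * max(abs(f_obs), 1.0))
    return f_obs, p


def dbscan_oracle(X, eps, min_pts):
    """Textbook neighborhood-expansion DBSCAN."""
    X = np.asarray(X, float)
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbors]
    labels = np.full(n, -2)
    cid = 0
    for i in range(n):
        if labels[i] != -2 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if core[j]:
                for q in neighbors[j]:
                    if labels[q] in (-2, -1):
                        if labels[q] == -2:
                            stack.append(q)
                        labels[q] = cid
        cid += 1
    labels[labels == -2] = -1
    return labels


def same_partition(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mask = a != -1
    pairs_a = (a[mask][:, None] == a[mask][None, :])
    pairs_b = (b[mask][:, None] == b[mask][None, :])
    return np.array_equal(pairs_a, pairs_b)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_identical_columns_perfect_agreement(self):
        Y = np.tile(np.arange(10.0)[:, None], (1, 2))
        assert icc(Y) == pytest.approx(1.0)

    def test_columns_independent_of_subject_near_zero(self, rng):
        Y = rng.normal(size=(4000, 2))
        assert abs(icc(Y)) < 0.05

    def test_variance_ratio_recovered(self, rng):
        subj = rng.normal(0, 3.0, size=(4000, 1))
        Y = subj + rng.normal(0, 1.0, size=(4000, 3))
        assert icc(Y) == pytest.approx(0.9, abs=0.02)

    def test_no_variance_undefined(self):
        assert np.isnan(icc(np.full((5, 2), 7.0)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(min_value=-1e3, max_value=1e3))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 2, size=(30, 1)) + rng.normal(0, 1, size=(30, 3))
        for form in ("icc1", "icc2", "icc3"):
            assert icc(Y + shift, form) == pytest.approx(icc(Y, form), abs=1e-8)

    def test_matches_pingouin(self, rng):
        """Cross-check all three single-measure forms against pingouin."""
        import pandas as pd
        import pingouin as pg

        Y = rng.normal(0, 2, size=(15, 1)) + rng.normal(0, 1, size=(15, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": Y.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")["ICC"]
        assert icc(Y, "icc1") == pytest.approx(ref["ICC(1,1)"], abs=1e-6)
        assert icc(Y, "icc2") == pytest.approx(ref["ICC(A,1)"], abs=1e-6)
        assert icc(Y, "icc3") == pytest.approx(ref["ICC(C,1)"], abs=1e-6)

    def test_reliability_harness_icc_approaches_one_as_jitter_shrinks(self, rng):
        """Duplicated measurements with shrinking jitter push ICC to 1."""
        base = rng.uniform(10, 20, size=50)
        iccs = []
        for jitter in (2.0, 0.5, 0.05):
            Y = base[:, None] + rng.normal(0, jitter, size=(50, 2))
            iccs.append(icc(Y))
        assert iccs[0] < iccs[1] < iccs[2]
        assert iccs[-1] > 0.99


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_n(self, rng):
        for _ in range(30):
            nx = int(rng.integers(2, 5))
            ny = int(rng.integers(2, 5))
            # integer draws force ties into the enumeration
            x = rng.integers(0, 6, size=nx).astype(float)
            y = rng.integers(0, 6, size=ny).astype(float)
            u, p = mann_whitney(x, y)
            u_ref, p_ref = mw_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        from scipy import stats as sps

        x = rng.integers(0, 10, size=30).astype(float)
        y = rng.integers(2, 12, size=25).astype(float)
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class TestPermanova:
    def test_matches_exhaustive_oracle_small_instances(self, rng):
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            X = rng.normal(size=(n1 + n2, 3))
            labels = np.array([0] * n1 + [1] * n2)
            res = permanova(X, labels, n_perm=9999, seed=0)
            f_ref, p_ref = permanova_oracle(X, labels)
            assert res.exhaustive
            assert res.pseudo_f == pytest.approx(f_ref)
            assert res.p_value == pytest.approx(p_ref)

    def test_identical_group_multisets_degenerate(self):
        """Duplicating every point into both groups gives zero between-group
        dispersion: pseudo-F at its analytic value for SS_between = 0."""
        base = np.array([[0.0, 1.0], [2.0, -1.0], [4.0, 0.5]])
        X = np.vstack([base, base])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = permanova(X, labels, n_perm=9999, seed=0)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_separation_small_p(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(6, 1, (10, 3))])
        labels = np.array([0] * 10 + [1] * 10)
        res = permanova(X, labels, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert not res.exhaustive

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(20, 3))
        labels = np.array([0] * 10 + [1] * 10)
        a = permanova(X, labels, n_perm=499, seed=7)
        b = permanova(X, labels, n_perm=499, seed=7)
        assert a == b

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permanova(rng.normal(size=(6, 2)), [0] * 6)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_vector(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_hand_computed_mixed_vector(self):
        # BH by hand: sorted (0.005, 0.04, 0.60) -> (0.015, 0.06, 0.60)
        assert fdr_adjust([0.04, 0.005, 0.60]) == pytest.approx([0.06, 0.015, 0.60])

    def test_all_equal_stay_equal(self):
        out = fdr_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_monotone_capped_and_inflationary(self, ps):
        adj = fdr_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in order stats
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(ps) - 1e-12)  # never below the raw p

    def test_idempotent_on_flat_adjusted_vectors(self):
        adj = fdr_adjust([0.01, 0.02, 0.03])
        assert fdr_adjust(adj) == pytest.approx(adj)


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

class TestDBSCAN:
    def test_two_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(6, 0.2, (15, 2))])
        labels = dbscan_disperse(X, eps=0.8, min_pts=4, standardize=False)
        assert len(set(labels)) == 2
        assert -1 not in labels

    def test_far_point_is_noise(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (12, 2)), [[50.0, 50.0]]])
        labels = dbscan_disperse(X, eps=1.0, min_pts=4, standardize=False)
        assert labels[-1] == -1

    def test_matches_neighborhood_expansion_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 25))
            X = rng.uniform(0, 4, size=(n, 2))
            eps = float(rng.uniform(0.3, 1.2))
            min_pts = int(rng.integers(2, 5))
            ours = dbscan_disperse(X, eps=eps, min_pts=min_pts, standardize=False)
            ref = dbscan_oracle(X, eps, min_pts)
            assert same_partition(ours, ref)

    def test_invalid_params_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            dbscan_disperse(X, eps=-1.0, min_pts=4)
        with pytest.raises(ValueError):
            dbscan_disperse(X, eps=1.0, min_pts=1)


# ---------------------------------------------------------------------------
# bootstrap validation harness
# ---------------------------------------------------------------------------

class TestBootstrapValidate:
    def _cohort(self, rng, shift):
        n = 24
        X0 = rng.normal(0, 1, size=(n, 3))
        X1 = rng.normal(0, 1, size=(n, 3)) + shift
        return np.vstack([X0, X1]), np.array([0] * n + [1] * n)

    def test_median_within_iqr(self, rng):
        X, y = self._cohort(rng, np.array([0.0, 1.5, 1.0]))
        rep = bootstrap_validate(X, y, model="rf", n_iter=10, seed=1, n_estimators=50)
        q1, q3 = rep.auc_iqr
        assert q1 <= rep.median_auc <= q3
        assert rep.aucs.shape == (10,)
        assert np.all((rep.aucs >= 0) & (rep.aucs <= 1))

    def test_reproducible_from_seed(self, rng):
        X, y = self._cohort(rng, np.array([0.0, 1.0, 0.5]))
        a = bootstrap_validate(X, y, model="lr", n_iter=8, seed=3)
        b = bootstrap_validate(X, y, model="lr", n_iter=8, seed=3)
        assert np.array_equal(a.aucs, b.aucs)

    def test_unbalanced_input_is_balanced_by_downsampling(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (8, 2))])
        y = np.array([0] * 30 + [1] * 8)
        rep = bootstrap_validate(X, y, model="rf", n_iter=5, seed=0, n_estimators=50)
        assert rep.median_auc > 0.7

    def test_single_member_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            bootstrap_validate(X, np.array([0, 0, 0, 0, 1]))

    def test_importance_ranking_reflects_effect_sizes(self, rng):
        """A feature with no group shift ranks below strongly shifted ones
        in both models."""
        X, y = self._cohort(rng, np.array([0.0, 2.0, 1.5]))
        for model in ("rf", "lr"):
            rep = bootstrap_validate(X, y, model=model, n_iter=15, seed=5,
                                     n_estimators=100,
                                     feature_names=["ea", "da", "edmr"])
            ranking = rep.importance_ranking()
            assert ranking.index("ea") == 2
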