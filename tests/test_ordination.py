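"""PCoA / aPCoA geometry, PERMANOVA inference and univariate tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from guildflow.diversity import DistanceMatrix
from guildflow.ordination import (
    apcoa,
    pcoa,
    permanova,
    univariate_compare,
)

from oracles import permanova_exact_p_oracle, permanova_f_oracle


def euclid_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    ids = ids or tuple(f"s{i}" for i in range(len(points)))
    return DistanceMatrix(tuple(ids), squareform(pdist(points)), "euclidean")


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = euclid_dm(np.array([[0.0], [1.0], [3.0]]))
        res = pcoa(d)
        assert (res.eigenvalues > 1e-9).sum() == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)
        rec = squareform(pdist(res.coordinates[:, :1]))
        assert np.allclose(rec, d.values, atol=1e-9)

    def test_all_zero_distances_degenerate(self):
        d = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        res = pcoa(d)
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_isometry(self):
        rng = np.random.default_rng(5)
        d = euclid_dm(rng.normal(size=(5, 3)))
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d.values, atol=1e-9)

    def test_axes_ordered_by_eigenvalue(self):
        rng = np.random.default_rng(11)
        res = pcoa(euclid_dm(rng.normal(size=(8, 4))))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)


class TestApcoa:
    def test_intercept_only_equals_pcoa(self):
        rng = np.random.default_rng(2)
        d = euclid_dm(rng.normal(size=(6, 3)))
        plain = pcoa(d)
        adj = apcoa(d, pd.DataFrame(index=list(d.ids)))
        assert np.allclose(np.abs(plain.coordinates), np.abs(adj.coordinates), atol=1e-8)

    def test_subject_adjustment_reveals_treatment(self):
        """Large subject offsets drown a small treatment shift in plain PCoA;
        removing subject effects puts the treatment contrast on PC1."""
        rng = np.random.default_rng(3)
        n_subj = 8
        offsets = rng.normal(scale=10.0, size=(n_subj, 2))
        pts, treat, subj = [], [], []
        for s in range(n_subj):
            for t in (0, 1):
                pts.append(offsets[s] + np.array([1.5 * t, 0]) + rng.normal(scale=0.1, size=2))
                treat.append(t)
                subj.append(s)
        pts = np.asarray(pts)
        d = euclid_dm(pts)
        cov = pd.get_dummies(pd.Series(subj, index=list(d.ids)), dtype=float).iloc[:, :-1]
        adj = apcoa(d, cov)
        treat = np.asarray(treat)
        pc1 = adj.coordinates[:, 0]
        gap = abs(pc1[treat == 1].mean() - pc1[treat == 0].mean())
        spread = pc1[treat == 1].std() + pc1[treat == 0].std()
        assert gap > 3 * spread  # clean separation after adjustment
        # unadjusted PC1 is dominated by subject, not treatment
        plain_pc1 = pcoa(d).coordinates[:, 0]
        gap_plain = abs(plain_pc1[treat == 1].mean() - plain_pc1[treat == 0].mean())
        assert gap_plain < plain_pc1.std()

    def test_adjusting_for_grouping_removes_separation(self):
        rng = np.random.default_rng(4)
        groups = np.repeat([0, 1], 6)
        pts = rng.normal(size=(12, 2)) + np.outer(groups, [5.0, 0.0])
        d = euclid_dm(pts)
        cov = pd.DataFrame({"group": groups.astype(float)}, index=list(d.ids))
        adj = apcoa(d, cov)
        for ax in range(adj.coordinates.shape[1]):
            v = adj.coordinates[:, ax]
            assert abs(v[groups == 1].mean() - v[groups == 0].mean()) < 0.3

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(6)
        d = euclid_dm(rng.normal(size=(5, 2)))
        cov = pd.DataFrame(
            {"x": [1, 2, 3, 4, 5], "x_copy": [2, 4, 6, 8, 10]},
            index=list(d.ids), dtype=float,
        )
        with pytest.raises(ValueError, match="x_copy"):
            apcoa(d, cov)


class TestPermanova:
    def test_exact_enumeration_matches_oracle(self):
        """6 samples: full enumeration equals the independent loop oracle."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        d = euclid_dm(pts)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, labels, exact=True, n_permutations=0)
        want = permanova_exact_p_oracle(d.values, labels)
        assert res.p_value == pytest.approx(want, abs=1e-12)
        assert res.pseudo_F == pytest.approx(
            permanova_f_oracle(d.values, labels), abs=1e-10
        )

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.2
        d = euclid_dm(pts)
        labels = ["a"] * 3 + ["b"] * 3
        exact = permanova(d, labels, exact=True).p_value
        mc = permanova(d, labels, n_permutations=20000, seed=1).p_value
        assert mc == pytest.approx(exact, abs=0.02)

    def test_label_renaming_invariance_and_determinism(self):
        rng = np.random.default_rng(10)
        d = euclid_dm(rng.normal(size=(10, 3)))
        labels = ["x"] * 5 + ["y"] * 5
        r1 = permanova(d, labels, n_permutations=499, seed=3)
        r2 = permanova(d, ["y"] * 5 + ["x"] * 5, n_permutations=499, seed=3)
        r3 = permanova(d, labels, n_permutations=499, seed=3)
        assert r1.p_value == r2.p_value == r3.p_value
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)

    def test_p_never_zero_and_r2_consistent(self):
        pts = np.vstack([np.zeros((4, 2)), np.ones((4, 2)) * 50])
        d = euclid_dm(pts)
        res = permanova(d, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=0)
        assert res.p_value >= 1.0 / 100.0
        assert 0.0 <= res.R2 <= 1.0
        assert res.R2 > 0.95

    def test_stratified_scheme_gains_paired_power(self):
        """Subject offsets + small treatment shift: within-subject permutation
        detects the shift where free permutation does not."""
        rng = np.random.default_rng(12)
        n_subj = 10
        offsets = rng.normal(scale=8.0, size=(n_subj, 2))
        pts, tp, subj = [], [], []
        for s in range(n_subj):
            for t in (0, 1):
                pts.append(offsets[s] + np.array([1.0 * t, 0]) + rng.normal(scale=0.15, size=2))
                tp.append("pre" if t == 0 else "post")
                subj.append(f"S{s}")
        d = euclid_dm(np.asarray(pts))
        strat = permanova(
            d, tp, scheme="stratified_by_subject", strata=subj,
            n_permutations=999, seed=5,
        )
        free = permanova(d, tp, scheme="free", n_permutations=999, seed=5)
        assert strat.p_value < 0.05
        assert free.p_value > strat.p_value

    def test_stratified_requires_strata(self):
        d = euclid_dm(np.random.default_rng(0).normal(size=(6, 2)))
        with pytest.raises(ValueError, match="strata"):
            permanova(d, ["a", "a", "a", "b", "b", "b"], scheme="stratified_by_subject")

    def test_type_one_error_nominal(self):
        """Null rejection rate at alpha=0.05 over 400 simulated datasets stays
        inside the 95% binomial band (the full 2,000-run check lives in the
        acceptance suite)."""
        rng = np.random.default_rng(77)
        nsim, rej = 400, 0
        for _ in range(nsim):
            d = euclid_dm(rng.normal(size=(12, 3)))
            p = permanova(
                d, ["a"] * 6 + ["b"] * 6, n_permutations=99,
                seed=int(rng.integers(2**31)),
            ).p_value
            rej += p <= 0.05
        lo, hi = stats.binom.interval(0.95, nsim, 0.05)
        assert lo <= rej <= hi


class TestUnivariate:
    def test_friedman_unanimous_two_conditions(self):
        """k=2 with condition 2 larger for every one of 5 subjects: Q = n."""
        data = np.array([[1, 2], [3, 4], [0, 5], [2, 6], [1, 3]])
        res = univariate_compare(data, test="friedman")
        assert res.statistic == pytest.approx(5.0)
        assert res.n == 5

    def test_friedman_matches_scipy_for_three_conditions(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(12, 3))
        res = univariate_compare(data, test="friedman")
        q, p = stats.friedmanchisquare(data[:, 0], data[:, 1], data[:, 2])
        assert res.statistic == pytest.approx(q)
        assert res.p_value == pytest.approx(p)

    def test_mann_whitney_identical_groups(self):
        res = univariate_compare([1, 2, 3], [1, 2, 3], test="mann_whitney")
        assert res.p_value == pytest.approx(1.0)

    def test_wilcoxon_constant_shift_smallest_exact_p(self):
        x = np.arange(6, dtype=float)
        res = univariate_compare(x + 1.0, x, test="wilcoxon_signed_rank")
        assert res.p_value == pytest.approx(2 / 64)  # 2 * 2^-6

    def test_wilcoxon_all_zero_differences(self):
        res = univariate_compare([1.0, 2.0], [1.0, 2.0], test="wilcoxon_signed_rank")
        assert res.p_value == 1.0
        assert res.n == 0

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            univariate_compare([1], [2], test="t_test")
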