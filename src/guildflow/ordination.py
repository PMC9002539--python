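"""Ordination and permutation inference on distance matrices.

Principal coordinates analysis (classical metric MDS via Gower centering),
covariate-adjusted PCoA (projecting covariate effects out of the centered
inner-product matrix before eigendecomposition), distance-based PERMANOVA
with free and subject-stratified permutation schemes suited to paired
designs, and the nonparametric univariate tests used throughout the
pipeline (Wilcoxon signed-rank, Mann-Whitney, Friedman).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "TestResult",
    "pcoa",
    "apcoa",
    "permanova",
    "univariate_compare",
]


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates on the positive-eigenvalue axes."""

    sample_ids: tuple
    coordinates: np.ndarray  # samples x positive axes, descending eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per positive axis, over positive sum
    negative_eigenvalue_mass: float  # |sum of negative eigenvalues|

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    R2: float
    scheme: str
    n: int

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_F,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "R2": self.R2,
            "scheme": self.scheme,
            "n": self.n,
        }


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
        }


def _gower_center(d_sq: np.ndarray) -> np.ndarray:
    n = d_sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_sq @ j


_EIG_TOL = 1e-9


def _eigen_ordination(
    g: np.ndarray, sample_ids: tuple
) -> OrdinationResult:
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scale = max(abs(w[0]), abs(w[-1]), 1.0)
    w = np.where(np.abs(w) < _EIG_TOL * scale, 0.0, w)
    pos = w > 0
    coords = v[:, pos] * np.sqrt(w[pos])
    pos_sum = w[pos].sum()
    prop = w[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    if not pos.any():
        coords = np.zeros((len(sample_ids), 0))
    return OrdinationResult(
        sample_ids=tuple(sample_ids),
        coordinates=coords,
        eigenvalues=w,
        proportion_explained=prop,
        negative_eigenvalue_mass=float(abs(w[w < 0].sum())),
    )


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinates analysis of a distance matrix."""
    g = _gower_center(d.values**2)
    return _eigen_ordination(g, d.ids)


def apcoa(d: DistanceMatrix, covariates: pd.DataFrame) -> OrdinationResult:
    """Covariate-adjusted PCoA.

    The Gower-centered inner-product matrix is pre- and post-multiplied by
    the residual-maker H = I - X(X'X)^-1 X' of the covariate design matrix
    (intercept added), then eigendecomposed; the ordination shows variation
    orthogonal to the covariates (e.g. subject identity in a paired design).
    """
    ids = list(d.ids)
    cov = covariates.loc[ids] if set(ids) <= set(covariates.index) else covariates
    if cov.shape[0] != len(ids):
        raise ValueError("covariate rows do not align with distance-matrix samples")
    x = np.column_stack([np.ones(len(ids)), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name offending columns via QR pivoting on the non-intercept part
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [
            cov.columns[i - 1]
            for i in range(1, x.shape[1])
            if diag[i] < 1e-8 * diag.max()
        ]
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    h = np.eye(len(ids)) - x @ np.linalg.solve(x.T @ x, x.T)
    g = _gower_center(d.values**2)
    return _eigen_ordination(h @ g @ h, d.ids)


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_within(d_sq: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray) -> float:
    ssw = 0.0
    for g, n_g in enumerate(group_sizes):
        mask = codes == g
        ssw += d_sq[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ssw


def _pseudo_f(ssw: float, ss_total: float, n: int, k: int) -> float:
    ssb = ss_total - ssw
    denom = ssw / (n - k)
    if denom <= 0:
        return np.inf
    return (ssb / (k - 1)) / denom


def permanova(
    d: DistanceMatrix,
    groups,
    scheme: str = "free",
    strata=None,
    n_permutations: int = 9999,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaResult:
    """Distance-based PERMANOVA with permutation p-value.

    ``scheme='free'`` permutes group labels over all samples (appropriate
    when samples are exchangeable, e.g. one sample per subject).
    ``scheme='stratified_by_subject'`` permutes labels independently within
    each stratum (subject), the exchangeable unit of a paired pre/post
    design; ``strata`` is then required. ``exact=True`` enumerates every
    permutation instead of Monte-Carlo sampling (small n only). The
    Monte-Carlo p-value uses the (1 + hits)/(1 + n_permutations) convention
    and never returns 0.
    """
    groups = np.asarray(list(groups))
    ids = list(d.ids)
    if len(groups) != len(ids):
        raise ValueError("group labels do not align with distance-matrix samples")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    sizes = np.bincount(codes)
    if k < 2 or (sizes < 2).any():
        raise ValueError("need >=2 groups with >=2 samples each")
    if scheme not in ("free", "stratified_by_subject"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if scheme == "stratified_by_subject" and strata is None:
        raise ValueError("stratified_by_subject scheme requires strata")

    n = len(ids)
    d_sq = d.values**2
    ss_total = d_sq.sum() / (2.0 * n)
    ssw_obs = _ss_within(d_sq, codes, sizes)
    f_obs = _pseudo_f(ssw_obs, ss_total, n, k)
    r2 = (ss_total - ssw_obs) / ss_total if ss_total > 0 else 0.0

    if scheme == "stratified_by_subject":
        strata = np.asarray(list(strata))
        stratum_idx = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        singles = [idx for idx in stratum_idx if len(idx) == 1]
        if singles:
            logger.warning(
                "stratified permanova: %d single-sample stratum(-a) held fixed",
                len(singles),
            )
        stratum_idx = [idx for idx in stratum_idx if len(idx) > 1]

    rng = np.random.default_rng(seed)
    if exact:
        f_perm = []
        if scheme == "free":
            for perm in itertools.permutations(range(n)):
                f_perm.append(
                    _pseudo_f(
                        _ss_within(d_sq, codes[list(perm)], sizes), ss_total, n, k
                    )
                )
        else:
            per_stratum = [
                list(itertools.permutations(idx)) for idx in stratum_idx
            ]
            for combo in itertools.product(*per_stratum):
                c = codes.copy()
                for idx, perm in zip(stratum_idx, combo):
                    c[list(perm)] = codes[idx]
                f_perm.append(_pseudo_f(_ss_within(d_sq, c, sizes), ss_total, n, k))
        f_perm = np.asarray(f_perm)
        n_perm = len(f_perm)
        p = float((f_perm >= f_obs - 1e-12).sum()) / n_perm
    else:
        hits = 0
        for _ in range(n_permutations):
            if scheme == "free":
                c = codes[rng.permutation(n)]
            else:
                c = codes.copy()
                for idx in stratum_idx:
                    c[idx] = codes[idx[rng.permutation(len(idx))]]
            if _pseudo_f(_ss_within(d_sq, c, sizes), ss_total, n, k) >= f_obs - 1e-12:
                hits += 1
        n_perm = n_permutations
        p = (1.0 + hits) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=int(n_perm),
        R2=float(r2),
        scheme=scheme,
        n=n,
    )


# ---------------------------------------------------------------------------
# univariate tests


def _friedman(data: np.ndarray) -> tuple[float, float, int]:
    """Friedman rank statistic with tie correction; supports k >= 2.

    ``data`` is subjects x conditions. Returns (Q, p, n_subjects); p from the
    chi-square approximation with k - 1 degrees of freedom.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("friedman needs a subjects x conditions array, k >= 2")
    data = data[~np.isnan(data).any(axis=1)]
    n, k = data.shape
    if n < 2:
        raise ValueError("friedman needs >=2 complete subjects")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rj = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
    # tie correction: C = 1 - sum(t^3 - t) / (n (k^3 - k))
    tie_sum = 0.0
    for row in data:
        _, cnt = np.unique(row, return_counts=True)
        tie_sum += float((cnt**3 - cnt).sum())
    c = 1.0 - tie_sum / (n * (k**3 - k))
    if c <= 0:
        return 0.0, 1.0, n  # all rows fully tied
    q /= c
    p = float(stats.chi2.sf(q, k - 1))
    return float(q), min(max(p, np.finfo(float).tiny), 1.0), n


def univariate_compare(x, y=None, test: str = "wilcoxon_signed_rank") -> TestResult:
    """Two-tailed nonparametric comparison.

    wilcoxon_signed_rank: paired ``x`` vs ``y``; zero differences are dropped
    (Wilcoxon's rule, count logged) and an all-zero input returns p = 1.
    mann_whitney: independent ``x`` vs ``y``. friedman: ``x`` is a subjects x
    conditions array (``y`` ignored); supports k = 2, where the statistic
    reduces to Q = n under a unanimous ordering.
    """
    if test == "wilcoxon_signed_rank":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("wilcoxon needs complete pairs")
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        diffs = x - y
        n_zero = int((diffs == 0).sum())
        if n_zero:
            logger.warning("wilcoxon: dropped %d zero difference(s)", n_zero)
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            logger.warning("wilcoxon: all differences zero; p = 1")
            return TestResult(test, 0.0, 1.0, 0)
        stat, p = stats.wilcoxon(nz, alternative="two-sided")
        return TestResult(test, float(stat), float(min(p, 1.0)), len(nz))
    if test == "mann_whitney":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(test, float(stat), float(min(p, 1.0)), len(x) + len(y))
    if test == "friedman":
        q, p, n = _friedman(x)
        return TestResult(test, q, p, n)
    raise ValueError(f"unknown test {test!r}")
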