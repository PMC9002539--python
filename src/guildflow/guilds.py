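"""Co-abundance guild analysis.

ASVs present in more than half of the samples ("prevalent") are clustered
into guilds — groups with co-abundant behaviour across samples, treated as
putative functional units. Pairwise association between ASVs is measured by
repeated-measures correlation (Bland-Altman): the Pearson correlation of
residuals after removing each subject's mean, which isolates within-subject
covariation in a paired design. Correlations are mapped to distances
d = (1 - r)/2, an average-linkage tree is built, and the tree is traversed
dichotomically from the root: a node is accepted as a guild when the minimum
pairwise correlation among its members exceeds a threshold, otherwise the
traversal descends into its two children. Guild abundance is the
arcsine-square-root transformed sum of member relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import AsvCountTable, StudyDesign
from .ordination import TestResult, univariate_compare

logger = logging.getLogger(__name__)

__all__ = [
    "RelAbundanceTable",
    "RmCorrResult",
    "GuildAssignment",
    "GuildAbundanceTable",
    "prevalence_filter",
    "to_relative",
    "rm_correlation",
    "rm_correlation_matrix",
    "critical_r",
    "guild_cluster",
    "guild_abundance",
    "compare_guilds",
]


@dataclass(frozen=True)
class RelAbundanceTable:
    """Relative abundances (samples x ASVs), optionally arcsine-sqrt scaled.

    Proportions are always computed against the full sample total, so a
    prevalent-ASV subset still holds proportions of the whole community.
    """

    data: pd.DataFrame
    transform: str = "none"  # {"none", "arcsine_sqrt"}
    full_community: bool = True  # rows sum to 1 only when the table is complete

    def __post_init__(self) -> None:
        if self.transform not in ("none", "arcsine_sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")
        arr = self.data.to_numpy(dtype=float)
        if self.transform == "none":
            if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
                raise ValueError("proportions outside [0, 1]")
            if self.full_community:
                sums = arr.sum(axis=1)
                if np.abs(sums - 1.0).max(initial=0.0) > 1e-9:
                    raise ValueError("rows of a full relative-abundance table must sum to 1")
        else:
            if (arr < -1e-12).any() or (arr > np.pi / 2 + 1e-12).any():
                raise ValueError("arcsine-sqrt values outside [0, pi/2]")

    def untransformed(self) -> pd.DataFrame:
        if self.transform == "none":
            return self.data
        return np.sin(self.data) ** 2

    def restrict(self, asv_ids) -> "RelAbundanceTable":
        return RelAbundanceTable(
            self.data[list(asv_ids)], self.transform, full_community=False
        )


def prevalence_filter(
    table: AsvCountTable, min_prevalence: float = 0.5
) -> tuple[AsvCountTable, pd.Series]:
    """Keep ASVs present (count > 0) in strictly more than ``min_prevalence``
    of the samples; returns the filtered table and the prevalence vector."""
    if not (0.0 < min_prevalence < 1.0):
        raise ValueError("min_prevalence must be in (0, 1)")
    prevalence = (table.data > 0).mean(axis=0)
    keep = prevalence > min_prevalence
    if not keep.any():
        raise ValueError("no ASV passes the prevalence filter")
    return AsvCountTable(table.data.loc[:, keep]), prevalence


def to_relative(table: AsvCountTable, transform: str = "none") -> RelAbundanceTable:
    """Counts to per-sample proportions, optionally arcsine-sqrt transformed."""
    totals = table.sample_totals().to_numpy().astype(float)
    if (totals <= 0).any():
        raise ValueError("sample with zero total reads")
    p = table.data.astype(float).div(totals, axis=0)
    if transform == "arcsine_sqrt":
        p = np.arcsin(np.sqrt(p.clip(0.0, 1.0)))
    return RelAbundanceTable(p, transform)


# ---------------------------------------------------------------------------
# repeated-measures (within-subject) correlation


@dataclass(frozen=True)
class RmCorrResult:
    r: float
    df: int
    p_value: float
    n_obs: int
    k_subjects: int
    valid: bool = True


def _center_by_subject(df: pd.DataFrame, subjects: np.ndarray) -> pd.DataFrame:
    return df - df.groupby(subjects).transform("mean")


def rm_correlation(x, y, subject_ids) -> RmCorrResult:
    """Repeated-measures correlation of two variables observed repeatedly on
    the same subjects: Pearson correlation of subject-mean-centered residuals
    with df = N - k - 1 (N observations, k subjects). Subjects contributing a
    single complete observation are dropped with a warning."""
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float)})
    subjects = np.asarray(list(subject_ids))
    ok = ~df.isna().any(axis=1)
    df, subjects = df[ok.to_numpy()], subjects[ok.to_numpy()]
    counts = pd.Series(subjects).value_counts()
    keep_subj = set(counts.index[counts >= 2])
    dropped = len(counts) - len(keep_subj)
    if dropped:
        logger.warning("rm_correlation: dropped %d single-observation subject(s)", dropped)
    mask = np.array([s in keep_subj for s in subjects])
    df, subjects = df[mask], subjects[mask]
    n, k = len(df), len(keep_subj)
    if k < 2 or n - k - 1 < 1:
        raise ValueError("rm_correlation needs >=2 subjects with >=2 observations")
    resid = _center_by_subject(df, subjects)
    sx, sy = resid["x"].to_numpy(), resid["y"].to_numpy()
    if np.allclose(sx, 0) or np.allclose(sy, 0):
        return RmCorrResult(np.nan, n - k - 1, np.nan, n, k, valid=False)
    r = float(np.corrcoef(sx, sy)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    ddof = n - k - 1
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(ddof / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), ddof))
    return RmCorrResult(r, ddof, min(p, 1.0), n, k)


def rm_correlation_matrix(
    data: pd.DataFrame, subject_ids
) -> tuple[pd.DataFrame, int]:
    """All-pairs repeated-measures correlation over the columns of ``data``
    (complete observations only). Returns (R, df). Columns with zero residual
    variance get NaN rows/columns."""
    subjects = np.asarray(list(subject_ids))
    resid = _center_by_subject(data, subjects).to_numpy(dtype=float)
    n, k = data.shape[0], len(pd.unique(subjects))
    ddof = n - k - 1
    if ddof < 1:
        raise ValueError("not enough observations for repeated-measures correlation")
    sd = resid.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(resid, rowvar=False)
    r[np.isclose(sd, 0), :] = np.nan
    r[:, np.isclose(sd, 0)] = np.nan
    return pd.DataFrame(r, index=data.columns, columns=data.columns), ddof


# ---------------------------------------------------------------------------
# dichotomic tree-based guild identification


@dataclass(frozen=True)
class GuildAssignment:
    """Partition of prevalent ASVs into guilds, numbered from 1 by descending
    total abundance; members below size or correlation criteria are left in
    ``unassigned``. ``audit`` records every traversal decision."""

    guild_members: dict  # guild number -> list of ASV ids
    unassigned: tuple
    audit: tuple = field(compare=False, default=())

    @property
    def assignment(self) -> dict:
        return {a: g for g, members in self.guild_members.items() for a in members}

    @property
    def n_guilds(self) -> int:
        return len(self.guild_members)

    def labels_for(self, asv_ids) -> np.ndarray:
        """Integer labels per ASV; unassigned ASVs get unique negative labels
        (each its own singleton cluster, for partition comparisons)."""
        amap = self.assignment
        out = []
        neg = 0
        for a in asv_ids:
            if a in amap:
                out.append(amap[a])
            else:
                neg -= 1
                out.append(neg)
        return np.asarray(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"asv_id": a, "guild_id": g}
            for g, members in self.guild_members.items()
            for a in members
        ]
        rows += [{"asv_id": a, "guild_id": 0} for a in self.unassigned]
        return pd.DataFrame(rows)


def _min_pairwise_r(r: np.ndarray, idx: list[int]) -> float:
    sub = r[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].min()) if len(idx) > 1 else 1.0


def critical_r(df: int, alpha: float = 0.05) -> float:
    """One-sided critical value of a correlation coefficient at ``alpha``
    given its t-distribution null with ``df`` degrees of freedom."""
    t = stats.t.ppf(1.0 - alpha, df)
    return float(t / np.sqrt(df + t * t))


def guild_cluster(
    abund: RelAbundanceTable,
    subject_ids,
    min_guild_size: int = 2,
    r_threshold: float | None = None,
    linkage: str = "average",
) -> GuildAssignment:
    """Cluster prevalent ASVs into guilds.

    Pairwise repeated-measures correlations r are mapped to distances
    d = (1 - r)/2; an agglomerative tree (default average linkage) is
    traversed top-down, accepting a node as a guild when the minimum pairwise
    r among its members strictly exceeds ``r_threshold`` and splitting into
    its two children otherwise. By default the threshold is the one-sided
    95% critical value of r at the repeated-measures df — i.e. every pair in
    an accepted guild is significantly positively correlated; with the
    handful of within-subject degrees of freedom a paired design provides,
    a raw threshold of 0 is routinely crossed by sampling noise alone and
    over-merges independent blocks. Accepted nodes smaller than
    ``min_guild_size`` are left unassigned, as are ASVs with undefined
    correlations (zero within-subject variance). Guilds are numbered by
    descending summed relative abundance; ties break on lower ASV index.
    """
    if abund.data.shape[1] < 3:
        raise ValueError("guild clustering needs >=3 ASVs")
    r_full, ddof = rm_correlation_matrix(abund.data, subject_ids)
    if r_threshold is None:
        r_threshold = critical_r(ddof)
    bad = r_full.columns[r_full.isna().all(axis=0)]
    if len(bad):
        logger.warning(
            "guild_cluster: %d ASV(s) with undefined correlation left unassigned: %s",
            len(bad), list(bad),
        )
    cols = [c for c in abund.data.columns if c not in set(bad)]
    r = r_full.loc[cols, cols].to_numpy()
    np.fill_diagonal(r, 1.0)
    dist = (1.0 - r) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    root = hierarchy.to_tree(z)

    audit: list[dict] = []
    accepted: list[list[int]] = []

    def visit(node) -> None:
        idx = node.pre_order(lambda leaf: leaf.id)
        min_r = _min_pairwise_r(r, idx)
        if min_r > r_threshold:
            audit.append(
                {"height": float(node.dist), "n": len(idx), "min_r": min_r,
                 "decision": "accept"}
            )
            accepted.append(idx)
        elif node.is_leaf():
            audit.append(
                {"height": 0.0, "n": 1, "min_r": min_r, "decision": "accept"}
            )
            accepted.append(idx)
        else:
            audit.append(
                {"height": float(node.dist), "n": len(idx), "min_r": min_r,
                 "decision": "split"}
            )
            visit(node.get_left())
            visit(node.get_right())

    visit(root)

    unassigned = list(bad)
    groups: list[list[str]] = []
    for idx in accepted:
        members = [cols[i] for i in idx]
        if len(members) < min_guild_size:
            unassigned.extend(members)
        else:
            groups.append(members)

    # number by descending summed (untransformed) abundance
    untr = abund.untransformed()
    order_index = {a: i for i, a in enumerate(abund.data.columns)}
    keyed = sorted(
        groups,
        key=lambda m: (-float(untr[m].to_numpy().sum()), min(order_index[a] for a in m)),
    )
    guild_members = {i + 1: sorted(m, key=order_index.get) for i, m in enumerate(keyed)}
    return GuildAssignment(
        guild_members=guild_members,
        unassigned=tuple(sorted(unassigned, key=order_index.get)),
        audit=tuple(audit),
    )


# ---------------------------------------------------------------------------
# guild abundance and group comparisons


@dataclass(frozen=True)
class GuildAbundanceTable:
    """Samples x guilds; arcsine-sqrt of the summed member proportions."""

    data: pd.DataFrame  # columns "Guild 1"... values in [0, pi/2]

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if (arr < -1e-12).any() or (arr > np.pi / 2 + 1e-12).any():
            raise ValueError("guild abundances outside [0, pi/2]")

    @property
    def guild_ids(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def guild_abundance(
    abund: RelAbundanceTable, assignment: GuildAssignment
) -> GuildAbundanceTable:
    """Per sample and guild: arcsine-sqrt of the summed untransformed member
    proportions (sum first, then transform)."""
    untr = abund.untransformed()
    cols = {}
    for g, members in assignment.guild_members.items():
        if not members:
            raise ValueError(f"guild {g} has no members")
        missing = set(members) - set(untr.columns)
        if missing:
            raise ValueError(f"guild {g} members missing from table: {sorted(missing)}")
        s = untr[members].sum(axis=1).clip(0.0, 1.0)
        cols[f"Guild {g}"] = np.arcsin(np.sqrt(s))
    return GuildAbundanceTable(pd.DataFrame(cols, index=untr.index))


def compare_guilds(
    gtable: GuildAbundanceTable,
    design: StudyDesign,
    contrast: str,
    group: str | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-guild group comparison.

    ``contrast='pre_vs_post'`` runs a two-tailed Wilcoxon matched-pairs
    signed-ranks test within taster ``group``, using subjects with both
    timepoints. ``contrast='NT_vs_ST'`` runs a two-tailed Mann-Whitney test
    at ``timepoint``. Output flags significance at p < 0.05 and a trend at
    p < 0.1.
    """
    meta = design.data.loc[gtable.data.index]
    rows = []
    if contrast == "pre_vs_post":
        if group is None:
            raise ValueError("pre_vs_post contrast requires a taster group")
        sub = meta[meta["taster_status"] == group]
        pre = sub[sub["timepoint"] == "pre"].set_index("subject_id")
        post = sub[sub["timepoint"] == "post"].set_index("subject_id")
        common = pre.index.intersection(post.index)
        if len(common) == 0:
            raise ValueError("no complete subject pairs for paired contrast")
        pre_samples = [
            sub[(sub["subject_id"] == s) & (sub["timepoint"] == "pre")].index[0]
            for s in common
        ]
        post_samples = [
            sub[(sub["subject_id"] == s) & (sub["timepoint"] == "post")].index[0]
            for s in common
        ]
        for guild in gtable.guild_ids:
            res = univariate_compare(
                gtable.data.loc[pre_samples, guild].to_numpy(),
                gtable.data.loc[post_samples, guild].to_numpy(),
                test="wilcoxon_signed_rank",
            )
            rows.append(_guild_row(guild, res))
    elif contrast == "NT_vs_ST":
        if timepoint is None:
            raise ValueError("NT_vs_ST contrast requires a timepoint")
        sub = meta[meta["timepoint"] == timepoint]
        nt = sub[sub["taster_status"] == "NT"].index
        st = sub[sub["taster_status"] == "ST"].index
        if len(nt) == 0 or len(st) == 0:
            raise ValueError("both taster groups needed for NT_vs_ST contrast")
        for guild in gtable.guild_ids:
            res = univariate_compare(
                gtable.data.loc[nt, guild].to_numpy(),
                gtable.data.loc[st, guild].to_numpy(),
                test="mann_whitney",
            )
            rows.append(_guild_row(guild, res))
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return pd.DataFrame(rows)


def _guild_row(guild: str, res: TestResult) -> dict:
    return {
        "guild_id": guild,
        "test": res.test,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n": res.n,
        "significant_05": res.p_value < 0.05,
        "trend_10": res.p_value < 0.1,
    }
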