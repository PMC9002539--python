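"""Rarefaction, alpha diversity and UniFrac beta diversity.

The phylogenetic metrics (Faith's PD, unweighted and weighted UniFrac) are
computed from a single postorder pass that tabulates, for every branch, the
read total of each sample descending through that branch. Unweighted UniFrac
is the fraction of branch length unique to one of the two communities;
weighted UniFrac sums branch length times the absolute difference in the
fraction of each sample's reads descending through the branch (raw by
default, with an optional standard normalizer). Faith's PD follows the
rooted convention: the minimal spanning subtree always includes the root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AsvCountTable, PhylogeneticTree

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "rarefy",
    "alpha_diversity",
    "alpha_diversity_table",
    "unifrac",
    "faith_pd",
    "ALPHA_METRICS",
]

ALPHA_METRICS = ("observed_asvs", "shannon", "pielou_evenness", "faith_pd")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with a metric tag."""

    ids: tuple
    values: np.ndarray
    metric: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            tuple(sample_ids), self.values[np.ix_(idx, idx)], self.metric
        )

    def write(self, path: str | Path) -> None:
        out = self.to_frame()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, metric: str = "custom") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy(dtype=float), metric)


def rarefy(table: AsvCountTable, depth: int, seed: int) -> AsvCountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning (never
    padded). Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = list(totals.index[~keep])
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if keep.sum() == 0:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    rows = []
    for sid in totals.index[keep]:
        row = table.data.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=totals.index[keep],
        columns=table.data.columns,
    )
    return AsvCountTable(out)


# ---------------------------------------------------------------------------
# branch bookkeeping shared by Faith PD and UniFrac


def _branch_table(
    tree: PhylogeneticTree, asv_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Return (lengths, membership) over all non-root branches.

    ``membership[b, j]`` is True when ASV ``asv_ids[j]`` is a tip descending
    through branch ``b``. The root carries no branch and is excluded.
    """
    col = {a: i for i, a in enumerate(asv_ids)}
    tip_names = set(tree.tip_names)
    missing = sorted(set(asv_ids) - tip_names)
    if missing:
        raise ValueError(f"ASVs missing from tree tips: {missing}")
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    masks: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(asv_ids), dtype=bool)
            if node.name in col:
                mask[col[node.name]] = True
        else:
            mask = np.zeros(len(asv_ids), dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if not node.is_root():
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)


def _present_asvs(table: AsvCountTable) -> list[str]:
    present = table.data.columns[(table.data > 0).any(axis=0)]
    return list(present)


def faith_pd(table: AsvCountTable, tree: PhylogeneticTree) -> pd.Series:
    """Faith's phylogenetic diversity per sample: total branch length of the
    minimal rooted subtree spanning the sample's present tips and the root."""
    kept = _check_tips(table, tree)
    lengths, member = _branch_table(tree, kept)
    present = table.data[kept].to_numpy() > 0  # samples x ASVs
    # branch is in the spanning subtree iff any present tip descends through it
    branch_present = member @ present.T > 0  # branches x samples
    vals = lengths @ branch_present
    return pd.Series(vals, index=table.sample_ids, name="faith_pd")


def _check_tips(table: AsvCountTable, tree: PhylogeneticTree) -> list[str]:
    asv_ids = table.asv_ids
    tip_names = set(tree.tip_names)
    used = [a for a, p in zip(asv_ids, (table.data > 0).any(axis=0)) if p]
    missing = sorted(set(used) - tip_names)
    if missing:
        raise ValueError(f"ASVs present in table but missing from tree: {missing}")
    return [a for a in asv_ids if a in tip_names]


def alpha_diversity(
    table: AsvCountTable,
    metric: str,
    tree: PhylogeneticTree | None = None,
    log_base: float = 2.0,
) -> pd.Series:
    """Per-sample alpha diversity.

    observed_asvs: number of ASVs with count > 0. shannon: -sum p log p over
    present ASVs (base 2 by default). pielou_evenness: shannon / log(richness)
    (0 when richness is 1). faith_pd: see :func:`faith_pd` (requires ``tree``).
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}; choose from {ALPHA_METRICS}")
    totals = table.sample_totals().to_numpy()
    if (totals <= 0).any():
        raise ValueError("sample with zero total reads")
    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a phylogenetic tree")
        return faith_pd(table, tree)
    counts = table.counts.astype(float)
    observed = (counts > 0).sum(axis=1)
    if metric == "observed_asvs":
        return pd.Series(observed, index=table.sample_ids, name=metric)
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(log_base)
    if metric == "shannon":
        return pd.Series(shannon, index=table.sample_ids, name=metric)
    # pielou: shannon / log(observed richness); degenerate single-ASV -> 0
    denom = np.log(observed.astype(float)) / np.log(log_base)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(observed > 1, shannon / np.where(denom > 0, denom, 1.0), 0.0)
    if (observed == 1).any():
        logger.warning("pielou evenness undefined for single-ASV samples; set to 0")
    return pd.Series(pielou, index=table.sample_ids, name=metric)


def alpha_diversity_table(
    table: AsvCountTable,
    tree: PhylogeneticTree | None = None,
    metrics: tuple[str, ...] = ALPHA_METRICS,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Long-format table (sample, metric, value) for the requested metrics."""
    parts = []
    for m in metrics:
        s = alpha_diversity(table, m, tree=tree, log_base=log_base)
        parts.append(
            pd.DataFrame({"sample_id": s.index, "metric": m, "value": s.to_numpy()})
        )
    return pd.concat(parts, ignore_index=True)


def unifrac(
    table: AsvCountTable,
    tree: PhylogeneticTree,
    weighted: bool = False,
    normalized: bool = False,
) -> DistanceMatrix:
    """All-pairs UniFrac distances between the table's samples.

    Unweighted: (branch length unique to one community) / (branch length in
    either community). Weighted raw: sum over branches of length times
    |p_A - p_B| where p_X is the fraction of sample X's reads descending
    through the branch; ``normalized=True`` divides by
    sum(length * (p_A + p_B)), bounding the result in [0, 1].
    """
    totals = table.sample_totals().to_numpy().astype(float)
    if (totals <= 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"empty samples: {empty}")
    kept = _check_tips(table, tree)
    lengths, member = _branch_table(tree, kept)
    counts = table.data[kept].to_numpy().astype(float)
    desc = member.astype(float) @ counts.T  # branches x samples
    n = counts.shape[0]
    d = np.zeros((n, n))
    if not weighted:
        pres = desc > 0
        wpres = lengths[:, None] * pres
        for i in range(n):
            for j in range(i + 1, n):
                union = np.where(pres[:, i] | pres[:, j], lengths, 0.0).sum()
                shared = np.where(pres[:, i] & pres[:, j], lengths, 0.0).sum()
                d[i, j] = d[j, i] = 0.0 if union == 0 else (union - shared) / union
        tag = "unweighted_unifrac"
    else:
        prop = desc / totals[None, :]
        for i in range(n):
            for j in range(i + 1, n):
                num = lengths @ np.abs(prop[:, i] - prop[:, j])
                if normalized:
                    den = lengths @ (prop[:, i] + prop[:, j])
                    d[i, j] = d[j, i] = 0.0 if den == 0 else num / den
                else:
                    d[i, j] = d[j, i] = num
        tag = "weighted_unifrac_normalized" if normalized else "weighted_unifrac"
    return DistanceMatrix(tuple(table.sample_ids), d, tag)
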