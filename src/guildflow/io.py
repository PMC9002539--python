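"""Input/output and study-design semantics.

Containers for the four core data objects of the pipeline — an ASV count
table, a rooted phylogeny over the ASVs, the per-sample study design, and
phenotype (salivary-protein / sensory) tables — plus the PROP taster-status
classifier and a generic low-abundance filter.

All tabular formats are UTF-8 TSV with a header row; trees are Newick.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "AsvCountTable",
    "StudyDesign",
    "PhylogeneticTree",
    "PhenotypeTable",
    "FormatError",
    "read_count_table",
    "read_newick_tree",
    "read_design",
    "read_phenotypes",
    "classify_prop",
    "filter_low_abundance",
    "NT_THRESHOLD_MM",
    "ST_THRESHOLD_MM",
    "BORDERLINE_BAND_MM",
]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class AsvCountTable:
    """Integer read counts, samples as rows and ASVs as columns."""

    data: pd.DataFrame  # samples x ASVs, integer dtype

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate ASV ids")
        # >= 2 ASVs is enforced at read time; filtered tables may narrow to 1
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise FormatError("count table needs at least 2 samples and 1 ASV")
        if df.isna().any().any():
            raise FormatError("NaN cell in count table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("non-integer count")
            object.__setattr__(self, "data", df.astype(np.int64))
            arr = self.data.to_numpy()
        if (arr < 0).any():
            raise FormatError("negative count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AsvCountTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class PhylogeneticTree:
    """Rooted tree whose tips are ASV ids, with non-negative branch lengths."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        names = self.tip_names
        if len(names) != len(set(names)):
            raise FormatError("duplicate tip labels in tree")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise FormatError("negative branch length")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))
        )

    def write(self, path: str | Path) -> None:
        self.tree.write(str(path), format="newick")

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


TASTER_LEVELS = ("NT", "MT", "ST")
TIMEPOINTS = ("pre", "post")

_DESIGN_REQUIRED = ["subject_id", "taster_status", "timepoint", "age", "gender", "bmi"]


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample design: subject, taster status, timepoint and covariates.

    Indexed by sample id. ``taster_status`` is NT/MT/ST, ``timepoint`` is
    pre/post, ``gender`` is F/M; optional LMS columns ``prop_rating_mm`` and
    ``nacl_rating_mm`` hold the screening ratings in millimetres.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _DESIGN_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"design missing columns: {missing}")
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in design")
        bad = set(df["taster_status"]) - set(TASTER_LEVELS)
        if bad:
            raise FormatError(f"unknown taster status values: {sorted(bad)}")
        bad = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise FormatError(f"unknown timepoint values: {sorted(bad)}")
        dup = df.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            raise FormatError(
                "duplicate (subject, timepoint): "
                + ", ".join(df.index[dup].astype(str))
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "StudyDesign":
        return StudyDesign(self.data.loc[list(sample_ids)])

    def check_covers(self, table: AsvCountTable) -> None:
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise FormatError(f"samples without a design row: {sorted(missing)}")

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class PhenotypeTable:
    """Real-valued phenotype measurements (proteins or sensory attributes).

    Samples as rows, variables as columns; missing values allowed but every
    present value must be finite. Units are variable-specific.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.columns.has_duplicates:
            raise FormatError("duplicate variable names")
        arr = df.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise FormatError("non-finite phenotype value")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers


def read_count_table(path: str | Path, samples_as_rows: bool = True) -> AsvCountTable:
    """Read a TSV count table; first column holds sample ids (or ASV ids when
    ``samples_as_rows=False``, in which case the table is transposed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not samples_as_rows:
        df = df.T
    if df.isna().any().any():
        raise FormatError(f"NaN cell in count table {path}")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise FormatError("count table needs at least 2 samples and 2 ASVs")
    return AsvCountTable(df)


def read_newick_tree(
    path: str | Path, missing_lengths: str = "error"
) -> PhylogeneticTree:
    """Read a rooted Newick tree.

    Branch lengths are required; ``missing_lengths='zero'`` substitutes 0.0
    instead of raising (phylogenetic metrics are length-based, so silent
    missing lengths are rejected by default).
    """
    # underscores are literal in ASV ids; disable the quoting convention
    tree = skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_lengths == "zero":
                node.length = 0.0
            else:
                raise FormatError(
                    f"missing branch length near node {node.name!r}; "
                    "pass missing_lengths='zero' to accept"
                )
    return PhylogeneticTree(tree)


def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StudyDesign(df)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# PROP taster classification

NT_THRESHOLD_MM = 15.0  # PROP LMS rating below which a subject is a non-taster
ST_THRESHOLD_MM = 67.0  # PROP LMS rating above which a subject is a super-taster
BORDERLINE_BAND_MM = 5.0  # half-width of the band where the NaCl reference applies


def classify_prop(
    prop_rating_mm: float,
    nacl_rating_mm: float,
    *,
    band_mm: float = BORDERLINE_BAND_MM,
) -> str:
    """Classify PROP taster status from LMS ratings of PROP and NaCl disks.

    Primary rule: PROP < 15 mm -> NT; PROP > 67 mm -> ST; otherwise MT.
    Within ``band_mm`` of either threshold the NaCl disk serves as the
    reference standard: non-tasters rate NaCl above PROP, super-tasters rate
    PROP above NaCl, and equal ratings resolve to MT.
    """
    for name, v in (("prop", prop_rating_mm), ("nacl", nacl_rating_mm)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name}_rating_mm {v} outside LMS range [0, 100]")
    if abs(prop_rating_mm - NT_THRESHOLD_MM) <= band_mm:
        if nacl_rating_mm > prop_rating_mm:
            return "NT"
        return "MT"
    if abs(prop_rating_mm - ST_THRESHOLD_MM) <= band_mm:
        if prop_rating_mm > nacl_rating_mm:
            return "ST"
        return "MT"
    if prop_rating_mm < NT_THRESHOLD_MM:
        return "NT"
    if prop_rating_mm > ST_THRESHOLD_MM:
        return "ST"
    return "MT"


# ---------------------------------------------------------------------------
# abundance filter


def filter_low_abundance(
    table: AsvCountTable, min_total_fraction: float = 0.0
) -> AsvCountTable:
    """Drop ASVs whose summed count over all samples is below a fraction of
    the grand total. Retained counts are unchanged; samples are never dropped.
    """
    if not (0.0 <= min_total_fraction < 1.0):
        raise ValueError("min_total_fraction must be in [0, 1)")
    totals = table.data.sum(axis=0)
    keep = totals >= min_total_fraction * totals.sum()
    if not keep.any():
        raise ValueError("empty table: all ASVs removed by abundance filter")
    return AsvCountTable(table.data.loc[:, keep])
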