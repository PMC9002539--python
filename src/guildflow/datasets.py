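"""Published summary data from the cranberry-polyphenol rinse study.

The study's raw 16S reads are deposited (BioProject PRJNA778221) but its
phenotype tables are not public, so the pipeline is exercised on synthetic
data. What the publication does print — the subject-characteristics table
(gender x taster-status subgroup sizes with mean age and BMI) and the
sequencing bookkeeping (39 usable samples at a mean read count) — is shipped
here as reference data, with helpers that recompute the pooled summaries
from the subgroup rows.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "subject_characteristics",
    "sequencing_summary",
    "pooled_mean",
    "total_reads",
]


def subject_characteristics() -> pd.DataFrame:
    """Gender x taster-status subgroups: n, mean age (years), mean BMI (kg/m2)."""
    return pd.DataFrame(
        [
            {"gender": "F", "taster_status": "NT", "n": 7, "mean_age": 21.0, "mean_bmi": 24.7},
            {"gender": "F", "taster_status": "ST", "n": 5, "mean_age": 20.6, "mean_bmi": 22.7},
            {"gender": "M", "taster_status": "NT", "n": 3, "mean_age": 19.7, "mean_bmi": 24.8},
            {"gender": "M", "taster_status": "ST", "n": 5, "mean_age": 24.6, "mean_bmi": 25.5},
        ]
    )


def sequencing_summary() -> dict:
    """Sample and read bookkeeping: 20 subjects x 2 timepoints minus one
    failed extraction, at the reported mean usable read count per sample."""
    return {
        "n_subjects": 20,
        "n_timepoints": 2,
        "n_failed_extractions": 1,
        "n_samples": 20 * 2 - 1,
        "mean_reads_per_sample": 167_958,
    }


def pooled_mean(table: pd.DataFrame, column: str, weight: str = "n") -> float:
    """Sample-size weighted pooled mean of a subgroup-summary column."""
    w = table[weight].to_numpy(dtype=float)
    return float((table[column].to_numpy(dtype=float) * w).sum() / w.sum())


def total_reads() -> float:
    """Total usable reads implied by the per-sample mean and sample count."""
    s = sequencing_summary()
    return float(s["n_samples"] * s["mean_reads_per_sample"])
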