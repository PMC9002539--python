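import logging

import numpy as np
import pandas as pd
import pytest
import skbio

from guildflow.io import AsvCountTable, PhylogeneticTree, StudyDesign
from guildflow.synthetic import SyntheticScenario, generate_dataset

logging.getLogger("guildflow").setLevel(logging.ERROR)


def tree_from_newick(newick: str) -> PhylogeneticTree:
    return PhylogeneticTree(
        skbio.TreeNode.read([newick], convert_underscores=False)
    )


@pytest.fixture
def three_tip_tree() -> PhylogeneticTree:
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table() -> AsvCountTable:
    return AsvCountTable(
        pd.DataFrame(
            [[5, 0, 2], [1, 3, 0], [4, 4, 4]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def paired_design() -> StudyDesign:
    rows = []
    for i, grp in enumerate(["NT"] * 3 + ["ST"] * 3):
        subj = f"{grp}{i % 3 + 1}"
        for tp in ("pre", "post"):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "subject_id": subj,
                    "taster_status": grp,
                    "timepoint": tp,
                    "age": 20 + i,
                    "gender": "F" if i % 2 else "M",
                    "bmi": 23.0 + i,
                }
            )
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic scenario at its canonical seed."""
    return generate_dataset(SyntheticScenario(seed=0))


@pytest.fixture(scope="session")
def tiny_scenario() -> SyntheticScenario:
    """Scaled-down scenario for structural / end-to-end tests."""
    return SyntheticScenario(
        n_subjects_per_group=6,
        n_asvs=60,
        n_prevalent=15,
        n_guilds=3,
        read_depth=800,
        dropout=(("ST06", "post"),),
        seed=0,
    )
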