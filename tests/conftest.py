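"""Shared fixtures: the published TLR7/8 motif tabulation and small helpers.

``TABLE1`` freezes the published per-miRNA motif tabulation for the twelve
motif-bearing miRNAs increased in epileptogenic-tissue exosomes: mature
sequence, reported fold change, and per-motif window counts for UUGU /
GUUU / UGUU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exomir import ExpressionExperiment, GeneSet, MiRNACountMatrix

# id: (p_value, fold_change, sequence, UUGU, GUUU, UGUU, total)
TABLE1 = {
    "hsa-miR-27a-5p": (0.04, 17.41, "AGGGCUUAGCUGCUUGUGAGCA", 1, 0, 0, 1),
    "hsa-miR-744-3p": (0.03, 5.49, "CUGUUGCCACUAACCUCAACCU", 0, 0, 1, 1),
    "hsa-miR-26a-2-3p": (0.02, 3.54, "CCUAUUCUUGAUUACUUGUUUC", 1, 1, 1, 3),
    "hsa-miR-652-3p": (0.04, 3.54, "AAUGGCGCCACUAGGGUUGUG", 1, 0, 0, 1),
    "hsa-miR-21-5p": (0.05, 3.48, "UAGCUUAUCAGACUGAUGUUGA", 0, 0, 1, 1),
    "hsa-miR-142-3p": (0.05, 3.21, "UGUAGUGUUUCCUACUUUAUGGA", 0, 1, 1, 2),
    "hsa-miR-29b-1-5p": (0.01, 2.74, "GCUGGUUUCAUAUGGUGGUUUAGA", 0, 2, 0, 2),
    "hsa-miR-629-5p": (0.03, 2.48, "UGGGUUUACGUUGGGAGAACU", 0, 1, 0, 1),
    "hsa-miR-28-3p": (0.05, 2.33, "CACUAGAUUGUGAGCUCCUGGA", 1, 0, 0, 1),
    "hsa-miR-3605-3p": (0.01, 1.90, "CCUCCGUGUUACCUGUCCUCUAG", 0, 0, 1, 1),
    "hsa-miR-223-3p": (0.04, 1.75, "UGUCAGUUUGUCAAAUACCCCA", 1, 1, 0, 2),
    "hsa-miR-30a-3p": (0.04, 1.73, "CUUUCAGUCGGAUGUUUGCAGC", 0, 1, 1, 2),
}


@pytest.fixture(scope="session")
def table1_sequences():
    from exomir import MatureSequenceSet

    return MatureSequenceSet.from_pairs((mid, row[2]) for mid, row in TABLE1.items())


@pytest.fixture
def toy_mirna_matrix():
    """4 miRNAs x 4 samples with an abundant, perfectly stable reference."""
    values = pd.DataFrame(
        {
            "epi_1": [80, 20, 8, 2],
            "epi_2": [160, 40, 16, 4],
            "non_1": [40, 20, 8, 2],
            "non_2": [44, 22, 9, 2],
        },
        index=["mir-a", "hsa-miR-26a-5p", "mir-b", "mir-c"],
    )
    groups = pd.Series(
        ["epileptogenic", "epileptogenic", "non_epileptogenic", "non_epileptogenic"],
        index=values.columns,
    )
    return MiRNACountMatrix(values=values, groups=groups)


def make_log2_experiment(columns: dict[str, np.ndarray], conditions: dict[str, str], genes=None):
    """Build a log2-state ExpressionExperiment directly from arrays."""
    values = pd.DataFrame(columns)
    values.index = genes if genes is not None else [f"G{i:03d}" for i in range(len(values))]
    cond = pd.Series({c: conditions[c] for c in values.columns})
    return ExpressionExperiment(values=values, conditions=cond, state="log2")
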