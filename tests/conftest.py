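import numpy as np
import pandas as pd
import pytest

from telopull.io import ProteinGroupTable, SampleInfo


@pytest.fixture
def lfq_sheet():
    return [
        SampleInfo("bait_1", "bait", 1),
        SampleInfo("bait_2", "bait", 2),
        SampleInfo("ctrl_1", "control", 1),
        SampleInfo("ctrl_2", "control", 2),
    ]


@pytest.fixture
def small_table(lfq_sheet):
    """5 proteins x 4 samples, one row per flag category, one missing cell."""
    ids = [f"P{i}" for i in range(5)]
    rng = np.random.default_rng(7)
    mat = pd.DataFrame(
        2.0 ** rng.normal(25, 1, size=(5, 4)),
        index=pd.Index(ids, name="protein_id"),
        columns=[s.name for s in lfq_sheet],
    )
    mat.iloc[0, 0] = np.nan
    flags = pd.DataFrame(
        {
            "contaminant": [False, True, False, False, False],
            "reverse": [False, False, True, False, False],
            "only_by_site": [False, False, False, True, False],
        },
        index=mat.index,
    )
    return ProteinGroupTable(intensities=mat, flags=flags, sample_sheet=lfq_sheet)


def write_pg_tsv(path, rows, columns, reverse_flags=None):
    """Write a minimal proteinGroups-style TSV for parser tests."""
    header = ["Majority protein IDs"] + [f"LFQ intensity {c}" for c in columns] + ["Reverse"]
    lines = ["\t".join(header)]
    for i, row in enumerate(rows):
        flag = "+" if reverse_flags and i in reverse_flags else ""
        lines.append("\t".join([row[0]] + [str(v) for v in row[1:]] + [flag]))
    path.write_text("\n".join(lines) + "\n")
    return path
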