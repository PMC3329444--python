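import numpy as np
import pandas as pd
import pytest

from genograde.association import CrossTab
from genograde.cohort import Cohort, HistoType, PatientRecord

# Published two-by-two distribution of 163 tumours: genomic grade columns
# (GG1, EQ, GG3) against histological grade, mitotic-index class and Ki67
# class rows.  Used as printed-table fixtures for the association module.
GG_COLS = ("GG1", "EQ", "GG3")

HG_BY_GG = {"1": (42, 8, 3), "2": (35, 22, 13), "3": (1, 5, 34)}
MI_BY_GG = {"MI1": (72, 23, 9), "MI2": (5, 9, 10), "MI3": (1, 3, 31)}
KI67_BY_GG = {"low": (69, 19, 5), "high": (9, 16, 45)}

# Composite low-MI/low-Ki67 counts per concordant HGxGG subgroup
# (HG1/GG1, HG2/GG1, HG2/GG3, HG3/GG3)
LOW_MI_LOW_KI67 = (39, 30, 1, 0)

# Hypothetical guideline-assignment counts (NONE, AHT, AHT_ACT, ACT):
# all grade-2 tumours and the ER+/HER2- subgroup, HG arm then GG arm.
TABLE_ALL_HG2 = {"HG": (0, 35, 31, 4), "GG": (5, 37, 24, 4)}
TABLE_ERPOS = {"HG": (0, 34, 26, 0), "GG": (5, 36, 19, 0)}


def _tab(rows: dict) -> CrossTab:
    labels = tuple(rows)
    counts = np.array([rows[r] for r in labels], dtype=int)
    return CrossTab(labels, GG_COLS, counts)


@pytest.fixture(scope="session")
def hg_by_gg_tab() -> CrossTab:
    """HG (rows 1/2/3) x GG (cols GG1/EQ/GG3) printed counts."""
    return _tab(HG_BY_GG)


@pytest.fixture(scope="session")
def mi_by_gg_tab() -> CrossTab:
    return _tab(MI_BY_GG)


@pytest.fixture(scope="session")
def ki67_by_gg_tab() -> CrossTab:
    return _tab(KI67_BY_GG)


def make_record(pid="P1", **overrides) -> PatientRecord:
    base = dict(
        patient_id=pid, age=55.0, tumor_size=18.0, hg=2, mitoses=8, ki67=15.0,
        er=True, pr=True, her2=False, follow_up=140.0, metastasis=False,
        histo_type=HistoType.IDC, lvi=False, tumor_cell_pct=70.0,
        received_aht=False, received_act=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def small_cohort() -> Cohort:
    return Cohort(
        (
            make_record("P1", hg=1, mitoses=2, ki67=5.0, tumor_cell_pct=60.0),
            make_record("P2", hg=2, mitoses=12, ki67=20.0, tumor_cell_pct=50.0,
                        metastasis=True, follow_up=48.0),
            make_record("P3", hg=3, mitoses=25, ki67=60.0, er=False, pr=False,
                        tumor_cell_pct=40.0),
        ),
        provenance="unit-test",
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
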