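import numpy as np
import pandas as pd
import pytest

import rbcscore as rs

BASE_RECORD = {
    "sex": "male",
    "age": 60.0,
    "height": 170.0,
    "weight": 80.0,
    "asa": "2",
    "anticoagulant": "no",
    "prior_surgeries": "0",
    "hb": 12.5,
    "quick": 100.0,
    "inr": 1.0,
    "ptt": 25.0,
    "thrombocytes": 250.0,
    "fracture": "no",
    "tumor": "no",
    "surgery_type": "lumbar",
    "incision": "dorsal",
    "vbr": "no",
    "stages": "1",
    "transfused": "no",
}


def make_cohort(rows, name="fixture"):
    """Build a Cohort from a list of partial record dicts (BASE_RECORD
    defaults filled in; value None means missing)."""
    full = []
    for r in rows:
        rec = {**BASE_RECORD, **r}
        full.append({k: (np.nan if v is None else v) for k, v in rec.items()})
    return rs.Cohort(pd.DataFrame(full), name=name)


@pytest.fixture
def tiny_cohort():
    """10 records: rows 0-1 missing asa, row 2 missing vbr (disjoint), so a
    complete-case filter on {asa, vbr} keeps 7 records."""
    rows = [
        {"asa": None, "transfused": "yes"},
        {"asa": None},
        {"vbr": None, "transfused": "yes"},
        {"hb": 9.0, "transfused": "yes"},
        {"surgery_type": "cervical"},
        {"surgery_type": "combination", "stages": "gt3", "transfused": "yes"},
        {"stages": "0"},
        {"sex": "female", "incision": "ventral"},
        {"tumor": "yes"},
        {"fracture": "yes"},
    ]
    return make_cohort(rows, name="tiny")


@pytest.fixture(scope="session")
def study_sized_cohort():
    """Synthetic stand-in for the 252-record study cohort with exactly one
    missing vertebral-body-replacement value."""
    cfg = rs.default_config(n=252, seed=42)
    cfg.missingness = {}
    cohort = rs.generate(cfg)
    df = cohort.data
    codes = df["vbr"].cat.codes.to_numpy().copy()
    codes[17] = -1  # one record with vbr unrecorded
    df["vbr"] = pd.Categorical.from_codes(codes, categories=df["vbr"].cat.categories)
    return rs.Cohort(df, name="study-sized")


@pytest.fixture(scope="session")
def big_clean_cohort():
    """n = 20000, no missingness: parameter-recovery scale."""
    cfg = rs.default_config(n=20000, seed=7)
    cfg.missingness = {}
    return rs.generate(cfg)


def auc_pair_counting(scores, labels):
    """Independent O(n^2) Mann-Whitney oracle: count event/non-event pairs
    where the event scores higher; ties count one half."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    pos = s[lab == 1]
    neg = s[lab == 0]
    diff = pos[:, None] - neg[None, :]
    return (np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / (
        pos.size * neg.size
    )
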