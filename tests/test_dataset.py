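"""Feature-table assembly, segmentation, split and standardization."""

import numpy as np
import pandas as pd
import pytest

from physioload.dataset import (
    mid_time,
    select_features,
    split_train_test,
    standardize,
)
from physioload.evaluation import PAIRS


def _pair_rows(table, pair="2v0"):
    lo, hi = PAIRS[pair]
    return table[table["condition"].isin((lo, hi))]


def test_row_counts_120s(p1_table_120):
    assert len(p1_table_120) == 24                       # 4 sessions x 6 blocks
    rows = _pair_rows(p1_table_120)
    assert len(rows) == 16
    train, test = split_train_test(rows)
    assert (len(train), len(test)) == (12, 4)


def test_row_counts_30s(p1_table_30):
    assert len(p1_table_30) == 96                        # 24 blocks x 4 sub-segments
    rows = _pair_rows(p1_table_30)
    assert len(rows) == 64
    train, test = split_train_test(rows)
    assert (len(train), len(test)) == (48, 16)


def test_split_has_no_leakage(p1_table_120):
    train, test = split_train_test(p1_table_120)
    keys = ["participant", "session", "block", "subseg"]
    t1 = set(map(tuple, train[keys].to_numpy()))
    t2 = set(map(tuple, test[keys].to_numpy()))
    assert not (t1 & t2)
    assert set(train["session"]) == {1, 2, 3} and set(test["session"]) == {4}
    with pytest.raises(ValueError, match="missing session"):
        split_train_test(p1_table_120[p1_table_120["session"] != 4])


def test_mid_time_examples_and_monotonicity(p1_table_120, p1_table_30):
    # the workload-task clock ignores baselines, breaks and rating periods
    assert mid_time(0, 0, 120.0) == 60.0
    assert mid_time(1, 0, 120.0) == 180.0
    assert mid_time(0, 0, 30.0) == 15.0
    for table in (p1_table_120, p1_table_30):
        ordered = table.sort_values(["session", "block", "subseg"])
        assert np.all(np.diff(ordered["mid_time"].to_numpy()) > 0)
    assert p1_table_120["mid_time"].iloc[:2].tolist() == [60.0, 180.0]
    assert (p1_table_120["time"] == p1_table_120["mid_time"]).all()


def test_standardize_contract():
    rng = np.random.default_rng(0)
    cols = ["a", "b", "c"]
    train = pd.DataFrame(rng.normal(5, 3, size=(20, 3)), columns=cols)
    train["c"] = 2.0                                      # constant column
    test = pd.DataFrame(rng.normal(9, 3, size=(8, 3)), columns=cols)
    xtr, xte, params = standardize(train, test, cols)
    assert np.allclose(xtr[:, :2].mean(axis=0), 0, atol=1e-12)
    assert np.allclose(xtr[:, :2].std(axis=0), 1, atol=1e-12)
    assert np.all(xtr[:, 2] == 0) and np.all(xte[:, 2] == 0)
    # test rows use the training transform, not their own statistics
    mu, sd = params["mean"][0], params["sd"][0]
    assert np.allclose(xte[:, 0], (test["a"] - mu) / sd)
    assert abs(xte[:, 0].mean()) > 0.5                    # shifted mean survives
    # idempotence on already-standardized training data
    ztr = pd.DataFrame(xtr, columns=cols)
    xtr2, _, _ = standardize(ztr, ztr, cols)
    assert np.allclose(xtr2, xtr, atol=1e-12)


@pytest.mark.parametrize(
    "spec, time, expected",
    [
        ("erp", False, 707),
        ("power", False, 259),
        ("alpha", False, 7),
        ("theta", False, 7),
        ("eeg", False, 966),
        ("erp_pz", False, 101),
        ("pz", False, 138),
        ("alpha_pz", False, 1),
        ("theta_fz", False, 1),
        ("physiology", False, 8),
        ("eye", False, 3),
        ("eeg+physiology+eye", False, 977),
        ("sc.mean", True, 2),
        ("eeg", True, 967),
    ],
)
def test_feature_set_dimensions(spec, time, expected):
    assert len(select_features(spec, include_time=time)) == expected


def test_select_features_rules():
    with pytest.raises(KeyError, match="valid names"):
        select_features("bogus")
    # alpha/theta sets never include raw power columns
    for spec in ("alpha", "theta", "alpha_pz", "theta_fz"):
        assert not any(".pow." in c for c in select_features(spec))
    # concatenation preserves sensor-group ordering: EEG, physiology, eye, time
    cols = select_features("eeg+physiology+eye", include_time=True)
    kinds = ["eeg" if c.startswith("eeg.") else
             "eye" if c.startswith("eye.") else
             "time" if c == "time" else "phys" for c in cols]
    order = [k for i, k in enumerate(kinds) if i == 0 or k != kinds[i - 1]]
    assert order == ["eeg", "phys", "eye", "time"]


def test_feature_table_is_complete(p1_table_120):
    for col in select_features("eeg+physiology+eye", include_time=True):
        assert col in p1_table_120.columns
    # 120 s blocks with default blink rates always contain blinks
    assert p1_table_120["eye.blink_dur"].notna().all()
    assert set(p1_table_120["condition"]) == {"0-back", "1-back", "2-back"}
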