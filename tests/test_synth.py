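"""Schedule constraints, n-back logic, determinism and generator truth."""

import numpy as np
import pandas as pd
import pytest

from physioload import SimulationConfig
from physioload.events import block_table, read_events_tsv, write_events_tsv
from physioload.synth import generate_participant, generate_schedule
from physioload.synth.schedule import CONSONANTS, _target_flags


@pytest.fixture(scope="module")
def schedule(default_config):
    return generate_schedule(default_config, seed=11)


def test_block_design(schedule, default_config):
    """4 sessions x (1 baseline + 6 workload blocks), 48 letters / 16 targets."""
    bt = block_table(schedule)
    assert len(bt) == 28
    work = bt[bt["condition"] != "baseline"]
    assert (work["n_stimuli"] == 48).all()
    assert (work["n_targets"] == 16).all()
    assert bt.groupby("session")["block"].count().eq(7).all()
    # 28 blocks x 2 min = 56 min of task
    total_min = (bt["block_end"] - bt["block_start"]).sum() / 60.0
    assert total_min == pytest.approx(56.0)
    assert default_config.total_task_minutes == pytest.approx(56.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_schedule_constraints_all_seeds(default_config, seed):
    """No same-condition adjacency; each condition once per session half."""
    bt = block_table(generate_schedule(default_config, seed=seed))
    for _, sess in bt.groupby("session"):
        conds = sess.sort_values("block")["condition"].tolist()
        assert conds[0] == "baseline"
        work = conds[1:]
        assert all(a != b for a, b in zip(work, work[1:]))
        assert sorted(work[:3]) == sorted(set(work)) == ["0-back", "1-back", "2-back"]
        assert sorted(work[3:]) == ["0-back", "1-back", "2-back"]


def test_onset_spacing_and_letters(schedule, default_config):
    back = {"0-back": 0, "1-back": 1, "2-back": 2}
    for (_, _, _), blk in schedule[schedule["onset"].notna()].groupby(
        ["participant", "session", "block"]
    ):
        onsets = blk["onset"].to_numpy()
        assert np.allclose(np.diff(onsets), default_config.soa)
        letters = blk["letter"].tolist()
        assert set(letters) <= set(CONSONANTS)
        # declared targets must be exactly the n-back-rule targets
        expected = _target_flags(letters, back[blk["condition"].iloc[0]])
        assert blk["is_target"].tolist() == expected


def test_events_tsv_roundtrip(tmp_path, schedule):
    path = tmp_path / "events.tsv"
    write_events_tsv(schedule, path)
    back = read_events_tsv(path)
    pd.testing.assert_frame_equal(
        back, schedule.reset_index(drop=True), check_exact=False, atol=1e-6
    )


def test_generation_is_deterministic():
    cfg = SimulationConfig(n_participants=1, letters_per_block=12,
                           block_duration=30.0, n_sessions=2)
    b1, e1 = generate_participant(cfg, 1, seed=9)
    b2, e2 = generate_participant(cfg, 1, seed=9)
    pd.testing.assert_frame_equal(e1, e2)
    for s in b1.sessions:
        assert np.array_equal(b1[s].eeg, b2[s].eeg)
        assert np.array_equal(b1[s].ecg, b2[s].ecg)
        assert np.array_equal(b1[s].sc, b2[s].sc)
        assert np.array_equal(b1[s].resp, b2[s].resp)
        pd.testing.assert_frame_equal(b1[s].gaze, b2[s].gaze)
        assert b1[s].truth["blinks"] == b2[s].truth["blinks"]


def test_zero_effects_remove_condition_dependence():
    """With all effects zeroed, block features carry no condition signal
    (two-sided location test on >200 blocks does not reject at alpha=.01)."""
    from scipy.stats import mannwhitneyu

    from physioload.dataset import extract_features

    cfg = SimulationConfig(
        n_participants=13, letters_per_block=12, block_duration=30.0,
        streams=("sc", "gaze"),
    ).zero_effect()
    rows = []
    for p in range(1, 14):
        bundle, events = generate_participant(cfg, p, seed=21)
        rows.append(extract_features(bundle, events, cfg, segment_length=30.0))
    table = pd.concat(rows)
    lo = table[table["condition"] == "0-back"]
    hi = table[table["condition"] == "2-back"]
    assert len(lo) + len(hi) >= 200
    for col in ("sc.mean", "eye.pupil", "eye.blink_rate"):
        p = mannwhitneyu(lo[col], hi[col]).pvalue
        assert p > 0.01, f"{col} shows a spurious workload effect (p={p})"


def test_alpha_suppressed_under_load_every_participant(default_table):
    """Pz log alpha power is lower in 2-back than 0-back for all participants."""
    col = "eeg.Pz.alpha"
    for _, g in default_table.groupby("participant"):
        assert (g.loc[g["condition"] == "2-back", col].mean()
                < g.loc[g["condition"] == "0-back", col].mean())


def test_artifact_trials_exceed_rejection_threshold(one_participant, default_config):
    """Injected artifact epochs have per-channel SD above 100 uV."""
    from physioload.eeg import epoch

    bundle, events = one_participant
    found = 0
    for s, rec in bundle.sessions.items():
        for onset in rec.truth["artifact_onsets"]:
            eps = epoch(rec.eeg, rec.fs_eeg, np.array([onset]))
            assert eps.data[0].std(axis=1).max() > 100.0
            found += 1
    assert found > 0, "default artifact rate produced no artifacts in 4 sessions"


def test_truth_run_lengths(one_participant):
    for rec in one_participant[0].sessions.values():
        for _, length in rec.truth["blinks"]:
            assert 2 <= length <= 25
        for _, length in rec.truth["losses"]:
            assert length > 25


def test_constant_interval_ecg_limit(default_config):
    """No jitter / no modulation / no effects -> constant detected RRI, RMSSD ~ 0."""
    from physioload.physio import detect_r_peaks, hrv_time_metrics

    cfg = default_config.with_(
        rri_jitter=0.0, hrv_mf_depth=0.0, hrv_hf_depth=0.0, rri_block_sd=0.0,
        n_participants=1, streams=("ecg",),
    ).zero_effect()
    bundle, _ = generate_participant(cfg, 1, seed=2)
    rri = detect_r_peaks(bundle[1].ecg, cfg.fs_physio)
    mean_rri, rmssd = hrv_time_metrics(rri)
    sample_ms = 1000.0 / cfg.fs_physio
    assert mean_rri == pytest.approx(800.0, abs=sample_ms)
    assert rmssd <= 2 * sample_ms  # grid quantization only


def test_sc_minimum_below_mean_every_block(p1_table_120):
    assert (p1_table_120["sc.min"] < p1_table_120["sc.mean"]).all()
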