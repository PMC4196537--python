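"""Simulation configuration for the synthetic n-back recording generator.

The generator emulates a working-memory (n-back) experiment: per participant,
4 sessions, each opening with a 2-min fixation baseline followed by six 2-min
workload blocks (two repetitions of each of 0-back, 1-back and 2-back in
pseudorandom order).  Within a workload block, 48 letters are shown at a
stimulus-onset asynchrony of 2.5 s (0.5 s letter + 2.0 s fixation) and one
third of them are targets.

Workload acts on the signals through per-modality effect sizes scaled by a
per-condition weight (``level_weights``): EEG alpha suppression, theta gain
and P300 attenuation; cardiac inter-beat-interval shortening with reduced
respiratory HRV modulation; faster respiration; higher tonic skin
conductance; pupil dilation; fewer blinks.  Peripheral modalities addition-
ally drift linearly with time on task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = ["SimulationConfig", "CONDITIONS", "WORKLOAD_CONDITIONS", "EEG_CHANNELS"]

CONDITIONS = ("baseline", "0-back", "1-back", "2-back")
WORKLOAD_CONDITIONS = ("0-back", "1-back", "2-back")

#: Fixed EEG montage and channel order used throughout the package.
EEG_CHANNELS = ("Fz", "FCz", "Pz", "C3", "C4", "F3", "F4")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multimodal recording generator.

    Default structural values reproduce the experiment's block design; the
    per-modality effect sizes are free parameters of the simulation (the
    underlying study does not quantify them) chosen so that default-settings
    classification accuracy is realistic for this kind of data.
    """

    # -- experiment structure ------------------------------------------------
    n_participants: int = 14
    n_sessions: int = 4
    reps_per_condition: int = 2
    block_duration: float = 120.0          # s
    soa: float = 2.5                       # s, stimulus onset asynchrony
    stimulus_duration: float = 0.5         # s
    letters_per_block: int = 48
    target_fraction: float = 1.0 / 3.0
    inter_block_gap: float = 10.0          # s, stands in for rating periods

    # -- sampling rates ------------------------------------------------------
    fs_eeg: float = 256.0                  # Hz
    fs_physio: float = 300.0               # Hz (ECG, skin conductance, respiration)
    fs_gaze: float = 60.0                  # Hz

    # -- workload weighting --------------------------------------------------
    # Per-condition multiplier applied to every effect size.  The 1-back /
    # 2-back spacing is asymmetric (a 2-back step costs more than a 1-back
    # step), mirroring the reported difficulty ordering 2v0 > 2v1 > 1v0.
    level_weights: tuple[float, float, float] = (0.0, 0.45, 1.0)

    # -- EEG generator -------------------------------------------------------
    eeg_noise_rms: float = 9.0             # uV, 1/f background RMS
    alpha_freq: float = 10.0               # Hz
    alpha_amp: float = 7.0                 # uV at the best channel, zero load
    alpha_suppression: float = 0.55        # fractional amplitude loss at weight 1
    theta_freq: float = 6.0                # Hz
    theta_amp: float = 3.0                 # uV at the best channel, zero load
    theta_gain: float = 0.5                # fractional amplitude gain at weight 1
    osc_phase_diffusion: float = 2.5       # rad^2/s phase random walk (decoheres
                                           # oscillations across stimulus epochs)
    p300_amp: float = 8.0                  # uV peak at Pz, zero load
    p300_attenuation: float = 0.45         # fractional amplitude loss at weight 1
    eeg_block_jitter: float = 0.32         # lognormal sigma of per-block amplitude
    artifact_rate: float = 0.01            # per-trial probability of an artifact
    artifact_amp: float = 200.0            # uV SD of injected artifact noise

    # -- cardiac generator ---------------------------------------------------
    rri_base: float = 0.80                 # s, resting inter-beat interval
    rri_workload_effect: float = 0.015     # s removed at weight 1
    rri_drift: float = 8.0e-6              # s of RRI removed per s of task time
    rri_block_sd: float = 0.025            # s, per-block random offset
    rri_jitter: float = 0.010              # s, white beat-to-beat jitter
    hrv_mf_depth: float = 0.022            # s, 0.10 Hz RRI modulation depth
    hrv_hf_depth: float = 0.020            # s, 0.30 Hz RRI modulation depth
    hrv_suppression: float = 0.30          # fractional depth loss at weight 1
    hrv_block_jitter: float = 0.50         # lognormal sigma of per-block HRV depth

    # -- respiration generator ----------------------------------------------
    resp_rate_base: float = 0.25           # Hz
    resp_rate_gain: float = 0.10           # fractional rate gain at weight 1
    resp_rate_drift: float = 1.5e-5        # fractional rate gain per s of task time
    resp_rate_block_sd: float = 0.09     # fractional per-block rate offset
    resp_amp: float = 1.0                  # a.u.
    resp_noise: float = 0.08               # a.u., additive white noise

    # -- skin conductance generator -----------------------------------------
    sc_base: float = 5.0                   # uS tonic level
    sc_gain: float = 0.5                   # uS added at weight 1
    sc_drift: float = 1.0e-4               # uS per s of task time
    sc_block_sd: float = 0.45              # uS per-block random offset
    sc_noise: float = 0.15                 # uS slow noise RMS
    sc_phasic_amp: float = 1.5             # uS block-onset peak amplitude
    sc_phasic_tau: float = 10.0            # s decay constant

    # -- gaze generator ------------------------------------------------------
    pupil_base: float = 3.2                # mm
    pupil_gain: float = 0.30               # mm added at weight 1
    pupil_drift: float = -4.0e-5           # mm per s of task time
    pupil_block_sd: float = 0.28           # mm per-block random offset
    pupil_noise: float = 0.05              # mm slow noise RMS
    blink_rate_base: float = 18.0          # blinks / min at zero load
    blink_rate_suppression: float = 0.40   # fractional rate loss at weight 1
    blink_rate_block_sd: float = 0.30      # fractional per-block rate offset
    tracking_loss_rate: float = 0.15       # >25-frame loss runs / min

    # -- bookkeeping ---------------------------------------------------------
    seed: int = 0
    streams: tuple[str, ...] = ("eeg", "ecg", "sc", "resp", "gaze")

    def __post_init__(self) -> None:
        if min(self.fs_eeg, self.fs_physio, self.fs_gaze) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_participants < 1 or self.n_sessions < 1:
            raise ValueError("need at least one participant and session")
        if not math.isclose(self.block_duration, self.letters_per_block * self.soa):
            raise ValueError(
                "block_duration must equal letters_per_block * soa "
                f"({self.letters_per_block} * {self.soa} != {self.block_duration})"
            )
        n_targets = self.target_fraction * self.letters_per_block
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ValueError("target_fraction * letters_per_block must be an integer")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
        unknown = set(self.streams) - {"eeg", "ecg", "sc", "resp", "gaze"}
        if unknown:
            raise ValueError(f"unknown streams: {sorted(unknown)}")

    # -- derived quantities --------------------------------------------------
    @property
    def n_targets_per_block(self) -> int:
        return round(self.target_fraction * self.letters_per_block)

    @property
    def blocks_per_session(self) -> int:
        """Baseline block plus the workload blocks."""
        return 1 + len(WORKLOAD_CONDITIONS) * self.reps_per_condition

    @property
    def n_blocks_total(self) -> int:
        return self.n_sessions * self.blocks_per_session

    @property
    def total_task_minutes(self) -> float:
        """Summed duration of all blocks (baseline included), in minutes."""
        return self.n_blocks_total * self.block_duration / 60.0

    @property
    def session_duration(self) -> float:
        """Recording length of one session, in seconds."""
        return self.blocks_per_session * (self.block_duration + self.inter_block_gap)

    def condition_weight(self, condition: str) -> float:
        """Effect-size multiplier for a block condition (baseline -> 0)."""
        if condition == "baseline":
            return 0.0
        return self.level_weights[WORKLOAD_CONDITIONS.index(condition)]

    def with_(self, **updates) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    def zero_effect(self) -> "SimulationConfig":
        """Copy with every workload effect and drift set to zero (null model)."""
        return self.with_(
            alpha_suppression=0.0, theta_gain=0.0, p300_attenuation=0.0,
            rri_workload_effect=0.0, rri_drift=0.0, hrv_suppression=0.0,
            resp_rate_gain=0.0, resp_rate_drift=0.0,
            sc_gain=0.0, sc_drift=0.0,
            pupil_gain=0.0, pupil_drift=0.0, blink_rate_suppression=0.0,
        )
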