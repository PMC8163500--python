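"""Synthetic multi-channel neural recordings for the dichotic paradigm.

Each simulated trial contains the statistical structure the analysis
assumes, with known ground truth:

* a syllable-rate evoked response — a fixed biphasic kernel (150 ms
  support) convolved with the 4 Hz syllable-onset train, present on all
  channels in both conditions;
* a phrase-rate component — a 1 Hz sinusoid phase-locked to sentence
  onsets, injected only in the Structured condition and only on a
  designated channel group.  Its phase is fixed per participant (so it is
  coherent across that participant's segments) but varies across
  participants;
* a linear response to the to-be-attended speech envelope — the true
  temporal response function convolved with the envelope, with an
  optional gain applied within a lag window on a channel group when the
  competing stream is Structured (the condition effect on speech
  tracking);
* 1/f background noise with configurable spectral exponent.

Per-participant variability enters through log-normal amplitude gains and
the participant-specific phrase phase.  All randomness derives from the
configuration seed, so a simulated experiment is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from . import stimgen

__all__ = [
    "SimConfig",
    "TrialRecording",
    "GroundTruth",
    "default_trf_kernel",
    "make_pink_noise",
    "make_attended_envelope",
    "simulate_trial",
    "simulate_experiment",
    "simulate_behavior",
    "save_dataset",
    "load_dataset",
]

STRUCTURED = "Structured"
NONSTRUCTURED = "NonStructured"


def default_trf_kernel(n_channels: int, sample_rate: float,
                       lag_range: tuple = (-0.050, 0.400),
                       peak_lags: tuple = (0.080, 0.140),
                       seed: int = 7) -> tuple:
    """A plausible speech-tracking kernel: two lobes at ~80 and ~140 ms.

    Returns ``(kernel, lags)`` with kernel of shape (n_channels, n_lags).
    Channel topography alternates polarity with smoothly varying gain, as
    for a dipolar field pattern.
    """
    lags = np.arange(round(lag_range[0] * sample_rate),
                     round(lag_range[1] * sample_rate) + 1) / sample_rate
    early = np.exp(-0.5 * ((lags - peak_lags[0]) / 0.012) ** 2)
    late = -0.8 * np.exp(-0.5 * ((lags - peak_lags[1]) / 0.018) ** 2)
    shape = early + late
    rng = np.random.default_rng(seed)
    gains = rng.uniform(0.6, 1.4, size=n_channels)
    polarity = np.where(np.arange(n_channels) % 2 == 0, 1.0, -1.0)
    return (gains * polarity)[:, None] * shape[None, :], lags


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Amplitudes are in arbitrary units relative to unit-variance 1/f noise.
    Defaults are calibrated so that, at the default trial and participant
    counts, the group-level syllable-rate (4 Hz) ITPC effect is large
    (Cohen's d > 1.5) and the phrase-rate (1 Hz) condition effect is
    moderate (d around 0.6), the regime reported for this paradigm.
    """

    n_participants: int = 29
    n_channels: int = 16
    n_trials_per_condition: int = 15
    sample_rate: float = 250.0
    n_sentences_per_trial: int = 22  # 44 s trials
    syllable_response_amp: float = 0.4
    phrase_response_amp: float = 0.028
    phrase_channels: tuple = (0, 1, 4, 5)
    trf_amp: float = 0.01
    trf_structured_gain: float = 1.5
    trf_gain_channels: tuple = (0, 1, 4, 5)
    trf_gain_window: tuple = (0.070, 0.180)
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    participant_amp_sd: float = 0.45  # log-normal sigma of per-participant gains
    stim_bank_size: int = 32
    stim_inventory_size: int = 12
    stim_sample_rate: float = 1000.0
    seed: int = 0
    trf_kernel_true: np.ndarray | None = None
    trf_lags: np.ndarray | None = None

    def __post_init__(self):
        if min(self.syllable_response_amp, self.phrase_response_amp,
               self.noise_amp) < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if any(c >= self.n_channels or c < 0 for c in self.phrase_channels):
            raise ValueError("phrase_channels must be a subset of all channels")
        if self.trf_kernel_true is None:
            self.trf_kernel_true, self.trf_lags = default_trf_kernel(
                self.n_channels, self.sample_rate)

    @property
    def trial_dur(self) -> float:
        return self.n_sentences_per_trial * 2.0

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_dur * self.sample_rate))


@dataclass(frozen=True)
class TrialRecording:
    """Simulated channels x samples data for one trial."""

    data: np.ndarray
    condition: str
    attended_envelope: np.ndarray
    tag_onset_index: int
    participant_id: int
    trial_id: int
    sample_rate: float


@dataclass
class GroundTruth:
    """What was injected, for recovery tests and dataset sidecars."""

    syllable_amp_per_channel: np.ndarray
    phrase_amp_per_channel: dict  # condition -> (n_channels,) array
    phrase_channels: tuple
    trf_kernel_true: np.ndarray
    trf_lags: np.ndarray
    trf_structured_gain: float
    trf_gain_channels: tuple
    trf_gain_window: tuple
    noise_exponent: float
    seed: int
    participant_phases: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return list(x)
            return x
        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in asdict(self).items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["syllable_amp_per_channel"] = np.asarray(raw["syllable_amp_per_channel"])
        raw["phrase_amp_per_channel"] = {k: np.asarray(v) for k, v in
                                         raw["phrase_amp_per_channel"].items()}
        raw["trf_kernel_true"] = np.asarray(raw["trf_kernel_true"])
        raw["trf_lags"] = np.asarray(raw["trf_lags"])
        for k in ("phrase_channels", "trf_gain_channels", "trf_gain_window"):
            raw[k] = tuple(raw[k])
        raw["participant_phases"] = {int(k): float(v) for k, v in
                                     raw["participant_phases"].items()}
        return cls(**raw)


def make_pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                    sample_rate: float, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping[None, :], n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def make_attended_envelope(rng: np.random.Generator, n_samples: int,
                           sample_rate: float, cutoff_hz: float = 8.0) -> np.ndarray:
    """Smoothed positive random envelope standing in for narrated speech."""
    x = rng.standard_normal(n_samples)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    spec[f > cutoff_hz] = 0.0
    y = np.fft.irfft(spec, n_samples)
    y = y - y.min()
    return y / max(y.std(), 1e-12)


def _evoked_kernel(sample_rate: float, support: float = 0.150) -> np.ndarray:
    """Fixed biphasic syllable-evoked kernel of 150 ms support."""
    n = int(round(support * sample_rate))
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n)


def _participant_rng(cfg: SimConfig, participant_id: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 1_000_003, participant_id])


def _participant_params(cfg: SimConfig, participant_id: int) -> dict:
    rng = _participant_rng(cfg, participant_id)
    return {
        "phrase_phase": float(rng.uniform(0, 2 * np.pi)),
        "phrase_gain": float(np.exp(cfg.participant_amp_sd * rng.standard_normal())),
        "syllable_gain": float(np.exp(0.2 * rng.standard_normal())),
        "channel_gain": rng.uniform(0.7, 1.3, size=cfg.n_channels),
    }


def _true_trf_for(cfg: SimConfig, condition: str) -> np.ndarray:
    kernel = cfg.trf_kernel_true * cfg.trf_amp
    if condition == STRUCTURED and cfg.trf_structured_gain != 1.0:
        kernel = kernel.copy()
        lo, hi = cfg.trf_gain_window
        win = (cfg.trf_lags >= lo - 1e-9) & (cfg.trf_lags <= hi + 1e-9)
        idx = np.asarray(cfg.trf_gain_channels, dtype=int)
        kernel[np.ix_(idx, np.flatnonzero(win))] *= cfg.trf_structured_gain
    return kernel


def _convolve_trf(kernel: np.ndarray, lags: np.ndarray, envelope: np.ndarray,
                  sample_rate: float) -> np.ndarray:
    """Causal/anticausal convolution r(t) = sum_l k(l) s(t - l)."""
    n = envelope.shape[0]
    lag_samples = np.round(lags * sample_rate).astype(int)
    out = np.zeros((kernel.shape[0], n))
    for j, l in enumerate(lag_samples):
        if l >= 0:
            out[:, l:] += kernel[:, j:j + 1] * envelope[None, : n - l]
        else:
            out[:, : n + l] += kernel[:, j:j + 1] * envelope[None, -l:]
    return out


def simulate_trial(cfg: SimConfig, condition: str,
                   task_irrelevant_seq, attended_envelope: np.ndarray,
                   participant_id: int, trial_id: int) -> TrialRecording:
    """Simulate one trial's channels x samples recording.

    The task-irrelevant sequence fixes the syllable/sentence onset grid;
    the attended envelope drives the speech-tracking response.
    """
    n = int(round(task_irrelevant_seq.duration * cfg.sample_rate))
    envelope = np.asarray(attended_envelope, dtype=float)
    if envelope.shape[0] != n:
        raise ValueError(
            f"attended envelope ({envelope.shape[0]} samples) does not match the "
            f"task-irrelevant sequence duration ({n} samples at {cfg.sample_rate} Hz)")
    if condition not in (STRUCTURED, NONSTRUCTURED):
        raise ValueError(f"unknown condition {condition!r}")
    params = _participant_params(cfg, participant_id)
    rng = np.random.default_rng([cfg.seed, 7_777_777, participant_id, trial_id,
                                 0 if condition == STRUCTURED else 1])
    t = np.arange(n) / cfg.sample_rate

    # syllable-rate evoked response, all channels
    onset_train = np.zeros(n)
    onsets = np.arange(0, n, int(round(stimgen.SYLLABLE_DUR * cfg.sample_rate)))
    onset_train[onsets] = 1.0
    evoked = np.convolve(onset_train, _evoked_kernel(cfg.sample_rate))[:n]
    data = (cfg.syllable_response_amp * params["syllable_gain"]
            * params["channel_gain"][:, None] * evoked[None, :])

    # phrase-rate component, Structured only, designated channels only
    if condition == STRUCTURED and cfg.phrase_response_amp > 0:
        phrase = np.sin(2 * np.pi * stimgen.TAG_RATES["phrase"] * t
                        + params["phrase_phase"])
        idx = np.asarray(cfg.phrase_channels, dtype=int)
        data[idx] += cfg.phrase_response_amp * params["phrase_gain"] * phrase

    # linear response to the attended envelope
    if cfg.trf_amp != 0:
        kernel = _true_trf_for(cfg, condition)
        data = data + _convolve_trf(kernel, cfg.trf_lags, envelope,
                                    cfg.sample_rate)

    if cfg.noise_amp > 0:
        data = data + cfg.noise_amp * make_pink_noise(
            rng, cfg.n_channels, n, cfg.sample_rate, cfg.noise_exponent)

    return TrialRecording(data=data, condition=condition,
                          attended_envelope=envelope, tag_onset_index=0,
                          participant_id=participant_id, trial_id=trial_id,
                          sample_rate=cfg.sample_rate)


def simulate_experiment(cfg: SimConfig) -> tuple:
    """Simulate all participants x conditions x trials.

    Returns ``(recordings, ground_truth)`` where ``recordings`` is a flat
    list of :class:`TrialRecording`.  Each trial gets a freshly generated
    task-irrelevant sequence (Structured trials draw sentences from one
    fixed inventory shared by the whole experiment, as in the stimulus
    design) and a fresh attended envelope.
    """
    stim_rng = np.random.default_rng([cfg.seed, 42])
    bank = stimgen.make_syllable_bank(cfg.stim_bank_size, cfg.stim_sample_rate,
                                      seed=int(stim_rng.integers(2**31)))
    inventory = stimgen.build_sentence_inventory(
        bank, cfg.stim_inventory_size, seed=int(stim_rng.integers(2**31)))

    recordings = []
    phases = {}
    for pid in range(cfg.n_participants):
        phases[pid] = _participant_params(cfg, pid)["phrase_phase"]
        for cond_idx, condition in enumerate((STRUCTURED, NONSTRUCTURED)):
            for tid in range(cfg.n_trials_per_condition):
                seq_seed = int(np.random.default_rng(
                    [cfg.seed, 99, pid, cond_idx, tid]).integers(2**31))
                if condition == STRUCTURED:
                    seq = stimgen.build_structured_sequence(
                        bank, inventory, cfg.n_sentences_per_trial, seed=seq_seed)
                else:
                    seq = stimgen.build_nonstructured_sequence(
                        bank, cfg.n_sentences_per_trial * 8, seed=seq_seed)
                env_rng = np.random.default_rng([cfg.seed, 55, pid, cond_idx, tid])
                envelope = make_attended_envelope(env_rng, cfg.trial_samples,
                                                 cfg.sample_rate)
                recordings.append(simulate_trial(
                    cfg, condition, seq, envelope, pid,
                    cond_idx * cfg.n_trials_per_condition + tid))

    params0 = _participant_params(cfg, 0)
    phrase_amp = {c: np.zeros(cfg.n_channels) for c in (STRUCTURED, NONSTRUCTURED)}
    phrase_amp[STRUCTURED][list(cfg.phrase_channels)] = cfg.phrase_response_amp
    truth = GroundTruth(
        syllable_amp_per_channel=cfg.syllable_response_amp * params0["channel_gain"],
        phrase_amp_per_channel=phrase_amp,
        phrase_channels=tuple(cfg.phrase_channels),
        trf_kernel_true=cfg.trf_kernel_true * cfg.trf_amp,
        trf_lags=cfg.trf_lags,
        trf_structured_gain=cfg.trf_structured_gain,
        trf_gain_channels=tuple(cfg.trf_gain_channels),
        trf_gain_window=tuple(cfg.trf_gain_window),
        noise_exponent=cfg.noise_exponent,
        seed=cfg.seed,
        participant_phases=phases,
    )
    return recordings, truth


def simulate_behavior(cfg: SimConfig, per_participant_accuracy_mean: float = 0.715,
                      sd: float = 0.15, seed: int | None = None,
                      n_questions: int = 4) -> pd.DataFrame:
    """Bernoulli answer table for the four comprehension questions per trial.

    Participant-specific correct-answer rates are drawn from a normal
    distribution and clipped to [1/3, 1] (guessing floor of 3-alternative
    questions).  Defaults mirror the reported group accuracy (0.715 ± 0.15).
    """
    if not 0 <= per_participant_accuracy_mean <= 1:
        raise ValueError("accuracy mean must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for pid in range(cfg.n_participants):
        rate = float(np.clip(rng.normal(per_participant_accuracy_mean, sd),
                             1.0 / 3.0, 1.0))
        for condition in (STRUCTURED, NONSTRUCTURED):
            for tid in range(cfg.n_trials_per_condition):
                correct = rng.random(n_questions) < rate
                for q in range(n_questions):
                    rows.append({"participant_id": pid, "trial_id": tid,
                                 "condition": condition, "question_index": q + 1,
                                 "correct": bool(correct[q])})
    return pd.DataFrame(rows)


def save_dataset(path, recordings: Sequence[TrialRecording],
                 ground_truth: GroundTruth | None = None) -> None:
    """Persist trials as /participant_{p}/trial_{t}/{data,envelope} in HDF5.

    The ground truth, if given, goes to a ``<path>.truth.json`` sidecar.
    """
    with h5py.File(path, "w") as fh:
        for rec in recordings:
            grp = fh.require_group(f"participant_{rec.participant_id}") \
                    .create_group(f"trial_{rec.trial_id}")
            grp.create_dataset("data", data=rec.data)
            grp.create_dataset("envelope", data=rec.attended_envelope)
            grp.attrs["condition"] = rec.condition
            grp.attrs["tag_onset_index"] = rec.tag_onset_index
            grp.attrs["sample_rate"] = rec.sample_rate
    if ground_truth is not None:
        ground_truth.to_json(str(path) + ".truth.json")


def load_dataset(path) -> list:
    recordings = []
    with h5py.File(path, "r") as fh:
        for pname in sorted(fh, key=lambda s: int(s.split("_")[1])):
            for tname in sorted(fh[pname], key=lambda s: int(s.split("_")[1])):
                grp = fh[pname][tname]
                recordings.append(TrialRecording(
                    data=grp["data"][()],
                    condition=str(grp.attrs["condition"]),
                    attended_envelope=grp["envelope"][()],
                    tag_onset_index=int(grp.attrs["tag_onset_index"]),
                    participant_id=int(pname.split("_")[1]),
                    trial_id=int(tname.split("_")[1]),
                    sample_rate=float(grp.attrs["sample_rate"])))
    return recordings
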