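"""Construction of hierarchical frequency-tagged syllable sequences.

Isochronous 250 ms synthetic syllable tokens are concatenated into either
linguistically Structured sequences (two syllables per word, two words per
phrase, two phrases per sentence, tagging the four levels at 4 / 2 / 1 /
0.5 Hz) or Non-Structured sequences (the same tokens in fully random
order).  The modulation spectrum of a sequence's broadband RMS envelope is
computed with the same segmentation used for the neural spectral analysis,
so stimulus and response spectra are directly comparable.

Tokens are synthetic stand-ins for recorded syllables: band-limited noise
carriers shaped by token-specific amplitude contours, intensity-equated
across the bank.  Half of the bank emulates word-initial syllables (energy
filling the full 250 ms slot) and half word-final syllables (shorter
energy followed by silence padding, as when a shorter recording is padded
to the fixed slot).  Because Structured sentences alternate these classes
at the 2 Hz word rate, the Structured envelope acquires a 2 Hz modulation
component that the Non-Structured ordering lacks — the acoustic word-rate
confound inherent to this stimulus design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SYLLABLE_DUR",
    "TAG_RATES",
    "SyllableToken",
    "StimulusSequence",
    "ModulationSpectrum",
    "make_syllable_bank",
    "build_sentence_inventory",
    "build_structured_sequence",
    "build_nonstructured_sequence",
    "apply_onset_ramp",
    "extract_envelope",
    "modulation_spectrum",
    "sequence_modulation_spectrum",
    "peak_frequency",
    "flanker_excess",
    "write_wav",
    "spectrum_to_tsv",
]

#: Duration of one syllable slot in seconds.
SYLLABLE_DUR = 0.250

#: Presentation rate of each linguistic level in a Structured sequence (Hz).
TAG_RATES = {"syllable": 4.0, "word": 2.0, "phrase": 1.0, "sentence": 0.5}

_SYLLABLES_PER_SENTENCE = 8
_FADE_DUR = 0.025  # fade-out applied to the kernel tail, avoids clicks
_TARGET_RMS = 0.1


@dataclass(frozen=True)
class SyllableToken:
    """One 250 ms acoustic unit: the atom of all stimuli."""

    token_id: int
    envelope_kernel: np.ndarray  # nonnegative amplitude contour, one slot long
    carrier_spec: dict  # {"center_hz": float, "bandwidth_hz": float}
    token_class: str  # "word_initial" | "word_final"
    waveform: np.ndarray  # rendered audio, intensity-equated
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[0]


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered syllable-token sequence with its rendered audio."""

    condition: str  # "Structured" | "NonStructured"
    token_ids: tuple
    waveform: np.ndarray
    envelope: np.ndarray
    sample_rate: float
    tag_rates: dict = field(default_factory=lambda: dict(TAG_RATES))
    onset_ramp_dur: float = 0.0

    @property
    def duration(self) -> float:
        return self.waveform.shape[0] / self.sample_rate


@dataclass(frozen=True)
class ModulationSpectrum:
    """Segment-averaged FFT magnitude of an amplitude envelope."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    segment_dur: float


def _smooth_contour(rng: np.random.Generator, n: int, sample_rate: float) -> np.ndarray:
    """Token-specific smooth positive modulation of the base syllable shape."""
    # low-pass white noise (~40 Hz) -> token-specific contour detail
    width = max(2, int(round(sample_rate / 40.0)))
    noise = uniform_filter1d(rng.standard_normal(n), size=width, mode="reflect")
    noise /= max(np.std(noise), 1e-12)
    return np.clip(1.0 + 0.30 * noise, 0.2, None)


def _band_noise(rng: np.random.Generator, n: int, sample_rate: float,
                center_hz: float, bandwidth_hz: float) -> np.ndarray:
    """Band-limited Gaussian noise carrier (FFT-masked white noise)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    lo = max(center_hz - bandwidth_hz / 2, 10.0)
    spec[(f < lo) | (f > center_hz + bandwidth_hz / 2)] = 0
    y = np.fft.irfft(spec, n)
    return y / max(np.std(y), 1e-12)


def make_syllable_bank(n_tokens: int, sample_rate: float = 1000.0,
                       seed: int = 0) -> list[SyllableToken]:
    """Create a bank of distinct, intensity-equated 250 ms syllable tokens.

    The first half of the bank is word-initial (energy over the full slot,
    faded out over the last 25 ms); the second half is word-final (a
    shorter burst followed by silence padding).  All tokens are scaled to
    a common RMS over the full slot.

    Parameters
    ----------
    n_tokens : number of tokens; at least 8 (one full sentence).
    sample_rate : audio sample rate in Hz, at least 200.
    seed : RNG seed; all token randomness derives from it.
    """
    if n_tokens < _SYLLABLES_PER_SENTENCE:
        raise ValueError(
            f"need at least {_SYLLABLES_PER_SENTENCE} tokens to form one sentence, "
            f"got {n_tokens}")
    if sample_rate < 200:
        raise ValueError(f"sample_rate must be >= 200 Hz, got {sample_rate}")

    rng = np.random.default_rng(seed)
    n = int(round(SYLLABLE_DUR * sample_rate))
    n_fade = max(2, int(round(_FADE_DUR * sample_rate)))
    n_initial = n_tokens // 2 + n_tokens % 2

    tokens: list[SyllableToken] = []
    for token_id in range(n_tokens):
        word_initial = token_id < n_initial
        if word_initial:
            n_active = n
        else:
            # shorter recording, padded with silence to the fixed slot
            n_active = int(round(rng.uniform(0.64, 0.80) * n))
        kernel = np.zeros(n)
        # base syllable shape: fast rise, marked decay over the active part
        t = np.arange(n_active) / n_active
        rise = rng.uniform(0.02, 0.05)
        decay = rng.uniform(0.70, 0.90)
        base = np.minimum(t / rise, 1.0) * (1.0 - decay * t)
        kernel[:n_active] = base * _smooth_contour(rng, n_active, sample_rate)
        # monotone fade to zero on the kernel tail (truncation de-click)
        fade_start = n_active - n_fade
        kernel[fade_start:n_active] *= np.linspace(1.0, 0.0, n_fade)
        kernel = np.clip(kernel, 0.0, None)
        # contract: the faded tail decays monotonically to 0
        kernel[fade_start:n_active] = np.minimum.accumulate(
            kernel[fade_start:n_active])

        center = rng.uniform(0.15, 0.30) * sample_rate
        bandwidth = 0.25 * sample_rate
        carrier = _band_noise(rng, n, sample_rate, center, bandwidth)
        waveform = carrier * kernel
        scale = _TARGET_RMS / np.sqrt(np.mean(waveform**2))
        tokens.append(SyllableToken(
            token_id=token_id,
            envelope_kernel=kernel * scale,
            carrier_spec={"center_hz": center, "bandwidth_hz": bandwidth},
            token_class="word_initial" if word_initial else "word_final",
            waveform=waveform * scale,
            sample_rate=sample_rate,
        ))
    return tokens


def build_sentence_inventory(bank: Sequence[SyllableToken], n_sentences: int = 12,
                             seed: int = 0) -> list[tuple]:
    """Draw a fixed inventory of 8-syllable sentences from a token bank.

    Word-initial slots (positions 0, 2, 4, 6) take word-initial tokens and
    word-final slots take word-final tokens, so every sentence realises the
    syllable/word/phrase/sentence hierarchy on the 4/2/1/0.5 Hz grid.
    """
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    rng = np.random.default_rng(seed)
    initial_ids = [t.token_id for t in bank if t.token_class == "word_initial"]
    final_ids = [t.token_id for t in bank if t.token_class == "word_final"]
    inventory = []
    for _ in range(n_sentences):
        ini = rng.choice(initial_ids, size=4, replace=len(initial_ids) < 4)
        fin = rng.choice(final_ids, size=4, replace=len(final_ids) < 4)
        sentence = tuple(int(x) for pair in zip(ini, fin) for x in pair)
        inventory.append(sentence)
    return inventory


def _render(bank: Sequence[SyllableToken], token_ids: Sequence[int],
            condition: str) -> StimulusSequence:
    by_id = {t.token_id: t for t in bank}
    waveform = np.concatenate([by_id[i].waveform for i in token_ids])
    sr = bank[0].sample_rate
    return StimulusSequence(
        condition=condition,
        token_ids=tuple(int(i) for i in token_ids),
        waveform=waveform,
        envelope=extract_envelope(waveform, sr),
        sample_rate=sr,
    )


def build_structured_sequence(bank: Sequence[SyllableToken],
                              sentence_inventory: Sequence[tuple],
                              n_sentences: int, seed: int = 0) -> StimulusSequence:
    """Concatenate ``n_sentences`` sentences drawn (with replacement) from a
    fixed inventory, with no acoustic gaps between syllables."""
    if len(sentence_inventory) == 0:
        raise ValueError("sentence inventory is empty")
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    for s in sentence_inventory:
        if len(s) != _SYLLABLES_PER_SENTENCE:
            raise ValueError("every inventory sentence must have exactly 8 tokens")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(sentence_inventory), size=n_sentences)
    token_ids = [tid for k in picks for tid in sentence_inventory[k]]
    return _render(bank, token_ids, "Structured")


def build_nonstructured_sequence(bank: Sequence[SyllableToken], n_syllables: int,
                                 seed: int = 0) -> StimulusSequence:
    """Concatenate ``n_syllables`` uniformly random token draws."""
    if n_syllables < 1:
        raise ValueError("n_syllables must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [bank[k].token_id for k in rng.integers(0, len(bank), size=n_syllables)]
    return _render(bank, ids, "NonStructured")


def apply_onset_ramp(seq: StimulusSequence, ramp_dur: float = 3.0) -> StimulusSequence:
    """Fade the sequence in linearly over its first ``ramp_dur`` seconds.

    Samples at or beyond ``ramp_dur`` are returned unchanged.
    """
    if ramp_dur >= seq.duration:
        raise ValueError(
            f"ramp_dur ({ramp_dur} s) must be shorter than the sequence "
            f"({seq.duration} s)")
    n_ramp = int(round(ramp_dur * seq.sample_rate))
    gain = np.ones_like(seq.waveform)
    gain[:n_ramp] = np.arange(n_ramp) / n_ramp
    waveform = seq.waveform * gain
    return replace(seq, waveform=waveform,
                   envelope=extract_envelope(waveform, seq.sample_rate),
                   onset_ramp_dur=ramp_dur)


def extract_envelope(waveform: np.ndarray, sample_rate: float,
                     window: float = 0.010) -> np.ndarray:
    """Broadband envelope: centred sliding-window RMS of the audio.

    Reflect padding at the edges avoids spurious onset transients.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("waveform is empty")
    win = int(round(window * sample_rate))
    if win < 2:
        raise ValueError(f"window of {window} s is shorter than 2 samples "
                         f"at {sample_rate} Hz")
    power = uniform_filter1d(waveform**2, size=win, mode="reflect")
    return np.sqrt(np.clip(power, 0.0, None))  # filter rounding can dip below 0


def modulation_spectrum(envelope: np.ndarray, sample_rate: float,
                        segment_dur: float = 8.0) -> ModulationSpectrum:
    """Segment the envelope into non-overlapping ``segment_dur`` windows,
    FFT each, and average the magnitudes across segments."""
    envelope = np.asarray(envelope, dtype=float)
    n_seg_samples = int(round(segment_dur * sample_rate))
    n_segments = envelope.shape[0] // n_seg_samples
    if n_segments < 1:
        raise ValueError(
            f"envelope ({envelope.shape[0] / sample_rate:.2f} s) shorter than "
            f"one {segment_dur} s segment")
    segments = envelope[: n_segments * n_seg_samples].reshape(n_segments, n_seg_samples)
    mags = np.abs(np.fft.rfft(segments, axis=1)) / n_seg_samples
    freqs = np.fft.rfftfreq(n_seg_samples, d=1.0 / sample_rate)
    return ModulationSpectrum(freqs=freqs, power=mags.mean(axis=0),
                              n_segments=n_segments, segment_dur=segment_dur)


def sequence_modulation_spectrum(seq: StimulusSequence,
                                 segment_dur: float = 8.0) -> ModulationSpectrum:
    """Modulation spectrum of a sequence, discarding any onset ramp first
    (trial starts are excluded from analysis)."""
    start = int(round(seq.onset_ramp_dur * seq.sample_rate))
    return modulation_spectrum(seq.envelope[start:], seq.sample_rate, segment_dur)


def peak_frequency(spec: ModulationSpectrum, fmin: float = 0.2,
                   fmax: float | None = None) -> float:
    """Frequency of the largest spectral magnitude with ``fmin < f``
    (excluding DC and near-DC bins) and, optionally, ``f < fmax``."""
    mask = spec.freqs > fmin
    if fmax is not None:
        mask &= spec.freqs < fmax
    idx = np.flatnonzero(mask)
    return float(spec.freqs[idx[np.argmax(spec.power[idx])]])


def flanker_excess(spec: ModulationSpectrum, freq: float, n_flank: int = 2) -> float:
    """Power at ``freq`` minus the mean of ``n_flank`` bins on each side."""
    i = int(np.argmin(np.abs(spec.freqs - freq)))
    flank = np.r_[spec.power[i - n_flank: i], spec.power[i + 1: i + 1 + n_flank]]
    return float(spec.power[i] - flank.mean())


def write_wav(path, seq: StimulusSequence) -> None:
    """Render a sequence to 16-bit PCM WAV (peak-normalized to 0.9 FS)."""
    x = seq.waveform / max(np.max(np.abs(seq.waveform)), 1e-12) * 0.9
    wavfile.write(path, int(round(seq.sample_rate)), (x * 32767).astype(np.int16))


def spectrum_to_tsv(path, spec: ModulationSpectrum, condition: str) -> None:
    pd.DataFrame({"freq_hz": spec.freqs, "power": spec.power,
                  "condition": condition}).to_csv(path, sep="\t", index=False)
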