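"""Simulate a small cohort and test for phase-locked tag-rate peaks.

Recordings are segmented into sentence-aligned 8 s windows; inter-trial
phase coherence (Rayleigh z) is computed per channel and frequency bin,
and each frequency of interest is tested against its flanking bins across
participants.
"""

import numpy as np

from hftag import neurosim, spectral

cfg = neurosim.SimConfig(n_participants=12, n_trials_per_condition=8, seed=0)
recordings, truth = neurosim.simulate_experiment(cfg)

for condition in ("Structured", "NonStructured"):
    spectra = []
    for pid in range(cfg.n_participants):
        recs = [r for r in recordings
                if r.participant_id == pid and r.condition == condition]
        segs = spectral.segment_trials(recs)
        spectra.append(spectral.channel_average(spectral.compute_itpc(segs)))
    z = np.asarray(spectra)
    freqs = spectral.compute_itpc(segs).freqs
    print(f"\n{condition}:")
    for foi in spectral.FOIS:
        res = spectral.foi_peak_test(z, freqs, foi)
        print(f"  {foi:4.1f} Hz: t = {res.t_stat:+6.2f}, p = {res.p:.4f}, "
              f"d = {res.cohen_d:+.2f}")

print("\nThe 4 Hz (syllable-rate) peak is strong in both conditions.  A")
print("positive 1 Hz (phrase-rate) effect appears only when the")
print("task-irrelevant stream is Structured; at this toy cohort size the")
print("moderate effect (d ~ 0.6) is a trend - the full experiment in")
print("examples/full_experiment.py at study scale makes it significant.")
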