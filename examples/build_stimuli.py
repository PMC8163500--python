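"""Build frequency-tagged syllable sequences and inspect their modulation
spectra.

Structured sequences nest words/phrases/sentences at 2/1/0.5 Hz on top of
the 4 Hz syllable rate; Non-Structured sequences use the same tokens in
random order.  Both must show a dominant 4 Hz envelope peak, and only the
Structured one acquires the acoustic 2 Hz word-rate confound.
"""

import numpy as np

from hftag import stimgen

bank = stimgen.make_syllable_bank(32, sample_rate=1000.0, seed=1)
inventory = stimgen.build_sentence_inventory(bank, n_sentences=12, seed=2)

structured = stimgen.build_structured_sequence(bank, inventory,
                                               n_sentences=32, seed=3)
nonstructured = stimgen.build_nonstructured_sequence(bank, n_syllables=256,
                                                     seed=3)

for seq in (structured, nonstructured):
    spec = stimgen.sequence_modulation_spectrum(seq)
    peak = stimgen.peak_frequency(spec)
    e2 = stimgen.flanker_excess(spec, 2.0)
    e1 = stimgen.flanker_excess(spec, 1.0)
    print(f"{seq.condition:>13}: {seq.duration:.0f} s, dominant envelope "
          f"peak at {peak} Hz; 2 Hz excess over flankers {e2:+.4f}, "
          f"1 Hz excess {e1:+.4f}")

print("\nThe 4 Hz peak is the syllable presentation rate; the positive 2 Hz")
print("excess appears only for Structured sequences (word-initial and")
print("word-final syllables differ acoustically), while 1 Hz and 0.5 Hz")
print("carry no envelope energy - any neural peak there must be linguistic.")
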