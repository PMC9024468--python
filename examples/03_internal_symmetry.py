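"""Profile the internal symmetry of stwintron-like sequences.

A sequence able to fold back into a hairpin is similar to its own reverse
complement.  The profile classifies every alignment column as a
Watson-Crick pair (M), a G.U wobble pair (W), unpaired (.) or a gap (-).
"""

import numpy as np

from stwintron import (
    call_terminal_inverted_repeat,
    palindrome_scan,
    random_background,
    reverse_complement,
    self_align,
)

rng = np.random.default_rng(11)

# a perfect 60-nt palindrome: every position pairs
arm = random_background(30, 0.5, rng)
perfect = arm + reverse_complement(arm)
profile = self_align(perfect)
print(f"perfect palindrome: match fraction {profile.match_fraction:.2f}, "
      f"{profile.gap_count} gaps")

# a stwintron-like construct: 50-nt terminal inverted repeat arms with 12
# substitutions (76% arm identity) around a 100-nt unrelated core
arm = random_background(50, 0.5, rng)
arm3 = list(reverse_complement(arm))
swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
for p in rng.choice(50, size=12, replace=False):
    arm3[p] = swap[arm3[p]]
tir_seq = arm + random_background(100, 0.5, rng) + "".join(arm3)

profile = self_align(tir_seq)
print(f"TIR construct: match fraction {profile.match_fraction:.2f} "
      f"(wobbles: {profile.wobble_count}, midpoint {profile.midpoint})")
call = call_terminal_inverted_repeat(tir_seq, (45, 55), min_identity=65)
print(f"terminal inverted repeat call: arm {call.arm_length} nt, "
      f"{call.identity:.0f}% identity")

# the 10-nt palindrome that centres the most symmetrical sister-derived introns
seq = random_background(30, 0.6, rng) + "CCTTTCTAGAAACC" + random_background(30, 0.6, rng)
for start, end in palindrome_scan(seq, min_len=10):
    print(f"palindrome at {start}-{end}: {seq[start:end]}")
# the reported window equals its own reverse complement — the hinge of a
# perfectly self-pairing hairpin stem
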