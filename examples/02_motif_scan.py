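"""Consensus motif scanning: find AP-1 sites (RATGASTCAT) on both strands.

Plants two concrete AP-1 instances — one forward, one on the reverse
strand — inside a random background sequence and scans for the degenerate
consensus. R matches A/G and S matches C/G; N in the genome matches nothing.
"""

import numpy as np

from regpot_target import MotifConsensus, reverse_complement, scan_sequence

rng = np.random.default_rng(0)
background = "".join(rng.choice(list("ACGT"), size=300))

forward_site = "AATGACTCAT"   # R->A, S->C
minus_site = "GATGAGTCAT"     # R->G, S->G, embedded as its reverse complement
seq = background[:100] + forward_site + background[100:200] \
    + reverse_complement(minus_site) + background[200:]

hits = scan_sequence(seq, MotifConsensus("RATGASTCAT", name="AP1"))
print(f"scanned {len(seq)} bp, found {len(hits)} hit(s):")
for h in hits:
    print(f"  [{h.interval.start:>4},{h.interval.end:>4}) strand {h.strand}  {h.matched_seq}")
print(
    "\nEach hit's matched_seq is read 5'->3' on the hit strand, so it always\n"
    "spells out an instance of the consensus; coordinates stay on the forward\n"
    "strand. Overlapping matches are all reported — a degenerate consensus can\n"
    "match both strands at nearly the same position, as at the first site here."
)
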