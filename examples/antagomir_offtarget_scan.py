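"""Scan the anti-miR21 antagomir against a pri-miRNA for complementarity.

Slides the full 25-nt antagomir across a synthetic pri-miRNA hairpin into
whose 3' arm the antagomir's reverse complement has been embedded, scoring
Watson-Crick pairs (1.0) and G:U wobbles (0.5) at every offset, and prints
the top windows.  The top hit is the candidate hybrid region through which
the antagomir could sequester the primary transcript.
"""

import numpy as np

from mirseed import ReferenceSmallRNA, complementarity_scan, reverse_complement
from mirseed.hybridscan import ANTI_MIR21

anti = ReferenceSmallRNA("anti-miR21", ANTI_MIR21, "antagomir")

# synthetic pri-miRNA: random backbone with a perfectly pairing 3' region
rng = np.random.default_rng(0)
backbone = "".join(rng.choice(list("ACGT"), size=60))
pri = ReferenceSmallRNA(
    "pri-synthetic", backbone + reverse_complement(anti.sequence) + "GAUUC",
    "pri_hairpin",
)

hits = complementarity_scan(anti, pri, mode="complement", wobble_weight=0.5)
print(f"query: {anti.ref_id} ({len(anti.sequence)} nt), "
      f"target: {pri.ref_id} ({len(pri.sequence)} nt)\n")
print("rank  target span  WC pairs  G:U wobbles  score")
for rank, h in enumerate(hits[:5], 1):
    print(f"{rank:>4d}  {h.target_start:>3d}-{h.target_end:<8d} {h.matched_bases:>8d}"
          f" {h.wobble_bases:>12d} {h.score:>6.1f}")
print()
print("A score equal to the query length (25) is a perfect ungapped duplex;")
print("the top window marks where the antagomir would hybridize on the target.")
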