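"""Match isomiR-like reads against a mature miRNA by seed-and-grow.

Builds a 16-mer seed index over the mature miR21 sequence, matches three
reads (an exact copy, a 3'-shortened isomiR, and a read with an untemplated
5' tail), and prints each match's reference span and non-matching flanks,
then the stacked gapless alignment.
"""

from mirseed import ReferenceSmallRNA, build_index, export_stack, match_library

mir21 = ReferenceSmallRNA("miR21", "UAGCUUAUCAGACUGAUGUUGA", "mature")
index = build_index([mir21], k=16)

reads = [
    (mir21.sequence, 40),            # canonical mature sequence
    (mir21.sequence[:19], 12),       # 3' trimmed isomiR
    ("CC" + mir21.sequence, 3),      # untemplated 5' addition
]
records = match_library(reads, index, mode="best")

print("ref_id  span      flank5  flank3  occurrences")
for r in records:
    print(f"{r.ref_id:7s} {r.ref_start:>2d}-{r.ref_end:<7d} {r.flank5 or '-':7s}"
          f" {r.flank3 or '-':7s} {r.occurrences}")
print()
print(export_stack(records, mir21))
print("Spans are 1-based on the reference; lowercase bases in the stack are")
print("read ends that do not match the reference (isomiR heterogeneity or tails).")
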