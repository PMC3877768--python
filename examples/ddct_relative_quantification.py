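"""Livak 2^-ddCt relative quantification from qPCR threshold cycles.

Builds a small Ct table (miR21 and miR30 with 18s rRNA as the internal
standard, duplicate wells per condition) and prints each miRNA's ddCt,
relative quantity RQ = 2^-ddCt, and percent change in the treated arm.
"""

from mirseed import CtMeasurement, rq_from_measurements

wells = [
    # condition   gene    reference?  Ct
    ("mock",      "miR21", False, 24.90), ("mock",      "miR21", False, 25.10),
    ("mock",      "miR30", False, 27.00), ("mock",      "miR30", False, 27.04),
    ("mock",      "18s",   True,  14.98), ("mock",      "18s",   True,  15.02),
    ("antimir21", "miR21", False, 25.05), ("antimir21", "miR21", False, 25.25),
    ("antimir21", "miR30", False, 29.32), ("antimir21", "miR30", False, 29.36),
    ("antimir21", "18s",   True,  15.00), ("antimir21", "18s",   True,  15.00),
]
measurements = [
    CtMeasurement(f"s{i}", cond, gene, ref, ct)
    for i, (cond, gene, ref, ct) in enumerate(wells)
]

print("gene    ddCt     RQ      percent change")
for r in rq_from_measurements(measurements, control="mock", treated="antimir21"):
    print(f"{r.gene:7s} {r.delta_delta_ct:+.3f}  {r.rq:.3f}  {r.percent_change:+8.1f}%")
print()
print("RQ < 1 means less template in the treated arm: each extra threshold")
print("cycle of delay halves the estimated starting quantity.")
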