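"""Simulate a mock vs anti-miR21 experiment and recover the fold changes.

Generates 3 replicate libraries of 5,000 reads per condition with known
per-miRNA abundances (miR21 at 0.87x and miR30 at 0.20x in the treated arm),
runs trim -> match -> count -> compare, and prints the estimated fold change,
percent change and Student's t-test p-value per miRNA next to the configured
truth.
"""

from mirseed import (
    CountTable,
    build_index,
    collapse_reads,
    compare_all,
    count_matches,
    match_library,
    trim_library,
)
from mirseed.simulate import default_config, simulate_experiment

config = default_config(rng_seed=7, reads_per_library=5_000)
libraries, truth = simulate_experiment(config)

refs = [r.ref for r in config.references]
index = build_index(refs, k=16)
table = CountTable(sample_conditions={s: s.rsplit("_", 1)[0] for s in libraries})
for sample_id in sorted(libraries):
    collapsed = collapse_reads(trim_library(libraries[sample_id], config.adapter))
    table = count_matches(match_library(collapsed, index), sample_id, table)

print("miRNA   estimated fold  percent change  p-value   configured fold")
for res in compare_all(table, "mock", "antimir21"):
    configured = (
        config.abundances["antimir21"][res.ref_id]
        / config.abundances["mock"][res.ref_id]
    )
    print(f"{res.ref_id:7s} {res.fold_change:14.3f} {res.percent_change:+14.1f}%"
          f" {res.p_value:9.2e} {configured:16.3f}")
print()
print("A fold change of 0.87 is a 13% reduction of matched miR21 reads in the")
print("antagomir-treated arm; miR20/miR28 are near 1 (not perturbed).")
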