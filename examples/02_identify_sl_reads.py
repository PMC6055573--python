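"""Identify SL-containing reads among unmapped reads, three ways.

Runs the e-value route (seeded local alignment, significance at E < 0.05,
proper-configuration filter) and the two anchored routes (>= 5 nt overlap,
<= 10% mismatches) on the same simulated reads, and prints the
identification report: the sensitive routes find more reads (including
short 5-8-nt SL remnants) at the cost of specificity.
"""

import pandas as pd

from sltrans import SimConfig, SLDatabase, simulate_dataset, run_pipeline

ds = simulate_dataset(SimConfig(seed=1, unmapped_background_fraction=1.0))
db = SLDatabase.celegans()
reads = ds.reads.unmapped_reads()

rows = []
for mode in ("default", "sensitive", "tourasse"):
    result = run_pipeline(reads, ds.genome, db=db, mode=mode)
    rows.append(result.classification.report().iloc[0])
report = pd.DataFrame(rows).set_index("mode")
cols = ["input_reads", "significant_alignments",
        "significant_properly_configured", "accepted_SL1", "accepted_SL2"]
print(report[cols].to_string())
# Of the 1,000 planted SL reads, the e-value route accepts those whose SL
# remnant is >= 9 nt (shorter ones cannot reach significance); the anchored
# routes go down to 5 nt and therefore accept more, while background reads
# start leaking in as false positives.
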