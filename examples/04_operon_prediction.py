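"""Predict operon gene position from the per-gene SL2 ratio.

SL2 trans-splicing marks genes at position >= 2 within operons, so the
per-gene ratio SL2/(SL1+SL2) predicts downstream operon position. The
prediction is scored with an ROC sweep over ratio thresholds on the genes
with at least one detected trans-splicing event.
"""

from sltrans import SimConfig, simulate_dataset, run_pipeline, roc
from sltrans.quantify import gene_counts_to_frame

ds = simulate_dataset(SimConfig(seed=1, unmapped_background_fraction=1.0))
result = run_pipeline(ds.reads.unmapped_reads(), ds.genome,
                      genes=ds.genes, mode="default")

frame = gene_counts_to_frame(result.gene_counts)
detected = frame[(frame.sl1 + frame.sl2) >= 1]
print(f"genes with >= 1 trans-splicing event: {len(detected)} of {len(frame)}")
print(detected.groupby("downstream_in_operon").ratio.describe()[["count", "mean"]])

r = roc(result.gene_counts, min_events=1, fdr_bounds=(0.05,))
print(f"AUC = {r.auc:.3f}; TPR at 5% FDR = {r.tpr_at_fdr[0.05]:.3f}")
# Downstream operon genes receive SL2 with probability 0.95 in the
# simulation (0.05 elsewhere), so the ratio separates the two groups almost
# perfectly: AUC ~ 1 and TPR ~ 1 at a 5% false discovery rate.
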