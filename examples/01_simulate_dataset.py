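"""Simulate a toy trans-splicing experiment with ground truth.

Builds a 100-kb genome carrying 50 genes (40% in operons of 2-8 genes),
each with a trans-splice site at its 5' end preceded by the TTTCAG acceptor
consensus, then simulates 1,000 SL-containing reads (SL 3'-suffix lengths
peaked at 10-11 nt) and 9,000 genomic background reads.
"""

from sltrans import SimConfig, simulate_dataset

cfg = SimConfig(seed=1, unmapped_background_fraction=1.0)
ds = simulate_dataset(cfg)

truth_reads = ds.reads.truth.reads
truth_genes = ds.reads.truth.genes

n_operons = truth_genes.operon_id.nunique()
n_downstream = (truth_genes.operon_position >= 2).sum()
print(f"genome: {len(ds.genome.contigs['chrS']):,} nt, {len(ds.genes)} genes, "
      f"{n_operons} operons ({n_downstream} downstream genes)")
print(f"simulated reads: {truth_reads.is_sl.sum()} SL-containing + "
      f"{(~truth_reads.is_sl).sum()} background")
print("SL suffix length distribution (mode should sit at 10-11 nt):")
print(truth_reads[truth_reads.is_sl].sl_suffix_length
      .value_counts().sort_index().to_string())
# Every SL read starts with the 3' end of one of the 12 SL isoforms and
# continues with genomic sequence from its gene's trans-splice site; the
# truth tables record isoform, class, suffix length, site and gene per read.
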