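# sltrans

Detection and quantification of **spliced-leader (SL) trans-splicing** events
from RNA-seq data.

In many eukaryotes — most prominently the nematode *Caenorhabditis elegans* —
a short capped RNA called the spliced leader is trans-spliced onto the 5' end
of pre-mRNAs. *C. elegans* has two SL classes: SL1 marks ordinary trans-spliced
genes, while SL2 marks genes at position two and beyond within operons
(clusters of 2–8 genes transcribed from one promoter). Reads that straddle a
trans-splicing junction carry a 3' fragment of the 22-nt SL followed by
genomic sequence; they fail end-to-end mapping, so the unmapped output of a
first-pass aligner is exactly where the evidence hides.

`sltrans` takes those unmapped reads and:

1. **selects candidates** — single-end, or the left-most mate of a pair, optionally
   requiring the other mate to have mapped (`-p`);
2. **identifies SL fragments** by one of two routes:
   * *e-value route* (default): seeded local alignment (shared word of 8 nt,
     then full affine-gap Smith–Waterman) against the 12 bundled *C. elegans*
     SL isoforms, with Karlin–Altschul significance
     `E = K·m'·n'·exp(−λ·score) < 0.05` over a length-adjusted search space,
     and a **proper-configuration filter**: the alignment must start at the
     read's 5' end and cover the SL's 3' end — the geometric signature of a
     real junction;
   * *anchored route* (`-s` sensitive / tourasse): the SL 3' suffix is matched
     against the read 5' prefix over every overlap ≥ 5 nt, accepting at most
     10% mismatches — more sensitive, less specific;
3. **trims** the SL fragment (reads left < 15 nt are dropped) and **remaps**
   the remainder — internally (unspliced k-mer mapper, for toy genomes) or via
   FASTQ export / BAM import for an external spliced mapper;
4. **quantifies**: single-nucleotide **trans-splice sites** with the upstream
   acceptor dinucleotide (the near-invariant AG of the TTTCAG consensus) and
   per-position consensus matrices; per-gene SL1/SL2 counts; and the
   **SL2 ratio** `SL2/(SL1+SL2)` as a predictor of downstream operon position,
   evaluated by ROC/AUC and TPR at a false-discovery-rate bound.

A first-class **simulator** generates toy genomes with operon-structured
annotation, planted TTTCAG acceptor sites, SL reads with realistic 3'-suffix
length distributions (peaked at 10–11 nt, mimicking reverse-transcriptase
drop-off), background reads, paired-end geometry with dovetailing mates, and
complete ground-truth tables — so the whole pipeline is testable without any
download.

## Worked example

```python
from sltrans import SimConfig, simulate_dataset, run_pipeline, roc

ds = simulate_dataset(SimConfig(seed=1, unmapped_background_fraction=1.0))
result = run_pipeline(ds.reads.unmapped_reads(), ds.genome,
                      genes=ds.genes, mode="default")
print(len(result.classification.accepted), result.ag_site_fraction)
r = roc(result.gene_counts, fdr_bounds=(0.05,))
print(r.auc, r.tpr_at_fdr[0.05])
```

On this simulation (1,000 SL reads + 9,000 background, 50 genes) the run
prints `821 1.0` and `1.0 1.0`: 821 reads are accepted as SL-containing
(the e-value route recovers essentially all error-free reads whose SL remnant
is ≥ 9–10 nt; shorter remnants cannot reach significance), every called site
falls on a planted acceptor so the AG fraction is 1.0, and the SL2 ratio
separates downstream-operon genes perfectly (AUC = 1.0, TPR = 1.0 at 5% FDR).
The scripts in `examples/` walk through each capability — simulation,
identification in all three modes, site calling with the consensus matrix
(2.0 bits at each of the six planted TTTCAG positions), and operon
prediction — printing the numbers they compute.

There is also a thin CLI:

```bash
sltrans simulate --out-dir sim --seed 1
sltrans run --bam sim/reads.sam --genome sim/genome.fa --gff sim/genes.gff3 \
        --out-dir out          # add -s for the sensitive route, -p for paired mode
```

which writes the identification report, per-read calls, sites (TSV + BED6),
consensus matrices and gene counts as tab-separated tables.

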