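"""Synthetic genomes, operon-structured annotations and SL trans-spliced reads.

The simulator emulates the inputs of a nematode-style SL trans-splicing
experiment on a toy scale: a random genome (AT-rich, ~36% GC) carrying
non-overlapping genes on both strands, a fraction of them grouped into
operons of 2-8 adjacent same-strand genes; one trans-splice site at each
gene's 5' end with the invariant TTTCAG acceptor hexamer written
immediately upstream on the transcribed strand; SL-containing reads built
as a 3' suffix of an SL isoform (length distribution peaked at 10-11 nt,
mimicking reverse-transcriptase drop-off) followed by genomic sequence from
the gene's site; fully genomic background reads; and paired-end geometry
with dovetailing mates whenever the fragment is shorter than twice the read
length. Downstream operon genes receive SL2 with high probability, other
genes SL1, so the gene-level SL2-ratio predictor can be evaluated against
ground truth.

All randomness flows from a single integer seed through one numpy
Generator; identical configs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp
from .align import SLDatabase
from .quantify import GeneModel
from .remap import Genome
from .samio import Read, write_sam

ACCEPTOR_HEXAMER = "TTTCAG"

#: Fig-2C-like suffix-length weights: mode at 10-11 nt, tail to full length.
DEFAULT_SUFFIX_WEIGHTS: dict[int, float] = {
    5: 2, 6: 3, 7: 4, 8: 6, 9: 10, 10: 16, 11: 16, 12: 10, 13: 7, 14: 5,
    15: 4, 16: 3, 17: 3, 18: 2, 19: 2, 20: 2, 21: 2, 22: 3,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the toy scale used throughout the test-suite: a 100-kb
    genome at 36% GC with 50 genes (40% of them in operons of 2-8 genes),
    1,000 SL reads and 9,000 background reads of 50 nt, sequencing errors at
    0.1%, and SL2 given to downstream operon genes with probability 0.95
    (0.05 otherwise). The 50-nt read length matches the random-segment
    length used for the specificity analysis; under the uncorrected
    Karlin-Altschul expectation it also keeps 10-nt perfect SL matches
    (the modal alignment length) significant at E < 0.05.
    """

    genome_length: int = 100_000
    gc_content: float = 0.36
    n_genes: int = 50
    operon_fraction: float = 0.4
    operon_size_range: tuple[int, int] = (2, 8)
    n_sl_reads: int = 1000
    n_background_reads: int = 9000
    read_length: int = 50
    layout: str = "single"  # or "paired"
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 40.0
    sl_suffix_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SUFFIX_WEIGHTS)
    )
    sequencing_error_rate: float = 0.001
    sl2_given_downstream: float = 0.95
    sl2_given_other: float = 0.05
    unmapped_background_fraction: float = 0.10
    gene_length: int = 400
    intergenic_gap: int = 150
    contig_name: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "operon_fraction",
            "sequencing_error_rate",
            "sl2_given_downstream",
            "sl2_given_other",
            "unmapped_background_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.operon_size_range
        if not (2 <= lo <= hi <= 8):
            raise ValueError("operon sizes must lie within [2, 8]")
        if self.layout not in ("single", "paired"):
            raise ValueError("layout must be 'single' or 'paired'")


@dataclass
class PlantedSite:
    gene_id: str
    contig: str
    position: int  # first transcribed base, 0-based
    strand: str


@dataclass
class SimTruth:
    """Ground truth: one row per simulated read and per gene."""

    reads: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class SimulatedReads:
    """SAM-ready records plus ground truth for one simulated library."""

    sam_records: list[dict]
    truth: SimTruth
    contig_lengths: dict[str, int]

    def write_sam(self, path: str) -> None:
        write_sam(self.sam_records, path, contigs=self.contig_lengths)

    def unmapped_reads(self) -> list[Read]:
        """The unmapped candidates, as samio.read_unmapped would yield them."""
        out = []
        for rec in self.sam_records:
            if not rec.get("unmapped", True):
                continue
            mate_index = rec["mate_index"] if rec.get("paired") else None
            out.append(
                Read(
                    id=rec["id"],
                    sequence=rec["sequence"],
                    qualities=rec.get("qualities"),
                    mate_index=mate_index,
                    is_unmapped=True,
                    mate_is_unmapped=(
                        bool(rec.get("mate_unmapped")) if rec.get("paired") else None
                    ),
                )
            )
        return out


@dataclass
class SimulatedDataset:
    genome: Genome
    genes: list[GeneModel]
    sites: list[PlantedSite]
    reads: SimulatedReads
    config: SimConfig


def random_genome(
    length: int, gc_content: float = 0.36, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Random iid genome as a numpy array of single-character strings."""
    rng = rng or np.random.default_rng(0)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return rng.choice(
        np.array(["A", "C", "G", "T"]), size=length, p=[at, gc, gc, at]
    )


def make_genome_and_genes(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Genome, list[GeneModel], list[PlantedSite]]:
    """Build the toy genome with planted acceptor sites and operon structure.

    Genes are laid out left to right with a fixed intergenic gap; operon
    members are adjacent and share a strand. Every gene receives one
    trans-splice site at its 5' end, with TTTCAG written immediately
    upstream on the transcribed strand.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    margin = max(100, cfg.read_length + 10)
    block = cfg.gene_length + cfg.intergenic_gap
    required = 2 * margin + cfg.n_genes * block
    if cfg.genome_length < required:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {cfg.n_genes} genes; "
            f"need at least {required}"
        )
    arr = random_genome(cfg.genome_length, cfg.gc_content, rng)

    # partition genes into operons and singletons
    n_operonic = int(round(cfg.operon_fraction * cfg.n_genes))
    groups: list[int] = []
    remaining = n_operonic
    lo, hi = cfg.operon_size_range
    while remaining >= lo:
        size = int(rng.integers(lo, min(hi, remaining) + 1))
        groups.append(size)
        remaining -= size
    group_sizes = groups + [1] * (cfg.n_genes - sum(groups))
    order = rng.permutation(len(group_sizes))
    group_sizes = [group_sizes[i] for i in order]

    genes: list[GeneModel] = []
    sites: list[PlantedSite] = []
    cursor = margin
    gene_no = 0
    operon_no = 0
    for size in group_sizes:
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = None
        if size >= 2:
            operon_no += 1
            operon_id = f"operon{operon_no:03d}"
        members = range(1, size + 1)
        if strand == "-":
            # position 1 is the promoter-proximal gene; on '-' the operon
            # runs right-to-left, so lay members out in reverse
            members = range(size, 0, -1)
        for pos_in_operon in members:
            gene_no += 1
            start, end = cursor, cursor + cfg.gene_length
            gene_id = f"gene{gene_no:04d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=cfg.contig_name,
                    start=start,
                    end=end,
                    strand=strand,
                    operon_id=operon_id,
                    operon_position=pos_in_operon if operon_id else None,
                )
            )
            if strand == "+":
                site = start
                arr[start - 6 : start] = list(ACCEPTOR_HEXAMER)
            else:
                site = end - 1
                arr[end : end + 6] = list(revcomp(ACCEPTOR_HEXAMER))
            sites.append(PlantedSite(gene_id, cfg.contig_name, site, strand))
            cursor += block
    genome = Genome({cfg.contig_name: "".join(arr)})
    return genome, genes, sites


def _inject_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    chars = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars), int(hits.size)


def simulate_reads(
    genome: Genome,
    genes: list[GeneModel],
    sites: list[PlantedSite],
    cfg: SimConfig,
    db: Optional[SLDatabase] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedReads:
    """Simulate the library and the first-pass mapper's verdict on it.

    SL reads are always emitted as unmapped records (an end-to-end mapper
    cannot place them); background reads are emitted as mapped records
    except for ``unmapped_background_fraction``, written as unmapped to
    exercise the false-positive path. In paired layout the SL fragment's
    left-most mate is read 2 (sense); its mate is unmapped too exactly when
    the pair dovetails into the SL fragment.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    db = db or SLDatabase.celegans()
    contig = cfg.contig_name
    seq = genome.contigs[contig]
    by_class = {
        c: [iso for iso in db if iso.sl_class == c] for c in ("SL1", "SL2")
    }
    site_of = {s.gene_id: s for s in sites}
    lengths = np.array(sorted(cfg.sl_suffix_length_distribution))
    weights = np.array(
        [cfg.sl_suffix_length_distribution[l] for l in lengths], dtype=float
    )
    weights /= weights.sum()

    records: list[dict] = []
    read_rows: list[dict] = []
    gene_tally = {g.gene_id: [0, 0] for g in genes}
    paired = cfg.layout == "paired"
    rl = cfg.read_length

    def gene_sense_sequence(site: PlantedSite, length: int) -> str:
        if site.strand == "+":
            return seq[site.position : site.position + length]
        return revcomp(seq[site.position - length + 1 : site.position + 1])

    for i in range(cfg.n_sl_reads):
        gene = genes[int(rng.integers(len(genes)))]
        site = site_of[gene.gene_id]
        downstream = (gene.operon_position or 0) >= 2
        p_sl2 = cfg.sl2_given_downstream if downstream else cfg.sl2_given_other
        sl_class = "SL2" if rng.random() < p_sl2 else "SL1"
        isoforms = by_class[sl_class]
        iso = isoforms[int(rng.integers(len(isoforms)))]
        suffix_len = int(min(lengths[rng.choice(len(lengths), p=weights)], len(iso.sequence)))
        gene_tally[gene.gene_id][0 if sl_class == "SL1" else 1] += 1
        read_id = f"sl_{i:06d}"

        if not paired:
            sense = iso.sequence[-suffix_len:] + gene_sense_sequence(
                site, rl - suffix_len
            )
            read_seq, n_err = _inject_errors(sense, cfg.sequencing_error_rate, rng)
            records.append({"id": read_id, "sequence": read_seq, "unmapped": True})
            read_rows.append(
                {
                    "read_id": read_id,
                    "is_sl": True,
                    "isoform_name": iso.name,
                    "sl_class": sl_class,
                    "sl_suffix_length": suffix_len,
                    "site_contig": contig,
                    "site_position": site.position,
                    "site_strand": site.strand,
                    "gene_id": gene.gene_id,
                    "n_errors": n_err,
                    "mate_unmapped": None,
                    "in_unmapped_input": True,
                }
            )
            continue

        # paired: fragment = SL suffix + genomic part, R2 = left-most/sense
        frag = int(
            np.clip(
                round(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd)),
                rl,
                suffix_len + cfg.gene_length,
            )
        )
        transcript = iso.sequence[-suffix_len:] + gene_sense_sequence(
            site, frag - suffix_len
        )
        r2_seq, n_err2 = _inject_errors(
            transcript[:rl], cfg.sequencing_error_rate, rng
        )
        r1_sense_start = frag - rl
        r1_seq, n_err1 = _inject_errors(
            revcomp(transcript[r1_sense_start:frag]), cfg.sequencing_error_rate, rng
        )
        r1_unmapped = r1_sense_start < suffix_len  # dovetails into the SL
        records.append(
            {
                "id": read_id,
                "sequence": r2_seq,
                "unmapped": True,
                "paired": True,
                "mate_index": 2,
                "mate_unmapped": r1_unmapped,
            }
        )
        if r1_unmapped:
            records.append(
                {
                    "id": read_id,
                    "sequence": r1_seq,
                    "unmapped": True,
                    "paired": True,
                    "mate_index": 1,
                    "mate_unmapped": True,
                }
            )
        else:
            # R1 is fully genomic; compute its forward-strand placement
            if site.strand == "+":
                pos = site.position + r1_sense_start - suffix_len
                reverse = True
            else:
                pos = site.position + suffix_len - frag + 1
                reverse = False
            records.append(
                {
                    # SAM stores reverse-strand alignments as the forward
                    # reference strand sequence
                    "id": read_id,
                    "sequence": revcomp(r1_seq) if reverse else r1_seq,
                    "unmapped": False,
                    "paired": True,
                    "mate_index": 1,
                    "mate_unmapped": True,
                    "contig": contig,
                    "pos": pos,
                    "reverse": reverse,
                }
            )
        read_rows.append(
            {
                "read_id": read_id,
                "is_sl": True,
                "isoform_name": iso.name,
                "sl_class": sl_class,
                "sl_suffix_length": suffix_len,
                "site_contig": contig,
                "site_position": site.position,
                "site_strand": site.strand,
                "gene_id": gene.gene_id,
                "n_errors": n_err2,
                "mate_unmapped": r1_unmapped,
                "in_unmapped_input": True,
            }
        )

    for i in range(cfg.n_background_reads):
        read_id = f"bg_{i:06d}"
        pos = int(rng.integers(0, len(seq) - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        segment = seq[pos : pos + rl]
        raw = segment if strand == "+" else revcomp(segment)
        read_seq, n_err = _inject_errors(raw, cfg.sequencing_error_rate, rng)
        unmapped = rng.random() < cfg.unmapped_background_fraction
        stored = read_seq if (unmapped or strand == "+") else revcomp(read_seq)
        rec: dict = {"id": read_id, "sequence": stored, "unmapped": unmapped}
        if paired:
            rec.update({"paired": True, "mate_index": 2, "mate_unmapped": False})
        if not unmapped:
            rec.update({"contig": contig, "pos": pos, "reverse": strand == "-"})
        records.append(rec)
        read_rows.append(
            {
                "read_id": read_id,
                "is_sl": False,
                "isoform_name": None,
                "sl_class": None,
                "sl_suffix_length": 0,
                "site_contig": None,
                "site_position": -1,
                "site_strand": None,
                "gene_id": None,
                "n_errors": n_err,
                "mate_unmapped": False if paired else None,
                "in_unmapped_input": unmapped,
            }
        )

    gene_rows = [
        {
            "gene_id": g.gene_id,
            "operon_id": g.operon_id,
            "operon_position": g.operon_position,
            "strand": g.strand,
            "start": g.start,
            "end": g.end,
            "true_sl1": gene_tally[g.gene_id][0],
            "true_sl2": gene_tally[g.gene_id][1],
        }
        for g in genes
    ]
    truth = SimTruth(
        reads=pd.DataFrame(read_rows), genes=pd.DataFrame(gene_rows)
    )
    return SimulatedReads(
        sam_records=records,
        truth=truth,
        contig_lengths=genome.lengths(),
    )


def simulate_dataset(
    cfg: SimConfig, db: Optional[SLDatabase] = None
) -> SimulatedDataset:
    """Genome + annotation + reads + truth from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    genome, genes, sites = make_genome_and_genes(cfg, rng)
    reads = simulate_reads(genome, genes, sites, cfg, db=db, rng=rng)
    return SimulatedDataset(genome, genes, sites, reads, cfg)


def sample_random_reads(
    genome: Genome,
    n: int,
    length: int = 50,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Read]:
    """Random genome segments of fixed length, drawn uniformly on both strands."""
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    contigs = [(name, s) for name, s in genome.contigs.items() if len(s) >= length]
    if not contigs:
        raise ValueError(f"no contig of length >= {length}")
    weights = np.array([len(s) - length + 1 for _, s in contigs], dtype=float)
    weights /= weights.sum()
    reads = []
    for i in range(n):
        ci = int(rng.choice(len(contigs), p=weights))
        name, s = contigs[ci]
        pos = int(rng.integers(0, len(s) - length + 1))
        segment = s[pos : pos + length]
        if rng.random() < 0.5:
            segment = revcomp(segment)
        reads.append(Read(id=f"rand_{i:06d}", sequence=segment))
    return reads


def write_fastq(reads: list[Read], path: str) -> None:
    with open(path, "w") as out:
        for r in reads:
            qual = (
                "".join(chr(q + 33) for q in r.qualities)
                if r.qualities is not None
                else "I" * len(r.sequence)
            )
            out.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """GFF3 export with operon attributes (1-based inclusive coordinates)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.operon_id:
                attrs.append(f"operon={g.operon_id}")
                attrs.append(f"operon_position={g.operon_position}")
            out.write(
                "\t".join(
                    [
                        g.contig,
                        "sltrans_sim",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
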