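"""Placing trimmed SL reads back on the genome.

The internal mapper is a deliberately simple unspliced end-to-end aligner:
an exact k-mer index over both strands, seeding on the read's first k-mer
and verifying the whole read with a small mismatch budget and no
soft-clipping. It is intended for toy/simulated genomes; for real genomes
with introns, trimmed reads are exported as FASTQ (one file per SL class)
for an external spliced mapper, and the resulting BAM is imported back.
Reads with two or more equally good placements are flagged as multimappers
and excluded from downstream quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pysam

from ._seq import revcomp
from .classify import TrimmedRead


@dataclass
class Genome:
    """Named contigs as uppercase nucleotide strings."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        contigs = {}
        with pysam.FastxFile(path) as fx:
            for rec in fx:
                contigs[rec.name] = rec.sequence.upper()
        return cls(contigs)

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as out:
            for name, seq in self.contigs.items():
                out.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    sl_class: str
    contig: str
    start: int  # 0-based leftmost mapped base
    strand: str  # '+' or '-'
    mapped_length: int
    mismatches: int
    unique: bool = True


class KmerIndex:
    """Exact k-mer lookup over the forward strand of every contig.

    Reverse-strand placements are found by querying with the
    reverse-complemented read, so only forward k-mers are stored.
    """

    def __init__(self, genome: Genome, k: int = 15):
        if not genome.contigs:
            raise ValueError("degenerate genome")
        shortest = min(len(s) for s in genome.contigs.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest contig ({shortest} nt)")
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _count_mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def map_read(
    tr: TrimmedRead, index: KmerIndex, max_mismatches: int = 2
) -> Optional[MappedRead]:
    """End-to-end placement of a trimmed read via its first k-mer.

    Returns the unique best placement (fewest mismatches, at most
    ``max_mismatches``), a ``unique=False`` record when several placements
    tie for best, or None when no admissible placement exists.
    """
    k = index.k
    seq = tr.sequence
    if len(seq) < k:
        return None
    placements: list[tuple[int, str, int, str]] = []  # (mm, contig, pos, strand)
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for contig, pos in index.lookup(oriented[:k]):
            ref = index.genome.contigs[contig]
            if pos + len(oriented) > len(ref):
                continue
            mm = _count_mismatches(oriented, ref[pos : pos + len(oriented)], max_mismatches)
            if mm <= max_mismatches:
                placements.append((mm, contig, pos, strand))
    if not placements:
        return None
    placements.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
    best_mm = placements[0][0]
    ties = [p for p in placements if p[0] == best_mm]
    mm, contig, pos, strand = ties[0]
    return MappedRead(
        read_id=tr.read_id,
        sl_class=tr.sl_class,
        contig=contig,
        start=pos,
        strand=strand,
        mapped_length=len(seq),
        mismatches=mm,
        unique=len(ties) == 1,
    )


def export_fastq(trimmed: Iterable[TrimmedRead], prefix: str) -> dict[str, str]:
    """Write trimmed reads to per-class FASTQ files (``<prefix>_SL1.fq`` ...).

    Files are created (possibly empty) for both classes so the export is
    predictable for downstream mappers. Returns class -> path.
    """
    paths = {c: f"{prefix}_{c}.fq" for c in ("SL1", "SL2")}
    handles = {c: open(p, "w") for c, p in paths.items()}
    try:
        for tr in trimmed:
            qual = (
                "".join(chr(q + 33) for q in tr.qualities)
                if tr.qualities is not None
                else "I" * len(tr.sequence)
            )
            handles[tr.sl_class].write(
                f"@{tr.read_id}\n{tr.sequence}\n+\n{qual}\n"
            )
    finally:
        for h in handles.values():
            h.close()
    return paths


def import_bam(path: str, class_map: dict[str, str]) -> Iterator[MappedRead]:
    """Reconstruct MappedRead records from an externally remapped BAM.

    ``class_map`` maps read_id -> SL class (e.g. built from the per-class
    FASTQ files of :func:`export_fastq`). Soft-clipped records violate the
    end-to-end contract and are rejected with a warning; reads missing from
    ``class_map`` raise an error listing the offenders.
    """
    missing: list[str] = []
    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for seg in bam:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.cigartuples and any(op in (4, 5) for op, _ in seg.cigartuples):
                warnings.warn(
                    f"read {seg.query_name}: soft/hard-clipped record rejected "
                    "(end-to-end remapping expected)"
                )
                continue
            sl_class = class_map.get(seg.query_name)
            if sl_class is None:
                missing.append(seg.query_name)
                continue
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            yield MappedRead(
                read_id=seg.query_name,
                sl_class=sl_class,
                contig=seg.reference_name,
                start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                mapped_length=seg.query_length,
                mismatches=int(nm),
                unique=seg.mapping_quality > 0,
            )
    if missing:
        raise KeyError(
            f"{len(missing)} remapped reads absent from class map: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
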