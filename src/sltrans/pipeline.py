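"""End-to-end orchestration: unmapped reads -> SL calls -> sites and genes.

The steps mirror the standard SL detection workflow: select candidate
unmapped reads, orient them to transcript sense, align against the SL
isoform set (e-value or anchored route), accept and trim the
properly-configured hits, remap the trimmed remainders, then aggregate into
trans-splice sites (with acceptor statistics) and per-gene SL1/SL2 counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .align import AlignScoring, SLDatabase
from .classify import (
    DEFAULT_MIN_REMAINING,
    ClassificationResult,
    identify_sl_reads,
)
from .quantify import (
    GeneModel,
    GeneSLCounts,
    TransSpliceSite,
    ag_fraction,
    call_sites,
    count_by_gene,
)
from .remap import Genome, KmerIndex, MappedRead, map_read
from .samio import (
    LibraryConfig,
    Read,
    orient_to_sense,
    read_unmapped,
    select_input_reads,
)


@dataclass
class PipelineResult:
    classification: ClassificationResult
    mapped: list[MappedRead]
    multimapped: int
    unmapped_after_trim: int
    sites: list[TransSpliceSite]
    gene_counts: Optional[list[GeneSLCounts]]
    unassigned_reads: Optional[int]

    @property
    def ag_site_fraction(self) -> Optional[float]:
        try:
            return ag_fraction(self.sites)
        except ValueError:
            return None


def run_pipeline(
    reads: Union[str, Iterable[Read]],
    genome: Genome,
    db: Optional[SLDatabase] = None,
    genes: Optional[Sequence[GeneModel]] = None,
    mode: str = "default",
    lib: Optional[LibraryConfig] = None,
    paired_mode: bool = False,
    scoring: Optional[AlignScoring] = None,
    min_overlap: int = 5,
    max_error_rate: float = 0.10,
    min_remaining_length: int = DEFAULT_MIN_REMAINING,
    mapper_k: int = 15,
    mapper_max_mismatches: int = 2,
    stranded_counting: bool = True,
    total_reads: Optional[int] = None,
) -> PipelineResult:
    """Run the full quantification on a BAM/SAM path or a stream of reads.

    ``genes`` is optional; without it only site-level results are produced.
    The internal unspliced mapper is used for remapping (toy genomes); for
    real genomes export the trimmed reads instead (remap.export_fastq).
    """
    lib = lib or LibraryConfig()
    db = db or SLDatabase.celegans()
    scoring = scoring or AlignScoring()
    if isinstance(reads, str):
        reads = read_unmapped(reads)
    selected = select_input_reads(reads, lib, paired_mode=paired_mode)
    oriented = (orient_to_sense(r, lib) for r in selected)
    classification = identify_sl_reads(
        oriented,
        db,
        mode=mode,
        scoring=scoring,
        min_overlap=min_overlap,
        max_error_rate=max_error_rate,
        min_remaining_length=min_remaining_length,
        total_reads=total_reads,
    )
    index = KmerIndex(genome, k=mapper_k)
    mapped: list[MappedRead] = []
    multimapped = 0
    unmapped_after_trim = 0
    for tr in classification.trimmed:
        mr = map_read(tr, index, max_mismatches=mapper_max_mismatches)
        if mr is None:
            unmapped_after_trim += 1
        elif not mr.unique:
            multimapped += 1
        else:
            mapped.append(mr)
    sites = call_sites(mapped, genome)
    gene_counts = unassigned = None
    if genes is not None:
        gene_counts, unassigned = count_by_gene(
            mapped, genes, stranded=stranded_counting
        )
    return PipelineResult(
        classification=classification,
        mapped=mapped,
        multimapped=multimapped,
        unmapped_after_trim=unmapped_after_trim,
        sites=sites,
        gene_counts=gene_counts,
        unassigned_reads=unassigned,
    )
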