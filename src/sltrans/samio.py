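"""Input handling for unmapped-read streams.

Trans-spliced reads carry a spliced-leader (SL) fragment at the transcript 5'
end and therefore fail end-to-end mapping in the first-pass alignment. This
module reads SAM/BAM (or FASTQ) produced by that first pass, keeps only the
unmapped records, and applies the library-layout prefilters: for paired-end
data only the mate carrying the fragment's transcript-5' end (the "left-most"
mate) can contain the SL, and in the stricter paired mode the other mate is
additionally required to have mapped.

Internal coordinates are 0-based half-open throughout the package; conversion
to/from SAM's 1-based convention happens only at file boundaries (via pysam).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from ._seq import revcomp


class Strandedness(enum.Enum):
    UNSTRANDED = "unstranded"
    SENSE_ON_MATE1 = "sense_on_mate1"
    SENSE_ON_MATE2 = "sense_on_mate2"


class Layout(enum.Enum):
    SINGLE = "single"
    PAIRED = "paired"


@dataclass(frozen=True)
class Read:
    """A sequencing read, possibly one mate of a pair.

    ``orientation`` records whether ``sequence`` is still as the sequencer
    emitted it ("as_sequenced") or has been re-oriented to transcript sense
    ("sense"). ``search_both_strands`` is set by :func:`orient_to_sense` for
    unstranded libraries, where the sense strand is unknown and the SL search
    must consider both strands.
    """

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    mate_index: Optional[int] = None  # 1 or 2, None for single-end
    is_unmapped: bool = True
    mate_is_unmapped: Optional[bool] = None
    orientation: str = "as_sequenced"
    search_both_strands: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")
        if (self.mate_index is None) != (self.mate_is_unmapped is None):
            raise ValueError(
                f"read {self.id}: mate flags must be present iff mate_index is set"
            )
        if self.mate_index not in (None, 1, 2):
            raise ValueError(f"read {self.id}: mate_index must be 1 or 2")


@dataclass(frozen=True)
class LibraryConfig:
    """Sequencing-library geometry.

    ``leftmost_mate`` names the mate that carries the fragment's
    transcript-5' end; it is the only mate that can start with an SL
    fragment. The default (mate 2) matches dUTP-style stranded protocols
    where read 2 is the sense, left-most read. Only meaningful for paired
    layouts.
    """

    layout: Layout = Layout.SINGLE
    strandedness: Strandedness = Strandedness.SENSE_ON_MATE1
    leftmost_mate: int = 2

    def __post_init__(self) -> None:
        if self.leftmost_mate not in (1, 2):
            raise ValueError("leftmost_mate must be 1 or 2")


class FormatError(RuntimeError):
    """Raised when an input file cannot be parsed as SAM/BAM/FASTQ."""


class ConfigurationError(RuntimeError):
    """Raised for inconsistent run configuration."""


def _read_from_segment(seg: pysam.AlignedSegment) -> Read:
    mate_index: Optional[int] = None
    mate_unmapped: Optional[bool] = None
    if seg.is_paired:
        mate_index = 1 if seg.is_read1 else 2
        mate_unmapped = seg.mate_is_unmapped
    quals = list(seg.query_qualities) if seg.query_qualities is not None else None
    return Read(
        id=seg.query_name,
        sequence=(seg.query_sequence or "").upper(),
        qualities=quals,
        mate_index=mate_index,
        is_unmapped=True,
        mate_is_unmapped=mate_unmapped,
    )


def read_unmapped(path: str) -> Iterator[Read]:
    """Yield the unmapped reads from a SAM/BAM file.

    Mapped, secondary and supplementary records are skipped; mate flags are
    preserved. A file with no unmapped records yields an empty stream.
    """
    try:
        handle = pysam.AlignmentFile(path, check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path} as SAM/BAM: {exc}") from exc
    with handle:
        try:
            for seg in handle:
                if seg.is_secondary or seg.is_supplementary:
                    continue
                if not seg.is_unmapped:
                    continue
                if not seg.query_sequence:
                    continue
                yield _read_from_segment(seg)
        except (ValueError, OSError) as exc:
            raise FormatError(f"malformed record in {path}: {exc}") from exc


def read_fastq(path: str) -> Iterator[Read]:
    """Read single-end candidates from FASTQ (alternative unmapped source)."""
    try:
        with pysam.FastxFile(path) as fx:
            for rec in fx:
                quals = (
                    rec.get_quality_array() if rec.quality is not None else None
                )
                yield Read(
                    id=rec.name,
                    sequence=rec.sequence.upper(),
                    qualities=list(quals) if quals is not None else None,
                )
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path} as FASTQ: {exc}") from exc


def select_input_reads(
    reads: Iterable[Read], cfg: LibraryConfig, paired_mode: bool = False
) -> Iterator[Read]:
    """Apply the layout prefilters to an unmapped-read stream.

    Single layout passes everything. Paired layout keeps only reads from the
    left-most mate of the fragment; with ``paired_mode`` the mate must also
    have mapped (fragments whose both mates failed to map are discarded —
    stricter, but loses dovetailing pairs where the SL makes both mates
    unmappable).
    """
    if paired_mode and cfg.layout is Layout.SINGLE:
        raise ConfigurationError("paired mode requires a paired library layout")
    for read in reads:
        if cfg.layout is Layout.SINGLE:
            yield read
            continue
        if read.mate_index != cfg.leftmost_mate:
            continue
        if paired_mode and read.mate_is_unmapped is not False:
            continue
        yield read


def orient_to_sense(read: Read, cfg: LibraryConfig) -> Read:
    """Re-orient a read to transcript sense according to library strandedness.

    For stranded libraries the selected mate is either already sense or its
    reverse complement is; unstranded libraries are returned unchanged with
    ``search_both_strands`` set so the SL search covers both strands.
    """
    if read.orientation != "as_sequenced":
        raise ValueError(f"read {read.id}: already oriented")
    if cfg.strandedness is Strandedness.UNSTRANDED:
        return replace(read, orientation="sense", search_both_strands=True)
    mate = read.mate_index or 1
    sense_mate = 1 if cfg.strandedness is Strandedness.SENSE_ON_MATE1 else 2
    if mate == sense_mate:
        return replace(read, orientation="sense")
    quals = list(read.qualities)[::-1] if read.qualities is not None else None
    return replace(
        read, sequence=revcomp(read.sequence), qualities=quals, orientation="sense"
    )


def write_sam(
    records: Iterable[dict],
    path: str,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write SAM records given as dicts (used by the simulator and tests).

    Each record dict carries: id, sequence, qualities (or None), flag fields
    (paired, mate_index, unmapped, mate_unmapped) and, for mapped records,
    contig / pos (0-based) / reverse.
    """
    header: dict = {"HD": {"VN": "1.6", "SO": "unsorted"}}
    if contigs:
        header["SQ"] = [{"SN": name, "LN": length} for name, length in contigs.items()]
    else:
        # pysam cannot iterate a SAM without any @SQ line, even one holding
        # only unmapped records; a placeholder keeps the file readable
        header["SQ"] = [{"SN": "unplaced", "LN": 1}]
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec["id"]
            seq = rec["sequence"]
            seg.query_sequence = seq
            quals = rec.get("qualities")
            seg.query_qualities = quals if quals is not None else [30] * len(seq)
            flag = 0
            if rec.get("paired"):
                flag |= 0x1
                flag |= 0x40 if rec["mate_index"] == 1 else 0x80
                if rec.get("mate_unmapped"):
                    flag |= 0x8
            if rec.get("unmapped", True):
                flag |= 0x4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            else:
                seg.reference_id = out.header.get_tid(rec["contig"])
                seg.reference_start = rec["pos"]
                seg.mapping_quality = 60
                seg.cigarstring = f"{len(seq)}M"
                if rec.get("reverse"):
                    flag |= 0x10
            seg.flag = flag
            out.write(seg)
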