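"""Turning SL alignments into accepted, trimmed SL-containing reads.

A genuine trans-splicing junction leaves a precise signature: the alignment
must start at the read's 5' end and finish at the SL sequence's 3' end (the
"properly configured" rule). In the e-value (default) route, acceptance
additionally requires significance (E below threshold); the anchored routes
are properly configured by construction. Accepted reads are trimmed of the
aligned SL fragment so they can be remapped; reads left shorter than
``min_remaining_length`` (default 15 nt) are rejected as unmappable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._seq import revcomp
from .align import AlignScoring, SLAlignment, SLDatabase, best_call
from .samio import Read

DEFAULT_MIN_REMAINING = 15


class RejectionReason(enum.Enum):
    NO_ALIGNMENT = "no_alignment"
    NOT_SIGNIFICANT = "not_significant"
    MISCONFIGURED = "misconfigured"
    TOO_SHORT_AFTER_TRIM = "too_short_after_trim"


@dataclass(frozen=True)
class SLCall:
    """An accepted SL-containing read: class assignment plus trim length.

    ``trim_length`` is the q_end of the underlying alignment — the number of
    bases removed from the (re-oriented) read 5' end.
    """

    read_id: str
    isoform_name: str
    sl_class: str
    aligned_length: int
    significant: bool
    properly_configured: bool
    trim_length: int
    mode: str
    evalue: Optional[float] = None
    on_reverse_complement: bool = False


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sequence: str
    qualities: Optional[Sequence[int]]
    sl_class: str
    source_mode: str


def is_properly_configured(
    aln: SLAlignment, isoform_length: int, rc_configurable: bool = False
) -> bool:
    """True iff the alignment is anchored at the read 5' end and SL 3' end.

    Reverse-complement hits are reported in re-oriented read coordinates, so
    the same geometric test applies — but on a read whose sense orientation
    is known (stranded library, default route), a reverse-complement hit
    sits at the read's 3' end and cannot be a trans-splicing junction;
    ``rc_configurable`` is set only when the sense strand is unknown
    (unstranded libraries) or the route treats both strands as candidate
    junctions by construction (the anchored sensitive/tourasse routes).
    """
    if aln.on_reverse_complement and not rc_configurable:
        return False
    return aln.q_start == 0 and aln.s_end == isoform_length


def accept(
    aln: Optional[SLAlignment],
    db: SLDatabase,
    mode: str,
    read_length: int,
    evalue_threshold: float = 0.05,
    min_remaining_length: int = DEFAULT_MIN_REMAINING,
    rc_configurable: bool = False,
) -> tuple[Optional[SLCall], Optional[RejectionReason]]:
    """Decide whether an alignment constitutes an SL-containing read.

    Returns (call, None) on acceptance and (None, reason) otherwise.
    Default mode requires significance and proper configuration; the
    anchored modes (sensitive/tourasse) only require that a match was found.
    All modes reject reads whose remainder after trimming would be shorter
    than ``min_remaining_length``.
    """
    if aln is None:
        return None, RejectionReason.NO_ALIGNMENT
    isoform = db[aln.isoform_name]
    if mode != "default":
        rc_configurable = True  # anchored matches are junction-shaped on either strand
    proper = is_properly_configured(aln, len(isoform.sequence), rc_configurable)
    significant = aln.evalue is not None and aln.evalue < evalue_threshold
    if mode == "default":
        if not significant:
            return None, RejectionReason.NOT_SIGNIFICANT
        if not proper:
            return None, RejectionReason.MISCONFIGURED
    elif not proper:  # cannot occur for anchored_match output; defensive
        return None, RejectionReason.MISCONFIGURED
    trim_length = aln.q_end
    if read_length - trim_length < min_remaining_length:
        return None, RejectionReason.TOO_SHORT_AFTER_TRIM
    return (
        SLCall(
            read_id=aln.read_id,
            isoform_name=aln.isoform_name,
            sl_class=isoform.sl_class,
            aligned_length=aln.aligned_length,
            significant=significant,
            properly_configured=proper,
            trim_length=trim_length,
            mode=mode,
            evalue=aln.evalue,
            on_reverse_complement=aln.on_reverse_complement,
        ),
        None,
    )


def trim(read: Read, call: SLCall) -> TrimmedRead:
    """Remove the aligned SL fragment from the read's 5' end.

    Reverse-complement calls refer to the re-oriented read, so the read is
    reverse-complemented first; the trimmed remainder is therefore always in
    the orientation that aligned to the forward SL sequence (transcript
    sense), which is what remapping and site calling expect.
    """
    if call.trim_length < 1:
        raise ValueError(f"read {read.id}: nothing to trim")
    if call.trim_length >= len(read.sequence):
        raise ValueError(f"read {read.id}: trim length covers whole read")
    seq = read.sequence
    quals = list(read.qualities) if read.qualities is not None else None
    if call.on_reverse_complement:
        seq = revcomp(seq)
        quals = quals[::-1] if quals is not None else None
    return TrimmedRead(
        read_id=read.id,
        sequence=seq[call.trim_length :],
        qualities=quals[call.trim_length :] if quals is not None else None,
        sl_class=call.sl_class,
        source_mode=call.mode,
    )


@dataclass
class ClassificationResult:
    """Per-read calls plus the Table-1-style tallies for one run."""

    mode: str
    accepted: list[tuple[Read, SLCall]]
    trimmed: list[TrimmedRead]
    total_reads: int
    input_reads: int
    significant_total: int = 0
    significant_proper: int = 0
    nonsignificant_total: int = 0
    nonsignificant_proper: int = 0
    accepted_by_class: Optional[dict[str, int]] = None
    rejections: Optional[dict[RejectionReason, int]] = None

    def report(self) -> pd.DataFrame:
        """One-row summary with the categories of the identification table."""
        row = {
            "mode": self.mode,
            "total_reads": self.total_reads,
            "input_reads": self.input_reads,
            "significant_alignments": self.significant_total,
            "significant_properly_configured": self.significant_proper,
            "nonsignificant_alignments": self.nonsignificant_total,
            "nonsignificant_properly_configured": self.nonsignificant_proper,
            "accepted_SL1": (self.accepted_by_class or {}).get("SL1", 0),
            "accepted_SL2": (self.accepted_by_class or {}).get("SL2", 0),
        }
        for reason in RejectionReason:
            row[f"rejected_{reason.value}"] = (self.rejections or {}).get(reason, 0)
        return pd.DataFrame([row])

    def call_table(self) -> pd.DataFrame:
        """Per-read call table (read_id, isoform, class, trim length, flags)."""
        rows = [
            {
                "read_id": c.read_id,
                "isoform": c.isoform_name,
                "sl_class": c.sl_class,
                "aligned_length": c.aligned_length,
                "trim_length": c.trim_length,
                "evalue": c.evalue,
                "significant": c.significant,
                "properly_configured": c.properly_configured,
                "on_reverse_complement": c.on_reverse_complement,
            }
            for _, c in self.accepted
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "read_id",
                "isoform",
                "sl_class",
                "aligned_length",
                "trim_length",
                "evalue",
                "significant",
                "properly_configured",
                "on_reverse_complement",
            ],
        )


def identify_sl_reads(
    reads: Iterable[Read],
    db: SLDatabase,
    mode: str = "default",
    scoring: Optional[AlignScoring] = None,
    min_overlap: int = 5,
    max_error_rate: float = 0.10,
    min_remaining_length: int = DEFAULT_MIN_REMAINING,
    total_reads: Optional[int] = None,
) -> ClassificationResult:
    """Run alignment + acceptance over a stream of oriented candidate reads.

    The significant/nonsignificant x properly/improperly-configured tallies
    count one alignment per read (the best isoform), so the four categories
    partition the reads that aligned at all.
    """
    scoring = scoring or AlignScoring()
    accepted: list[tuple[Read, SLCall]] = []
    trimmed: list[TrimmedRead] = []
    by_class = {"SL1": 0, "SL2": 0}
    rejections = {reason: 0 for reason in RejectionReason}
    sig_total = sig_proper = nonsig_total = nonsig_proper = 0
    n_input = 0
    for read in reads:
        n_input += 1
        aln = best_call(
            read,
            db,
            mode=mode,
            scoring=scoring,
            min_overlap=min_overlap,
            max_error_rate=max_error_rate,
        )
        rc_configurable = read.search_both_strands or mode != "default"
        if aln is not None:
            proper = is_properly_configured(
                aln, len(db[aln.isoform_name].sequence), rc_configurable
            )
            significant = (
                aln.evalue is not None and aln.evalue < scoring.evalue_threshold
            )
            if significant:
                sig_total += 1
                sig_proper += proper
            else:
                nonsig_total += 1
                nonsig_proper += proper
        call, reason = accept(
            aln,
            db,
            mode,
            read_length=len(read.sequence),
            evalue_threshold=scoring.evalue_threshold,
            min_remaining_length=min_remaining_length,
            rc_configurable=rc_configurable,
        )
        if call is None:
            rejections[reason] += 1
            continue
        accepted.append((read, call))
        by_class[call.sl_class] += 1
        trimmed.append(trim(read, call))
    return ClassificationResult(
        mode=mode,
        accepted=accepted,
        trimmed=trimmed,
        total_reads=total_reads if total_reads is not None else n_input,
        input_reads=n_input,
        significant_total=sig_total,
        significant_proper=sig_proper,
        nonsignificant_total=nonsig_total,
        nonsignificant_proper=nonsig_proper,
        accepted_by_class=by_class,
        rejections=rejections,
    )
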