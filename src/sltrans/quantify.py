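"""Trans-splice-site and gene-level quantification of SL trans-splicing.

A uniquely remapped trimmed read starts exactly at the trans-splice site:
its first transcribed base is the first base of the trans-spliced exon. The
acceptor dinucleotide (near-invariant AG, the tail of the UUUCAG consensus)
lies immediately upstream of that base on the transcribed strand; the
fraction of called sites bearing AG is the standard specificity proxy for
SL detection, since the true genome-wide set of sites is unknown.

Gene-level counts feed the operon predictor: genes at position two and
beyond in operons are resolved by SL2 trans-splicing, so the per-gene ratio
SL2/(SL1+SL2) predicts downstream-operon position; the predictor is
evaluated with an ROC sweep over ratio thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._seq import revcomp
from .remap import Genome, MappedRead

BASES = ("A", "C", "G", "T")


@dataclass
class TransSpliceSite:
    """A strand-aware trans-splice site with per-class read counts.

    ``position`` is the 0-based coordinate of the first trans-spliced
    (first transcribed) base. ``acceptor`` is the dinucleotide immediately
    upstream on the transcribed strand (reverse-complemented for '-' sites);
    None when the site sits within 2 nt of the contig edge.
    """

    contig: str
    position: int
    strand: str
    count_sl1: int = 0
    count_sl2: int = 0
    acceptor: Optional[str] = None

    @property
    def total(self) -> int:
        return self.count_sl1 + self.count_sl2


@dataclass
class ConsensusMatrix:
    """Per-position base frequencies and information content around sites.

    Positions run from -upstream to +downstream-1, with 0 the first
    transcribed base. ``information`` is 2 + sum_b f_b log2 f_b (bits).
    """

    frequencies: pd.DataFrame  # index: bases, columns: positions
    information: pd.Series
    n_sites: int
    n_dropped: int = 0


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    operon_id: Optional[str] = None
    operon_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.operon_position is not None and self.operon_position >= 2:
            if self.operon_id is None:
                raise ValueError(
                    f"gene {self.gene_id}: downstream operon position without operon_id"
                )


@dataclass
class GeneSLCounts:
    gene_id: str
    sl1: int
    sl2: int
    downstream_label: bool

    @property
    def ratio(self) -> Optional[float]:
        """SL2/(SL1+SL2), undefined (None) when no event was detected."""
        total = self.sl1 + self.sl2
        return self.sl2 / total if total > 0 else None


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    tpr_at_fdr: dict[float, float]


def call_sites(
    mapped: Iterable[MappedRead], genome: Genome
) -> list[TransSpliceSite]:
    """Collapse uniquely mapped SL reads into single-nucleotide sites.

    '+' reads give the site at their leftmost base; '-' reads at their
    rightmost base (the first transcribed base on the minus strand). Reads
    sharing (contig, site, strand) merge into one site with per-class
    counts. Multimappers are ignored.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    for mr in mapped:
        if not mr.unique:
            continue
        if mr.strand == "+":
            pos = mr.start
        else:
            pos = mr.start + mr.mapped_length - 1
        key = (mr.contig, pos, mr.strand)
        slot = counts.setdefault(key, [0, 0])
        slot[0 if mr.sl_class == "SL1" else 1] += 1
    sites = []
    for (contig, pos, strand), (n1, n2) in sorted(counts.items()):
        seq = genome.contigs[contig]
        if strand == "+":
            acceptor = seq[pos - 2 : pos] if pos >= 2 else None
        else:
            acceptor = (
                revcomp(seq[pos + 1 : pos + 3]) if pos + 3 <= len(seq) else None
            )
        sites.append(
            TransSpliceSite(
                contig=contig,
                position=pos,
                strand=strand,
                count_sl1=n1,
                count_sl2=n2,
                acceptor=acceptor,
            )
        )
    return sites


def ag_fraction(sites: Sequence[TransSpliceSite]) -> float:
    """Fraction of sites (each counted once) whose acceptor is AG.

    Sites with an undefined acceptor (contig edge) are excluded; having no
    site with a defined acceptor is an error.
    """
    defined = [s for s in sites if s.acceptor is not None]
    if not defined:
        raise ValueError("no site with a defined acceptor dinucleotide")
    return sum(1 for s in defined if s.acceptor == "AG") / len(defined)


def consensus(
    sites: Sequence[TransSpliceSite],
    genome: Genome,
    sl_class: Optional[str] = None,
    window: tuple[int, int] = (8, 4),
) -> ConsensusMatrix:
    """Tabulate the strand-aware sequence environment around sites.

    ``window = (U, V)`` spans positions -U..+V-1 relative to the first
    transcribed base. Each site contributes once (unweighted by read count);
    windows overrunning a contig edge are dropped and counted.
    """
    upstream, downstream = window
    if sl_class is not None:
        if sl_class == "SL1":
            sites = [s for s in sites if s.count_sl1 > s.count_sl2]
        else:
            sites = [s for s in sites if s.count_sl2 >= s.count_sl1 and s.count_sl2 > 0]
    if not sites:
        raise ValueError("no sites to tabulate")
    positions = list(range(-upstream, downstream))
    tab = np.zeros((4, len(positions)), dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    n_used = n_dropped = 0
    for s in sites:
        seq = genome.contigs[s.contig]
        if s.strand == "+":
            lo, hi = s.position - upstream, s.position + downstream
            if lo < 0 or hi > len(seq):
                n_dropped += 1
                continue
            window_seq = seq[lo:hi]
        else:
            lo, hi = s.position - downstream + 1, s.position + upstream + 1
            if lo < 0 or hi > len(seq):
                n_dropped += 1
                continue
            window_seq = revcomp(seq[lo:hi])
        n_used += 1
        for col, base in enumerate(window_seq):
            if base in base_idx:
                tab[base_idx[base], col] += 1
    if n_used == 0:
        raise ValueError("all windows overran contig edges")
    col_totals = tab.sum(axis=0)
    col_totals[col_totals == 0] = 1.0
    freqs = tab / col_totals
    info = np.array(
        [
            2.0 + sum(f * math.log2(f) for f in freqs[:, j] if f > 0)
            for j in range(freqs.shape[1])
        ]
    )
    freq_df = pd.DataFrame(freqs, index=list(BASES), columns=positions)
    return ConsensusMatrix(
        frequencies=freq_df,
        information=pd.Series(info, index=positions),
        n_sites=n_used,
        n_dropped=n_dropped,
    )


def count_by_gene(
    mapped: Iterable[MappedRead],
    genes: Sequence[GeneModel],
    stranded: bool = True,
) -> tuple[list[GeneSLCounts], int]:
    """Per-gene SL1/SL2 counts by whole-gene interval overlap.

    A read is assigned to a gene when its mapped interval overlaps the gene
    span on the matching strand (ignoring strand when ``stranded`` is
    False); reads overlapping two or more genes are left unassigned.
    Returns (counts for every gene, number of unassigned unique reads).
    """
    trees: dict[str, IntervalTree] = {}
    for idx, g in enumerate(genes):
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, idx)
    tallies = {g.gene_id: [0, 0] for g in genes}
    unassigned = 0
    for mr in mapped:
        if not mr.unique:
            continue
        tree = trees.get(mr.contig)
        hits = []
        if tree is not None:
            for iv in tree.overlap(mr.start, mr.start + mr.mapped_length):
                g = genes[iv.data]
                if stranded and g.strand != mr.strand:
                    continue
                hits.append(g)
        if len(hits) != 1:
            unassigned += 1
            continue
        slot = tallies[hits[0].gene_id]
        slot[0 if mr.sl_class == "SL1" else 1] += 1
    result = [
        GeneSLCounts(
            gene_id=g.gene_id,
            sl1=tallies[g.gene_id][0],
            sl2=tallies[g.gene_id][1],
            downstream_label=(g.operon_position or 0) >= 2,
        )
        for g in genes
    ]
    return result, unassigned


def roc(
    counts: Sequence[GeneSLCounts],
    min_events: int = 1,
    fdr_bounds: Sequence[float] = (0.05,),
) -> ROCResult:
    """ROC of the SL2 ratio as a predictor of downstream operon position.

    Genes with fewer than ``min_events`` detected events are excluded (their
    ratio is undefined). ``tpr_at_fdr`` reports, for each bound, the highest
    TPR achievable at a false discovery rate FP/(FP+TP) within the bound.
    """
    kept = [c for c in counts if c.sl1 + c.sl2 >= min_events]
    labels = np.array([c.downstream_label for c in kept], dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes required for ROC")
    scores = np.array([c.ratio for c in kept], dtype=float)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc_value = float(_sk_auc(fpr, tpr))
    n_pos = int(labels.sum())
    tpr_at_fdr: dict[float, float] = {}
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # evaluate only at distinct-threshold boundaries (last index of each score)
    boundary = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    for bound in fdr_bounds:
        best_tpr = 0.0
        for i in np.flatnonzero(boundary):
            denom = tp[i] + fp[i]
            fdr = fp[i] / denom if denom else 0.0
            if fdr <= bound:
                best_tpr = max(best_tpr, tp[i] / n_pos)
        tpr_at_fdr[bound] = best_tpr
    return ROCResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc_value, tpr_at_fdr=tpr_at_fdr
    )


# ---------------------------------------------------------------------------
# annotation I/O and table export


def read_gff3_genes(
    path: str,
    operon_id_key: str = "operon",
    operon_pos_key: str = "operon_position",
    feature_type: str = "gene",
) -> list[GeneModel]:
    """Load gene models (with optional operon attributes) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        operon_id = feat.attributes.get(operon_id_key, [None])[0]
        pos_raw = feat.attributes.get(operon_pos_key, [None])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                operon_id=operon_id,
                operon_position=int(pos_raw) if pos_raw is not None else None,
            )
        )
    return genes


def sites_to_frame(sites: Sequence[TransSpliceSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": s.contig,
                "position": s.position,
                "strand": s.strand,
                "count_sl1": s.count_sl1,
                "count_sl2": s.count_sl2,
                "acceptor": s.acceptor,
            }
            for s in sites
        ],
        columns=["contig", "position", "strand", "count_sl1", "count_sl2", "acceptor"],
    )


def write_sites_bed(sites: Sequence[TransSpliceSite], path: str) -> None:
    """BED6 (+ per-class counts) export; BED is 0-based half-open already."""
    with open(path, "w") as out:
        for s in sites:
            name = f"site_{s.contig}_{s.position}_{s.strand}"
            out.write(
                "\t".join(
                    [
                        s.contig,
                        str(s.position),
                        str(s.position + 1),
                        name,
                        str(s.total),
                        s.strand,
                        str(s.count_sl1),
                        str(s.count_sl2),
                    ]
                )
                + "\n"
            )


def gene_counts_to_frame(counts: Sequence[GeneSLCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "sl1": c.sl1,
                "sl2": c.sl2,
                "ratio": c.ratio,
                "downstream_in_operon": c.downstream_label,
            }
            for c in counts
        ],
        columns=["gene_id", "sl1", "sl2", "ratio", "downstream_in_operon"],
    )
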