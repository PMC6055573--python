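"""Site calling, acceptor consensus, gene counting and the ROC predictor."""

import math

import numpy as np
import pytest

from sltrans import (
    GeneModel,
    Genome,
    ag_fraction,
    call_sites,
    consensus,
    count_by_gene,
    read_gff3_genes,
    roc,
)
from sltrans._seq import revcomp
from sltrans.quantify import GeneSLCounts
from sltrans.remap import MappedRead
from sltrans.simulate import write_gff3


def _mr(contig="c", start=0, strand="+", length=30, sl_class="SL1",
        read_id="r", unique=True):
    return MappedRead(read_id=read_id, sl_class=sl_class, contig=contig,
                      start=start, strand=strand, mapped_length=length,
                      mismatches=0, unique=unique)


@pytest.fixture()
def acceptor_genome():
    # position 500 is immediately preceded by ...TTTCAG on the plus strand
    seq = list("ACGT" * 300)
    seq[494:500] = list("TTTCAG")
    return Genome({"c": "".join(seq)})


class TestCallSites:
    def test_plus_strand_site_and_acceptor(self, acceptor_genome):
        sites = call_sites([_mr(start=500)], acceptor_genome)
        (s,) = sites
        assert (s.position, s.strand, s.acceptor) == (500, "+", "AG")

    def test_reads_at_same_site_merge(self, acceptor_genome):
        reads = [
            _mr(start=500, sl_class="SL1", read_id="a"),
            _mr(start=500, sl_class="SL1", read_id="b"),
            _mr(start=500, sl_class="SL2", read_id="c"),
        ]
        (s,) = call_sites(reads, acceptor_genome)
        assert (s.count_sl1, s.count_sl2) == (2, 1)

    def test_minus_strand_acceptor_is_reverse_complemented(self):
        # build a contig where a '-' gene's acceptor lies downstream:
        # site at the read's rightmost base; genomic CT just after it reads
        # AG on the minus strand
        seq = "A" * 50 + "CT" + "A" * 48
        genome = Genome({"m": seq})
        (s,) = call_sites([_mr(contig="m", start=20, strand="-", length=30)], genome)
        assert s.position == 49 and s.strand == "-"
        assert s.acceptor == revcomp(seq[50:52]) == "AG"

    def test_contig_edge_leaves_acceptor_undefined(self):
        genome = Genome({"e": "ACGTACGTACGTACGTACGT"})
        (s,) = call_sites([_mr(contig="e", start=1, strand="+", length=10)], genome)
        assert s.acceptor is None

    def test_multimappers_excluded_and_counts_conserved(self, acceptor_genome):
        reads = [_mr(start=500, read_id=f"r{i}") for i in range(5)]
        reads.append(_mr(start=600, read_id="multi", unique=False))
        sites = call_sites(reads, acceptor_genome)
        assert sum(s.total for s in sites) == 5


class TestAgFraction:
    def test_all_and_none(self, acceptor_genome):
        all_ag = call_sites([_mr(start=500)], acceptor_genome)
        assert ag_fraction(all_ag) == 1.0
        none_ag = call_sites([_mr(start=40)], acceptor_genome)
        assert ag_fraction(none_ag) == 0.0

    def test_no_defined_acceptor_is_an_error(self):
        genome = Genome({"e": "ACGTACGTACGTACGTACGT"})
        sites = call_sites([_mr(contig="e", start=1, strand="+", length=10)], genome)
        with pytest.raises(ValueError):
            ag_fraction(sites)


class TestConsensus:
    def test_planted_hexamer_reaches_two_bits(self, acceptor_genome):
        sites = call_sites([_mr(start=500)], acceptor_genome)
        mat = consensus(sites, acceptor_genome, window=(6, 2))
        for pos in range(-6, 0):
            assert mat.information[pos] == pytest.approx(2.0)
        assert np.allclose(mat.frequencies.sum(axis=0), 1.0)

    def test_uniform_background_has_low_information(self, rng):
        genome = Genome({"r": "".join(rng.choice(list("ACGT"), size=20_000))})
        reads = [
            _mr(contig="r", start=int(p), read_id=f"r{i}")
            for i, p in enumerate(rng.integers(10, 19_900, size=800))
        ]
        mat = consensus(call_sites(reads, genome), genome, window=(6, 2))
        assert mat.information.max() < 0.1

    def test_matches_bruteforce_tabulation(self, rng):
        genome = Genome({"r": "".join(rng.choice(list("ACGT"), size=5_000))})
        positions = sorted(set(int(p) for p in rng.integers(20, 4_900, size=60)))
        reads = [_mr(contig="r", start=p, read_id=f"r{p}") for p in positions]
        sites = call_sites(reads, genome)
        U, V = 5, 3
        mat = consensus(sites, genome, window=(U, V))
        seq = genome.contigs["r"]
        for offset in range(-U, V):
            counts = {b: 0 for b in "ACGT"}
            for p in positions:
                counts[seq[p + offset]] += 1
            for base in "ACGT":
                assert mat.frequencies.loc[base, offset] == pytest.approx(
                    counts[base] / len(positions)
                )
            info = 2.0 + sum(
                (c / len(positions)) * math.log2(c / len(positions))
                for c in counts.values() if c
            )
            assert mat.information[offset] == pytest.approx(info)

    def test_strand_awareness_on_minus_sites(self):
        seq = "G" * 40 + "TTTCAG" + "C" * 10 + "CTGAAA" + "G" * 38
        genome = Genome({"p": seq})
        plus = call_sites([_mr(contig="p", start=46, strand="+", length=10)], genome)
        minus = call_sites([_mr(contig="p", start=46, strand="-", length=10)], genome)
        m_plus = consensus(plus, genome, window=(6, 1))
        m_minus = consensus(minus, genome, window=(6, 1))
        for pos in range(-6, 0):
            assert m_plus.frequencies[pos].equals(m_minus.frequencies[pos])


class TestCountByGene:
    GENES = [
        GeneModel("g1", "c", 100, 400, "+"),
        GeneModel("g2", "c", 450, 800, "+"),
        GeneModel("g3", "c", 780, 1100, "-"),
    ]

    def test_read_inside_single_gene(self):
        counts, unassigned = count_by_gene([_mr(start=150)], self.GENES)
        assert {c.gene_id: c.sl1 for c in counts} == {"g1": 1, "g2": 0, "g3": 0}
        assert unassigned == 0

    def test_strand_mismatch_not_assigned(self):
        counts, unassigned = count_by_gene([_mr(start=900, strand="+")], self.GENES)
        assert unassigned == 1

    def test_read_overlapping_two_genes_unassigned(self):
        genes = [GeneModel("a", "c", 100, 400, "+"), GeneModel("b", "c", 390, 700, "+")]
        counts, unassigned = count_by_gene([_mr(start=380)], genes)
        assert unassigned == 1 and all(c.sl1 + c.sl2 == 0 for c in counts)

    def test_assigned_plus_unassigned_conserved(self, rng):
        reads = [
            _mr(start=int(p), strand="+" if rng.random() < 0.5 else "-",
                read_id=f"r{i}")
            for i, p in enumerate(rng.integers(0, 1200, size=300))
        ]
        counts, unassigned = count_by_gene(reads, self.GENES)
        assert sum(c.sl1 + c.sl2 for c in counts) + unassigned == 300

    def test_ratio_undefined_without_events(self):
        c = GeneSLCounts("g", 0, 0, False)
        assert c.ratio is None
        assert GeneSLCounts("g", 1, 3, True).ratio == pytest.approx(0.75)


class TestRoc:
    def test_perfect_separation(self):
        counts = [GeneSLCounts(f"d{i}", 0, 10, True) for i in range(20)] + [
            GeneSLCounts(f"o{i}", 10, 0, False) for i in range(20)
        ]
        result = roc(counts)
        assert result.auc == pytest.approx(1.0)
        assert result.tpr_at_fdr[0.05] == pytest.approx(1.0)

    def test_shuffled_labels_near_half(self, rng):
        counts = [
            GeneSLCounts(f"g{i}", int(rng.integers(0, 20)),
                         int(rng.integers(0, 20)) + 1, bool(rng.random() < 0.5))
            for i in range(600)
        ]
        assert abs(roc(counts).auc - 0.5) < 0.1

    def test_matches_bruteforce_sweep_on_ten_genes(self):
        ratios = [0.0, 0.1, 0.2, 0.35, 0.5, 0.55, 0.7, 0.8, 0.9, 1.0]
        labels = [False, False, False, True, False, True, True, False, True, True]
        counts = [
            GeneSLCounts(f"g{i}", round(100 * (1 - r)), round(100 * r), lab)
            for i, (r, lab) in enumerate(zip(ratios, labels))
        ]
        result = roc(counts)
        # brute force: every threshold, predicted positive = ratio >= t
        n_pos = sum(labels)
        n_neg = len(labels) - n_pos
        brute = set()
        for t in [-0.1] + ratios + [1.1]:
            tp = sum(1 for r, lab in zip(ratios, labels) if r >= t and lab)
            fp = sum(1 for r, lab in zip(ratios, labels) if r >= t and not lab)
            brute.add((round(fp / n_neg, 12), round(tp / n_pos, 12)))
        got = {(round(f, 12), round(t, 12)) for f, t in zip(result.fpr, result.tpr)}
        assert got <= brute
        # AUC equals the trapezoid over the full brute curve
        pts = sorted(brute)
        auc = sum(
            (x2 - x1) * (y1 + y2) / 2 for (x1, y1), (x2, y2) in zip(pts, pts[1:])
        )
        assert result.auc == pytest.approx(auc)

    def test_single_class_is_an_error(self):
        counts = [GeneSLCounts(f"g{i}", 1, 1, True) for i in range(5)]
        with pytest.raises(ValueError):
            roc(counts)

    def test_min_events_filter_excludes_undefined_ratios(self):
        counts = [GeneSLCounts("a", 0, 0, True), GeneSLCounts("b", 5, 5, True),
                  GeneSLCounts("c", 8, 0, False)]
        result = roc(counts, min_events=1)
        assert len(result.thresholds) <= 3  # gene 'a' excluded


class TestGff3RoundTrip:
    def test_write_then_read_preserves_models(self, tmp_path):
        genes = [
            GeneModel("gA", "chr1", 99, 400, "+", "op1", 1),
            GeneModel("gB", "chr1", 550, 900, "+", "op1", 2),
            GeneModel("gC", "chr1", 1000, 1300, "-", None, None),
        ]
        path = str(tmp_path / "genes.gff3")
        write_gff3(genes, path)
        got = read_gff3_genes(path)
        assert [(g.gene_id, g.start, g.end, g.strand, g.operon_id, g.operon_position)
                for g in got] == [
            ("gA", 99, 400, "+", "op1", 1),
            ("gB", 550, 900, "+", "op1", 2),
            ("gC", 1000, 1300, "-", None, None),
        ]
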