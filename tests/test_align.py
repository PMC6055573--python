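"""Seeded local aligner, anchored matcher, and e-value statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sltrans import (
    AlignScoring,
    Read,
    SLDatabase,
    SLIsoform,
    anchored_match,
    best_call,
    evalue,
    local_align,
)
from sltrans._seq import revcomp
from sltrans.align import (
    _shares_word,
    effective_lengths,
    relative_entropy,
    solve_ungapped_lambda,
)
from sltrans.samio import ConfigurationError


class TestDatabase:
    def test_bundled_celegans_set(self, db):
        assert len(db) == 12
        assert db.class_of["SL1"] == "SL1"
        assert sum(1 for i in db if i.sl_class == "SL2") == 11
        # the two flagship leaders are 22 nt; natural variants span 21-23
        assert len(db["SL1"].sequence) == 22
        assert len(db["SL2"].sequence) == 22
        assert all(21 <= len(i.sequence) <= 23 for i in db)
        # every isoform ends in the AG that sits at the splice junction
        assert all(i.sequence.endswith("AG") for i in db)

    def test_duplicate_names_rejected(self):
        iso = SLIsoform("X", "SL1", "ACGTACGT")
        with pytest.raises(ValueError):
            SLDatabase([iso, iso])


class TestLocalAlign:
    def test_planted_suffix_is_anchored_alignment(self, db, scoring):
        iso = db["SL2"]
        read = Read(id="r", sequence=iso.sequence[-11:] + "T" * 39)
        aln = local_align(read, iso, scoring)
        assert (aln.q_start, aln.s_end) == (0, len(iso.sequence))
        assert aln.aligned_length == 11
        assert aln.score == 11 * scoring.match_reward
        assert aln.mismatches == 0 and aln.gaps == 0

    def test_no_shared_word_returns_none(self, db, scoring):
        iso = db["SL1"]
        read = Read(id="r", sequence="C" * 50)  # no SL has an 8-mer of Cs
        assert not _shares_word(read.sequence, iso.sequence, scoring.word_size)
        assert local_align(read, iso, scoring) is None

    def test_reverse_complement_hit_flagged(self, db, scoring):
        iso = db["SL1"]
        # read carries the reverse complement of the SL 5' half
        read = Read(id="r", sequence="T" * 20 + revcomp(iso.sequence[:11]) + "G" * 19)
        aln = local_align(read, iso, scoring, search_rc=True)
        assert aln is not None and aln.on_reverse_complement
        assert aln.score == 11 * scoring.match_reward

    def test_read_shorter_than_word_size(self, db, scoring):
        read = Read(id="r", sequence="ACGTA")
        assert local_align(read, db["SL1"], scoring) is None

    def test_score_matches_smith_waterman_oracle(self, db, scoring, sw_oracle, rng):
        """Seeded aligner equals full-DP oracle whenever a seed exists; a
        None means the pair genuinely shares no word of word_size."""
        n_aligned = n_missed = 0
        for _ in range(500):
            length = int(rng.integers(10, 77))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if rng.random() < 0.5 and length > 12:
                iso = db.isoforms[int(rng.integers(len(db)))]
                k = int(rng.integers(5, min(len(iso.sequence), length) + 1))
                seq = iso.sequence[-k:] + seq[k:]
            iso = db.isoforms[int(rng.integers(len(db)))]
            aln = local_align(Read(id="r", sequence=seq), iso, scoring)
            if aln is None:
                n_missed += 1
                if length >= scoring.word_size:
                    assert not _shares_word(seq, iso.sequence, scoring.word_size)
            else:
                n_aligned += 1
                assert aln.score == sw_oracle.score(seq, iso.sequence)
        assert n_aligned >= 100 and n_missed >= 100  # both branches exercised

    def test_gapless_score_consistency(self, db, scoring, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            iso = db.isoforms[int(rng.integers(len(db)))]
            aln = local_align(Read(id="r", sequence=seq), iso, scoring)
            if aln is not None and aln.gaps == 0:
                matches = aln.aligned_length - aln.mismatches
                assert aln.score == (
                    matches * scoring.match_reward
                    + aln.mismatches * scoring.mismatch_penalty
                )


class TestAnchoredMatch:
    def test_ten_nt_overlap_tolerates_one_mismatch(self, db):
        iso = db["SL1"]
        suffix = list(iso.sequence[-10:])
        suffix[4] = "A" if suffix[4] != "A" else "G"
        read = Read(id="r", sequence="".join(suffix) + "T" * 40)
        aln = anchored_match(read, iso)
        assert aln is not None and aln.aligned_length == 10 and aln.mismatches == 1

    def test_five_nt_overlap_allows_no_mismatch(self, db):
        iso = db["SL1"]
        prefix = list(iso.sequence[-5:])
        prefix[2] = "A" if prefix[2] != "A" else "G"
        # avoid accidental longer overlaps by padding with Cs
        read = Read(id="r", sequence="".join(prefix) + "C" * 40)
        aln = anchored_match(read, iso)
        assert aln is None or aln.mismatches <= math.floor(0.1 * aln.aligned_length)

    def test_four_nt_overlap_below_minimum(self, db):
        iso = db["SL1"]
        read = Read(id="r", sequence=iso.sequence[-4:] + "C" * 40)
        assert anchored_match(read, iso) is None

    def test_agrees_with_bruteforce_enumeration(self, db, rng):
        """Exhaustive check against enumeration of every (overlap, mismatch)
        pair for short reads."""

        def brute(read_seq, sl, min_overlap=5, rate=0.10):
            best = None
            for L in range(min_overlap, min(len(sl), len(read_seq)) + 1):
                mm = sum(
                    1
                    for a, b in zip(read_seq[:L], sl[len(sl) - L :])
                    if a != b or "N" in (a, b)
                )
                if mm <= math.floor(rate * L):
                    best = (L, mm)
            return best

        for _ in range(400):
            length = int(rng.integers(5, 31))
            seq = "".join(rng.choice(list("ACGTN"), size=length,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            if rng.random() < 0.6:
                iso = db.isoforms[int(rng.integers(len(db)))]
                k = int(rng.integers(3, min(len(iso.sequence), length) + 1))
                seq = iso.sequence[-k:] + seq[k:]
            iso = db.isoforms[int(rng.integers(len(db)))]
            aln = anchored_match(Read(id="r", sequence=seq), iso)
            expected = brute(seq, iso.sequence)
            if expected is None:
                assert aln is None
            else:
                assert (aln.aligned_length, aln.mismatches) == expected

    @given(st.integers(5, 22))
    @settings(deadline=None, derandomize=True)
    def test_perfect_suffix_always_accepted(self, overlap):
        db = SLDatabase.celegans()
        iso = db["SL2"]
        overlap = min(overlap, len(iso.sequence))
        read = Read(id="r", sequence=iso.sequence[-overlap:] + "C" * 30)
        aln = anchored_match(read, iso)
        assert aln is not None and aln.aligned_length >= overlap


class TestEvalue:
    def test_monotone_in_score_and_lengths(self, scoring):
        assert evalue(22, 50, 264, scoring) < evalue(20, 50, 264, scoring)
        assert evalue(20, 50, 264, scoring) < evalue(20, 76, 264, scoring)
        assert evalue(20, 50, 264, scoring) < evalue(20, 50, 528, scoring)

    def test_zero_score_equals_search_space(self, scoring):
        assert evalue(0, 50, 264, scoring) == pytest.approx(
            scoring.karlin_k * 50 * 264
        )

    def test_closed_form(self, scoring):
        expected = scoring.karlin_k * 50 * 264 * math.exp(-scoring.lam * 22)
        assert evalue(22, 50, 264, scoring) == pytest.approx(expected)

    def test_rank_identical_to_score_rank(self, scoring):
        scores = list(range(8, 40))
        es = [evalue(s, 50, 264, scoring) for s in scores]
        assert es == sorted(es, reverse=True)

    def test_ungapped_lambda_solves_karlin_identity(self):
        lam = solve_ungapped_lambda(2, -3)
        identity = 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam)
        assert identity == pytest.approx(1.0, abs=1e-9)
        assert lam == pytest.approx(0.634, abs=2e-3)

    def test_effective_lengths_shrink_search_space(self, scoring):
        m_eff, n_eff = effective_lengths(50, 264, 12, scoring)
        assert 1 <= m_eff < 50 and 12 <= n_eff < 264
        assert relative_entropy(scoring) > 0
        raw = AlignScoring(length_adjusted=False)
        assert effective_lengths(50, 264, 12, raw) == (50.0, 264.0)

    def test_significance_cutoff_matches_modal_alignment_lengths(self, db, scoring):
        """Perfect 9-11-nt SL matches on 50-nt reads are significant at 0.05;
        8-nt matches are not (so anchored 5-8-nt matches are the sensitive
        mode's exclusive territory)."""
        m, n = effective_lengths(50, db.total_length, len(db), scoring)
        m, n = int(round(m)), int(round(n))
        assert evalue(18, m, n, scoring) < 0.05  # 9-nt perfect match
        assert evalue(20, m, n, scoring) < 0.05  # 10 nt
        assert evalue(22, m, n, scoring) < 0.05  # 11 nt
        assert evalue(16, m, n, scoring) > 0.05  # 8 nt


class TestBestCall:
    def test_returns_best_isoform(self, db, scoring):
        iso = db["SL2"]
        read = Read(id="r", sequence=iso.sequence[-12:] + "T" * 38)
        aln = best_call(read, db, "default", scoring)
        # SL2's 12-nt suffix is shared with no other isoform at equal length
        assert aln.score >= 12 * scoring.match_reward
        assert db.class_of[aln.isoform_name] == "SL2"

    def test_tie_broken_by_database_order(self, db, scoring):
        # SL3's 10-nt suffix GTTAACCAAG is identical in SL8/SL9/SL10
        shared = db["SL3"].sequence[-10:]
        assert db["SL8"].sequence[-10:] == shared
        read = Read(id="r", sequence=shared + "C" * 40)
        aln = best_call(read, db, "default", scoring)
        assert aln.isoform_name == "SL3"  # first in database order
        assert db.class_of[aln.isoform_name] == "SL2"

    def test_no_match_returns_none(self, db, scoring):
        read = Read(id="r", sequence="C" * 50)
        assert best_call(read, db, "default", scoring) is None

    def test_empty_database_is_configuration_error(self, scoring):
        with pytest.raises((ConfigurationError, ValueError)):
            best_call(Read(id="r", sequence="ACGT" * 10), SLDatabase([]), "default", scoring)

    def test_sensitive_respects_strandedness(self, db, scoring):
        iso = db["SL1"]
        rc_read = Read(
            id="r", sequence="C" * 30 + revcomp(iso.sequence[-12:])
        )
        # stranded (sense-oriented) read: sensitive mode must not search rc
        assert best_call(rc_read, db, "sensitive", scoring) is None
        unstranded = Read(
            id="r", sequence=rc_read.sequence, search_both_strands=True
        )
        aln = best_call(unstranded, db, "sensitive", scoring)
        assert aln is not None and aln.on_reverse_complement
        # tourasse always searches the reverse complement
        assert best_call(rc_read, db, "tourasse", scoring) is not None
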