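"""Alignment primitives: oracle agreement, translation, ORFs, search, merging."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from panfam.align import (
    GenomicHit,
    KmerIndex,
    ScoringScheme,
    dna_default,
    find_orfs,
    fit_align,
    global_align,
    local_align,
    merge_hits,
    reverse_complement,
    seed_extend_search,
    translate,
)

from .oracles import enumerate_global, enumerate_local, gotoh_global, gotoh_local

SCHEME = ScoringScheme((1, -1), -2, -1)


class TestGlobalAlign:
    @pytest.mark.parametrize(
        "a,b,score,identity",
        [
            ("ACGT", "ACGT", 4, 1.0),
            ("ACGT", "AGT", 0, None),   # 3 matches + one length-1 gap (-3)
            ("", "ACG", -5, 0.0),       # single length-3 gap
        ],
    )
    def test_examples(self, a, b, score, identity):
        aln = global_align(a, b, SCHEME)
        assert aln.score == score
        if identity is not None:
            assert aln.identity == pytest.approx(identity)

    def test_gap_removal_reproduces_inputs(self):
        aln = global_align("ACGTTGCA", "AGTTGA", SCHEME)
        assert aln.aligned_a.replace("-", "") == "ACGTTGCA"
        assert aln.aligned_b.replace("-", "") == "AGTTGA"

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme((1, -1), 2, 1)
        with pytest.raises(ValueError):
            ScoringScheme((1, -1), -1, -2)  # open must be <= extend


class TestLocalAlign:
    def test_embedded_motif(self):
        aln = local_align("TTTACGTTT", "GGGACGGGG", SCHEME)
        assert aln.score == 3
        assert aln.aligned_a == "ACG"

    def test_identical_full_length(self):
        aln = local_align("ACGTACGT", "ACGTACGT", SCHEME)
        assert aln.score == 8

    def test_no_positive_pair_is_empty(self):
        aln = local_align("AAAA", "TTTT", SCHEME)
        assert aln.score == 0
        assert aln.aligned_a == ""


class TestOracleEquivalence:
    """The DP oracle is validated by exhaustive enumeration at tiny sizes;
    the aligners are then validated against the DP oracle at length <= 12."""

    def test_dp_oracle_matches_enumeration(self):
        rng = random.Random(42)
        for _ in range(40):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 5)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 5)))
            assert gotoh_global(a, b, 1, -1, -2, -1) == pytest.approx(
                enumerate_global(a, b, 1, -1, -2, -1)
            )
            if a and b:
                assert gotoh_local(a, b, 1, -1, -2, -1) == pytest.approx(
                    enumerate_local(a, b, 1, -1, -2, -1)
                )

    def test_aligners_match_dp_oracle(self):
        rng = random.Random(7)
        for _ in range(200):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            assert global_align(a, b, SCHEME).score == pytest.approx(
                gotoh_global(a, b, 1, -1, -2, -1)
            )
            assert local_align(a, b, SCHEME).score == pytest.approx(
                gotoh_local(a, b, 1, -1, -2, -1)
            )


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,frame,strand,expected",
        [
            ("ATGAAATAG", 0, "+", "MK*"),
            ("CAT", 0, "-", "M"),
            ("ATGA", 0, "+", "M"),
            ("ATGNNNAAA", 0, "+", "MXK"),
            ("AATGGC", 1, "+", "M"),
        ],
    )
    def test_examples(self, dna, frame, strand, expected):
        assert translate(dna, frame, strand) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=30),
           st.integers(min_value=0, max_value=2))
    def test_reverse_complement_identity(self, dna, frame):
        assert translate(reverse_complement(dna), frame, "+") == \
            translate(dna, frame, "-")


class TestFindOrfs:
    def test_simple_orf(self):
        orfs = find_orfs("ATGAAATAG", min_aa=2)
        assert orfs == [(0, "+", 0, 9, "MK")]

    def test_no_atg(self):
        assert find_orfs("CCCCCCCCC", min_aa=1) == []

    def test_reverse_strand_coordinates(self):
        fwd = "ATGAAACCCTAG"  # MKP*
        seq = "GG" + reverse_complement(fwd) + "TTT"
        orfs = [o for o in find_orfs(seq, min_aa=3) if o[1] == "-"]
        assert len(orfs) == 1
        frame, strand, start, end, pep = orfs[0]
        assert pep == "MKP"
        assert seq[start:end] == reverse_complement(fwd)


class TestSeedExtend:
    def _random_dna(self, rng, n):
        return "".join(rng.choice("ACGT") for _ in range(n))

    def test_planted_exact_copy(self):
        rng = random.Random(0)
        query = self._random_dna(rng, 300)
        background = self._random_dna(rng, 10_000)
        subject = background[:5000] + query + background[5000:]
        hits = seed_extend_search(query, {"c1": subject})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (5000, 5300, "+")
        assert h.identity == 1.0 and h.coverage == 1.0

    def test_planted_reverse_complement(self):
        rng = random.Random(1)
        query = self._random_dna(rng, 300)
        background = self._random_dna(rng, 10_000)
        subject = background[:5000] + reverse_complement(query) + background[5000:]
        hits = seed_extend_search(query, {"c1": subject})
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_no_shared_kmers_no_hits(self):
        rng = random.Random(5)
        query = self._random_dna(rng, 300)
        subject = self._random_dna(rng, 10_000)
        shared = {query[i:i + 15] for i in range(len(query) - 14)} & \
                 {subject[i:i + 15] for i in range(len(subject) - 14)}
        assert not shared  # the premise of the test
        assert seed_extend_search(query, {"c1": subject}) == []

    def test_query_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError):
            seed_extend_search("ACGT", {"c1": "ACGT" * 100})

    def test_diverged_copy_recovered(self):
        rng = random.Random(9)
        query = self._random_dna(rng, 400)
        copy = "".join(
            c if rng.random() > 0.04 else rng.choice("ACGT".replace(c, ""))
            for c in query
        )
        subject = self._random_dna(rng, 8000) + copy + self._random_dna(rng, 2000)
        hits = seed_extend_search(query, {"c1": subject}, min_identity=0.9,
                                  min_coverage=0.8)
        assert len(hits) == 1
        assert hits[0].identity >= 0.9


def _hit(start, end, qspan=None, replicon="c1", strand="+"):
    return GenomicHit("q", None, replicon, start, end, strand, 0.95, 0.5, 100.0,
                      query_span=qspan)


class TestMergeHits:
    def test_overlapping_fragments_merge(self):
        loci = merge_hits([_hit(100, 400, (0, 250)), _hit(300, 600, (240, 500))])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 600)

    def test_distant_hits_stay_separate(self):
        loci = merge_hits([_hit(0, 300), _hit(10_000, 10_300)], max_gap=2000)
        assert len(loci) == 2

    def test_nearby_fragments_merge_across_gap(self):
        loci = merge_hits([_hit(0, 300, (0, 300)), _hit(400, 700, (320, 620))],
                          max_gap=2000)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (0, 700)

    def test_two_full_length_copies_never_merge(self):
        # Tandem copies closer than max_gap: both cover the whole query.
        loci = merge_hits([_hit(0, 500, (0, 500)), _hit(900, 1400, (0, 500))],
                          max_gap=2000)
        assert len(loci) == 2

    def test_idempotent_and_order_independent(self):
        hits = [_hit(0, 300, (0, 300)), _hit(350, 650, (310, 610)),
                _hit(5000, 5300, (0, 300))]
        loci1 = merge_hits(hits)
        loci2 = merge_hits(list(reversed(hits)))
        assert [(l.start, l.end) for l in loci1] == \
            [(l.start, l.end) for l in loci2]
        rehit = [
            _hit(l.start, l.end, (0, l.end - l.start)) for l in loci1
        ]
        assert [(l.start, l.end) for l in merge_hits(rehit)] == \
            [(l.start, l.end) for l in loci1]


class TestFitAlign:
    def test_overhangs_are_free(self):
        aln = fit_align("ACGTACGT", "TTTTACGTACGTTTTT", SCHEME)
        assert aln.score == 8
        assert aln.query_span == (0, 8)
        assert aln.subject_span == (4, 12)

    def test_internal_deletion_called(self):
        a = "ACGTACGTGGCCAAGG"
        b = "TT" + a[:6] + a[9:] + "TT"  # 3-base deletion inside a
        aln = fit_align(a, b, dna_default())
        indels = aln.indels()
        assert indels == [(6, -3)]
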