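"""Alignment, identity and K2P distance unit/property tests."""
import random
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eggbarcode import (
    ReferenceLibrary,
    ReferenceRecord,
    align_pair,
    k2p_distance,
    orient_query,
    percent_identity,
    reverse_complement,
    search_library,
)
from eggbarcode.errors import (
    InputError,
    SaturatedDistanceError,
    UndefinedIdentityError,
)
from eggbarcode.pairwise import PairwiseAlignment, count_columns, k2p_from_proportions

from _oracles import brute_force_align_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def _mini_library():
    return ReferenceLibrary([
        ReferenceRecord(id="r1", sequence="ACGTACGTACGTACGTACGT",
                        family="F", genus="G", species="G a"),
        ReferenceRecord(id="r2", sequence="TTTTACGTACGTACGTCCCC",
                        family="F", genus="G", species="G b"),
    ])


class TestAlignPair:
    def test_identical_sequences(self):
        seq = "ACGT" * 20
        aln = align_pair(seq, seq)
        assert aln.n_compared == 80
        assert aln.n_matches == 80
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_mismatch_no_gaps(self):
        aln = align_pair("ACGT", "ACTT", gap_open=-2, gap_extend=-2)
        assert aln.n_columns == 4
        assert aln.n_matches == 3
        assert aln.n_compared == 4

    def test_query_floats_free_inside_reference(self):
        aln = align_pair("AAAACGTACGTTTT", "CGTACG")
        assert aln.n_matches == 6
        assert aln.score == 6

    def test_internal_gap_is_charged(self):
        rng = random.Random(42)
        left = "".join(rng.choice("ACGT") for _ in range(30))
        right = "".join(rng.choice("ACGT") for _ in range(30))
        ref = left + "TTTTT" + right
        query = left + right
        aln = align_pair(ref, query)
        # 60 matches minus an internal 5-column gap (open -5, 4 extensions -2)
        assert aln.score == 60 - 5 - 4 * 2
        assert "-----" in aln.aligned_b

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            align_pair("", "ACGT")
        with pytest.raises(InputError):
            align_pair("ACGT", "")

    def test_ambiguity_codes_excluded_from_compared(self):
        aln = align_pair("ACGTN", "ACGTA")
        assert aln.n_compared == 4
        assert aln.n_matches == 4

    @pytest.mark.parametrize("trial", range(40))
    def test_score_matches_exhaustive_enumeration(self, trial):
        rng = random.Random(1000 + trial)
        ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
        query = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
        got = align_pair(ref, query).score
        want = brute_force_align_score(ref, query)
        assert got == pytest.approx(want)

    def test_score_matches_biopython_on_random_pairs(self):
        Align = pytest.importorskip("Bio.Align")
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligner.open_left_deletion_score = 0
            aligner.extend_left_deletion_score = 0
            aligner.open_right_deletion_score = 0
            aligner.extend_right_deletion_score = 0
        rng = random.Random(7)
        for _ in range(100):
            ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 80)))
            q = list(ref)
            for _ in range(rng.randint(0, 6)):
                q[rng.randrange(len(q))] = rng.choice("ACGT")
            if rng.random() < 0.4 and len(q) > 4:
                p = rng.randrange(len(q) - 2)
                del q[p : p + rng.randint(1, 2)]
            query = "".join(q) or "A"
            assert align_pair(ref, query).score == pytest.approx(
                aligner.score(ref, query)
            )

    @given(a=dna, b=dna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_alignment_counts_partition_compared_columns(self, a, b):
        aln = align_pair(a, b)
        assert len(aln.aligned_a) == len(aln.aligned_b) == aln.n_columns
        assert aln.n_matches + aln.n_transitions + aln.n_transversions == aln.n_compared
        # ungapping the rows recovers the inputs
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(align_pair("ACGT" * 25, "ACGT" * 25)) == 1.0

    def test_one_mismatch_in_hundred(self):
        a = "ACGT" * 25
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert percent_identity(align_pair(a, b)) == pytest.approx(0.99)

    def test_gap_columns_excluded_from_denominator(self):
        # 48 aligned columns of which one mismatch, plus a 2-base deletion
        aln = PairwiseAlignment(
            aligned_a="A" * 25 + "CC" + "A" * 23,
            aligned_b="A" * 20 + "T" + "A" * 4 + "--" + "A" * 23,
            score=0.0,
            n_columns=50,
            n_compared=48,
            n_matches=47,
            n_transitions=0,
            n_transversions=1,
        )
        assert percent_identity(aln) == pytest.approx(47 / 48)

    def test_undefined_identity(self):
        aln = align_pair("NNNN", "NNNN")
        with pytest.raises(UndefinedIdentityError):
            percent_identity(aln)

    def test_symmetry_for_substitution_only_pairs(self):
        # Free end gaps sit on the query row only, so identity is symmetric
        # whenever the optimal alignment is substitution-only (the generic
        # barcode case); degenerate repeats can break exact symmetry.
        rng = random.Random(13)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(60))
            b = list(a)
            for _ in range(rng.randint(0, 10)):
                b[rng.randrange(60)] = rng.choice("ACGT")
            b = "".join(b)
            assert percent_identity(align_pair(a, b)) == pytest.approx(
                percent_identity(align_pair(b, a))
            )

    def test_extra_mismatches_never_increase_identity(self):
        rng = random.Random(5)
        ref = "".join(rng.choice("ACGT") for _ in range(120))
        prev = 1.0
        seq = list(ref)
        positions = rng.sample(range(len(ref)), 30)
        for pos in positions:
            cur = seq[pos]
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cur]
            ident = percent_identity(align_pair(ref, "".join(seq)))
            assert ident <= prev + 1e-12
            prev = ident


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance(align_pair("ACGT" * 20, "ACGT" * 20)) == 0.0

    def test_closed_form_value(self):
        # P=0.10, Q=0.05: d = -1/2 ln[(0.75) * sqrt(0.9)]
        assert k2p_from_proportions(0.10, 0.05) == pytest.approx(0.17018, abs=1e-5)

    def test_saturation_boundary(self):
        with pytest.raises(SaturatedDistanceError):
            k2p_from_proportions(0.45, 0.10)  # 1 - 2P - Q == 0

    def test_symmetric_in_alignment_direction(self):
        a = "ACGTACGTACGTACGTACGTGGCC"
        b = "ACGTACGTACGAACGTACGTGGTC"
        assert k2p_distance(align_pair(a, b)) == pytest.approx(
            k2p_distance(align_pair(b, a))
        )

    def test_k2p_at_least_total_substitution_proportion(self):
        # Jensen-type bound d >= P + Q over a grid inside the domain
        for P in np.linspace(0, 0.3, 13):
            for Q in np.linspace(0, 0.3, 13):
                if 1 - 2 * P - Q > 1e-9 and 1 - 2 * Q > 1e-9:
                    assert k2p_from_proportions(P, Q) >= P + Q - 1e-12

    def test_transition_transversion_classification(self):
        n, match, ts, tv = count_columns("AG" + "CT" + "AC" + "GT", "GA" + "TC" + "CA" + "TG")
        assert (n, match, ts, tv) == (8, 0, 4, 4)


class TestOrientAndSearch:
    def test_query_equal_to_reference_unchanged(self):
        lib = _mini_library()
        q = lib.records[0].sequence
        assert orient_query(q, lib) == q

    def test_reverse_complement_flipped_back(self):
        lib = _mini_library()
        q = reverse_complement(lib.records[0].sequence)
        assert orient_query(q, lib) == lib.records[0].sequence

    def test_orientation_agrees_with_two_strand_brute_force(self):
        lib = _mini_library()
        rng = random.Random(3)
        for _ in range(10):
            q = "".join(rng.choice("ACGT") for _ in range(20))
            fwd = max(
                percent_identity(align_pair(r.sequence, q)) for r in lib
            )
            rc = max(
                percent_identity(align_pair(r.sequence, reverse_complement(q)))
                for r in lib
            )
            expect = reverse_complement(q) if rc > fwd else q
            assert orient_query(q, lib) == expect

    def test_exact_hit_ranks_first(self):
        lib = _mini_library()
        hl = search_library(lib.records[0].sequence, lib, top_n=10)
        assert hl.hits[0].reference_id == "r1"
        assert hl.hits[0].identity == 1.0
        assert hl.hits[0].rank == 1

    def test_top_n_truncation(self):
        lib = _mini_library()
        hl = search_library(lib.records[0].sequence, lib, top_n=100)
        assert len(hl.hits) == 2  # library smaller than top_n

    def test_ranking_matches_brute_force_on_random_library(self):
        rng = random.Random(9)
        base = "".join(rng.choice("ACGT") for _ in range(60))
        records = []
        for i in range(20):
            seq = list(base)
            for _ in range(rng.randint(0, 12)):
                seq[rng.randrange(len(seq))] = rng.choice("ACGT")
            records.append(
                ReferenceRecord(id=f"ref{i:02d}", sequence="".join(seq),
                                family="F", genus=f"G{i % 3}",
                                species=f"G{i % 3} sp{i}")
            )
        lib = ReferenceLibrary(records)
        q = base
        hl = search_library(q, lib, top_n=20)
        brute = sorted(
            ((percent_identity(align_pair(r.sequence, q)), r.id) for r in lib),
            key=lambda t: (-t[0], t[1]),
        )
        assert [h.reference_id for h in hl.hits] == [rid for _, rid in brute]
        assert [h.identity for h in hl.hits] == pytest.approx(
            [ident for ident, _ in brute]
        )

    def test_second_best_is_best_other_species(self):
        lib = _mini_library()
        hl = search_library(lib.records[0].sequence, lib, top_n=10)
        best_sp = hl.hits[0].species
        expect = max(h.identity for h in hl.hits if h.species != best_sp)
        assert hl.second_best_species_identity == pytest.approx(expect)

    def test_single_species_library_has_no_second_best(self):
        lib = ReferenceLibrary([
            ReferenceRecord(id="a", sequence="ACGTACGTACGT",
                            family="F", genus="G", species="G a"),
            ReferenceRecord(id="b", sequence="ACGTACGAACGT",
                            family="F", genus="G", species="G a"),
        ])
        hl = search_library("ACGTACGTACGT", lib, top_n=5)
        assert hl.second_best_species_identity is None
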