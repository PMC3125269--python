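import numpy as np
import pytest
from Bio import Align

from beskit._intervals import overlap_length, total_length
from beskit.masking import (
    CensusClass,
    MaskParams,
    RepeatElement,
    classify_hit_count,
    cross_mask_fraction,
    evalue_ungapped,
    mask_reads,
    mask_with_library,
    masked_fraction,
    nonrepetitive_eligible,
    screen_contaminants,
    self_hit_census,
)
from beskit.masking import revcomp

from conftest import make_read, random_dna


def sw_identity(a: str, b: str) -> float:
    """Independent Smith-Waterman oracle: best local-alignment identity."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0
    aln = alns[0]
    matches = sum(
        1
        for (qs, qe), (ts, te) in zip(*aln.aligned)
        for x, y in zip(a[qs:qe], b[ts:te])
        if x == y
    )
    columns = sum(qe - qs for qs, qe in aln.aligned[0])
    return matches / columns if columns else 0.0


def mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


@pytest.fixture(scope="module")
def library():
    rng = np.random.default_rng(42)
    return [RepeatElement("tc1", "DNA/TcMar-Tc1", random_dna(rng, 300)),
            RepeatElement("line2", "LINE/L2", random_dna(rng, 500))]


class TestMaskWithLibrary:
    def test_exact_copy_is_fully_masked(self, library):
        rng = np.random.default_rng(0)
        flank_l, flank_r = random_dna(rng, 200), random_dna(rng, 150)
        read = make_read(flank_l + library[0].consensus + flank_r)
        masked = mask_with_library(read, library)
        assert overlap_length(masked.mask, 200, 500) == 300
        # background essentially untouched
        assert overlap_length(masked.mask, 0, 195) == 0

    def test_diverged_copy_masked_when_oracle_identity_above_threshold(self, library):
        rng = np.random.default_rng(1)
        copy = mutate(rng, library[0].consensus, 0.15)
        assert sw_identity(copy, library[0].consensus) >= 0.80
        read = make_read(random_dna(rng, 120) + copy + random_dna(rng, 120))
        masked = mask_with_library(read, library, MaskParams(min_identity=0.80))
        assert overlap_length(masked.mask, 120, 120 + 300) >= 0.9 * 300

    def test_reverse_complement_copy_masked(self, library):
        rng = np.random.default_rng(2)
        read = make_read(random_dna(rng, 100) + revcomp(library[1].consensus)
                         + random_dna(rng, 100))
        masked = mask_with_library(read, library)
        assert overlap_length(masked.mask, 100, 600) == 500

    def test_no_hit_read_unchanged(self, library):
        read = make_read(random_dna(np.random.default_rng(3), 400))
        assert mask_with_library(read, library).mask == []

    def test_masking_is_idempotent(self, library):
        rng = np.random.default_rng(4)
        read = make_read(random_dna(rng, 100) + library[0].consensus + random_dna(rng, 80))
        once = mask_with_library(read, library)
        twice = mask_with_library(once, library)
        assert twice.mask == once.mask
        assert twice.bases == read.bases

    def test_lower_identity_threshold_never_masks_less(self, library):
        rng = np.random.default_rng(5)
        reads = [
            make_read(random_dna(rng, 60) + mutate(rng, library[0].consensus, d)
                      + random_dna(rng, 60), read_id=f"c{i}_T7")
            for i, d in enumerate([0.02, 0.1, 0.18, 0.3])
        ]
        strict = [mask_with_library(r, library, MaskParams(min_identity=0.9)) for r in reads]
        loose = [mask_with_library(r, library, MaskParams(min_identity=0.7)) for r in reads]
        assert masked_fraction(loose) >= masked_fraction(strict)

    def test_parameter_recovery_on_implanted_copies(self, library):
        """>=95% of implanted repeat bases masked, <=2% of background."""
        rng = np.random.default_rng(6)
        reads, implants = [], []
        for i in range(120):
            left = random_dna(rng, int(rng.integers(50, 200)))
            right = random_dna(rng, int(rng.integers(50, 200)))
            elem = library[int(rng.integers(2))]
            copy = mutate(rng, elem.consensus, float(rng.uniform(0, 0.15)))
            if rng.random() < 0.5:
                copy = revcomp(copy)
            reads.append(make_read(left + copy + right, read_id=f"c{i}_T7"))
            implants.append((len(left), len(left) + len(copy)))
        masked = mask_reads(reads, library)
        implant_bp = sum(e - s for s, e in implants)
        hit_bp = sum(overlap_length(r.mask, s, e)
                     for r, (s, e) in zip(masked, implants))
        bg_bp = sum(len(r.bases) - (e - s) for r, (s, e) in zip(masked, implants))
        bg_hit = sum(total_length(r.mask) for r in masked) - hit_bp
        assert hit_bp / implant_bp >= 0.95
        assert bg_hit / bg_bp <= 0.02


class TestMaskedFraction:
    def test_matches_hand_arithmetic(self):
        reads = [make_read("A" * 100, "c1_T7", mask=[(0, 60)]),
                 make_read("A" * 100, "c2_T7", mask=[(0, 59)])]
        assert masked_fraction(reads) == pytest.approx(59.5)

    def test_extremes(self):
        assert masked_fraction([make_read("ACGT" * 25)]) == 0.0
        assert masked_fraction([make_read("ACGT" * 25, mask=[(0, 100)])]) == 100.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            masked_fraction([])


class TestCrossMask:
    def test_identical_libraries_mask_fully(self, library):
        assert cross_mask_fraction(library, library) == pytest.approx(100.0)

    def test_subset_library_fully_masked_by_superset(self, library):
        assert cross_mask_fraction(library[:1], library) == pytest.approx(100.0)

    def test_disjoint_random_libraries_barely_mask(self):
        rng = np.random.default_rng(7)
        lib_a = [RepeatElement(f"a{i}", "Unknown", random_dna(rng, 400)) for i in range(3)]
        lib_b = [RepeatElement(f"b{i}", "Unknown", random_dna(rng, 400)) for i in range(3)]
        assert cross_mask_fraction(lib_a, lib_b,
                                   MaskParams(min_identity=0.8, min_hit_len=50)) < 2.0

    def test_asymmetry_is_possible(self, library):
        extra = library + [RepeatElement("x", "Unknown",
                                         random_dna(np.random.default_rng(8), 400))]
        assert cross_mask_fraction(library, extra) == pytest.approx(100.0)
        assert cross_mask_fraction(extra, library) < 100.0


class TestNonrepetitiveEligible:
    @pytest.mark.parametrize("run_len,expected", [(101, True), (100, False)])
    def test_strictly_more_than_threshold(self, run_len, expected):
        n = 400
        read = make_read("A" * n, mask=[(0, 150), (150 + run_len, n)])
        ok, run = nonrepetitive_eligible(read, min_run=100)
        assert ok is expected
        assert run == (150, 150 + run_len)

    def test_unmasked_read_is_whole_run(self):
        read = make_read("A" * 550)
        assert nonrepetitive_eligible(read) == (True, (0, 550))

    def test_fully_masked_read(self):
        read = make_read("A" * 200, mask=[(0, 200)])
        assert nonrepetitive_eligible(read) == (False, None)


class TestScreenContaminants:
    def test_vector_substring_removed_random_kept(self):
        rng = np.random.default_rng(9)
        vector = RepeatElement("pBAC", "vector", random_dna(rng, 2000))
        inside = vector.consensus[300:800]
        reads = [make_read(inside, "c1_T7"), make_read(random_dna(rng, 500), "c2_T7")]
        kept, removed = screen_contaminants(reads, [vector], min_identity=0.9, min_cov=0.8)
        assert [r.read_id for r in removed] == ["c1_T7"]
        assert [r.read_id for r in kept] == ["c2_T7"]

    def test_chance_similarity_below_threshold_kept(self):
        rng = np.random.default_rng(10)
        vector = RepeatElement("pBAC", "vector", random_dna(rng, 1000))
        read = make_read(random_dna(rng, 400))
        assert sw_identity(read.bases, vector.consensus) < 0.9
        kept, removed = screen_contaminants([read], [vector], min_identity=0.9, min_cov=0.5)
        assert removed == []
        assert kept == [read]

    def test_empty_read_set(self):
        vector = RepeatElement("pBAC", "vector", "ACGT" * 100)
        assert screen_contaminants([], [vector]) == ([], [])


class TestCensus:
    @pytest.mark.parametrize("count,expected", [
        (0, CensusClass.LOW), (10, CensusClass.LOW), (11, CensusClass.MODERATE),
        (50, CensusClass.MODERATE), (51, CensusClass.HIGH),
    ])
    def test_bin_boundaries(self, count, expected):
        assert classify_hit_count(count) is expected

    def test_identical_triplet_counts_two_each(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 400)
        reads = [make_read(seq, f"c{i}_T7") for i in range(3)]
        results = self_hit_census(reads)
        assert [r.hit_count for r in results] == [2, 2, 2]
        assert all(r.census_class is CensusClass.LOW for r in results)

    def test_mutated_family_of_30_is_moderate(self):
        rng = np.random.default_rng(12)
        template = random_dna(rng, 300)
        reads = [
            make_read(random_dna(rng, 50) + mutate(rng, template, 0.04)
                      + random_dna(rng, 50), f"c{i}_T7")
            for i in range(30)
        ]
        results = self_hit_census(reads)
        assert all(r.hit_count == 29 for r in results)
        assert all(r.census_class is CensusClass.MODERATE for r in results)

    def test_only_unmasked_sequence_participates(self):
        rng = np.random.default_rng(13)
        shared = random_dna(rng, 300)
        r1 = make_read(shared + random_dna(rng, 100), "c1_T7", mask=[(0, 300)])
        r2 = make_read(shared + random_dna(rng, 100), "c2_T7", mask=[(0, 300)])
        results = self_hit_census([r1, r2])
        assert [r.hit_count for r in results] == [0, 0]


def test_evalue_decreases_with_score_and_scales_with_search_space():
    assert evalue_ungapped(40, 500, 500) < evalue_ungapped(30, 500, 500)
    assert evalue_ungapped(30, 500, 500) < evalue_ungapped(30, 5000, 5000)
    assert evalue_ungapped(30, 0, 500) == float("inf")
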