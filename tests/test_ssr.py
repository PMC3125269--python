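import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beskit.ssr import (
    SSRLocus,
    canonical_class,
    default_min_copies,
    find_tandem_repeats,
    flank_eligible,
    flank_sequences,
    summarize_ssrs,
)

from conftest import make_read, random_dna

RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(m):
    return "".join(RC[c] for c in reversed(m))


# ---------------------------------------------------------------------------
# independent brute-force enumerator for perfect tandem arrays


def brute_force_perfect(seq, max_period=3, min_length=12):
    """Enumerate every maximal perfect tandem array by direct window scan."""
    n = len(seq)
    cands = []
    for p in range(1, max_period + 1):
        for start in range(n - 2 * p + 1):
            if start > 0 and start - 1 + p < n and seq[start - 1] == seq[start - 1 + p]:
                continue  # left-extendable, not maximal
            run = 0
            while start + p + run < n and seq[start + run] == seq[start + p + run]:
                run += 1
            if run == 0:
                continue
            length = run + p
            motif = seq[start : start + p]
            primitive = all(
                motif != motif[:d] * (p // d) for d in range(1, p) if p % d == 0
            )
            if (length >= min_length and length / p >= default_min_copies(p)
                    and primitive and set(motif) <= set("ACGT")):
                cands.append((start, start + length, motif))
    # the documented overlap-resolution rule, implemented independently:
    # all perfect arrays tie on purity, so longer first, then leftmost/shortest period
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], len(c[2])))
    kept = []
    for c in cands:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in kept):
            kept.append(c)
    return sorted(kept)


class TestDetectorAgainstBruteForce:
    @pytest.mark.parametrize("alphabet,length,seed", [
        ("AC", 200, 0), ("AC", 600, 1), ("ACG", 400, 2), ("ACGT", 600, 3),
        ("AT", 300, 4), ("AC", 600, 5), ("ACG", 600, 6), ("AT", 600, 7),
    ])
    def test_random_strings(self, alphabet, length, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, length, alphabet)
        got = sorted((l.start, l.end, l.motif)
                     for l in find_tandem_repeats(seq, max_period=3,
                                                  max_mismatch_frac=0.0))
        assert got == brute_force_perfect(seq, max_period=3)

    def test_implanted_arrays(self):
        rng = np.random.default_rng(8)
        for trial in range(30):
            parts = [random_dna(rng, int(rng.integers(10, 60)))]
            for _ in range(int(rng.integers(1, 4))):
                motif = random_dna(rng, int(rng.integers(1, 4)))
                parts.append(motif * int(rng.integers(4, 15)))
                parts.append(random_dna(rng, int(rng.integers(10, 60))))
            seq = "".join(parts)[:600]
            got = sorted((l.start, l.end, l.motif)
                         for l in find_tandem_repeats(seq, max_period=3,
                                                      max_mismatch_frac=0.0))
            assert got == brute_force_perfect(seq, max_period=3)


class TestDetector:
    def test_simple_dimer(self):
        (locus,) = find_tandem_repeats("ACACACACACAC")
        assert (locus.start, locus.end, locus.motif, locus.copies) == (0, 12, "AC", 6.0)
        assert locus.purity == 1.0

    def test_tg_array_gets_tg_ca_class(self):
        (locus,) = find_tandem_repeats("TGTGTGTGTGTGTGTGTGTG")
        assert locus.canonical_class == canonical_class("TG") == canonical_class("CA")

    def test_single_substitution_bridged(self):
        (locus,) = find_tandem_repeats("ACACACACACATACACACACAC")
        assert (locus.start, locus.end, locus.motif) == (0, 22, "AC")
        assert locus.purity == pytest.approx(18 / 20)

    def test_out_of_phase_prefix_not_absorbed(self):
        (locus,) = find_tandem_repeats("TTTTACACACACACACGGG")
        assert (locus.start, locus.end, locus.motif) == (4, 16, "AC")

    def test_nonprimitive_periods_not_double_reported(self):
        loci = find_tandem_repeats("ACAC" * 6, max_period=10)
        assert [(l.period, l.start, l.end) for l in loci] == [(2, 0, 24)]

    def test_every_locus_satisfies_contract(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 5000, "ACGT")
        for l in find_tandem_repeats(seq, max_mismatch_frac=0.2):
            assert l.end - l.start >= 2 * l.period
            assert l.purity >= 0.8

    def test_recovery_of_implanted_perfect_loci(self):
        """Implanted perfect SSRs recovered with exact boundaries >=99%."""
        rng = np.random.default_rng(10)
        motifs = ["A", "AC", "TG", "GA", "AAT", "TCTG", "TCAAA", "ACGTAC",
                  "ACGTACG", "ACGGTCAT", "ACGTACGTA", "ACGTACGTAC"]
        total = exact = 0
        for i in range(400):
            motif = motifs[int(rng.integers(len(motifs)))]
            p = len(motif)
            copies = max(int(np.ceil(14 / p)), int(rng.integers(4, 12)))
            left = random_dna(rng, int(rng.integers(60, 150)))
            right = random_dna(rng, int(rng.integers(60, 150)))
            # sharpen implant boundaries so the array is maximal
            while len(left) >= p and left[-1] == (motif * copies)[p - 1 - (0) % p]:
                left = left[:-1] + ("G" if motif[p - 1] != "G" else "C")
                break
            seq = left + motif * copies + right
            start, end = len(left), len(left) + p * copies
            if seq[start - 1] == seq[start - 1 + p]:
                seq = seq[: start - 1] + _other(seq[start - 1 + p]) + seq[start:]
            if end + p <= len(seq) and seq[end] == seq[end - p]:
                seq = seq[:end] + _other(seq[end - p]) + seq[end + 1 :]
            loci = find_tandem_repeats(seq)
            total += 1
            if any((l.start, l.end) == (start, end) for l in loci):
                exact += 1
        assert exact / total >= 0.99


def _other(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


class TestCanonicalClass:
    @pytest.mark.parametrize("motif,expected", [
        ("GA", "GA/TC"), ("TC", "GA/TC"), ("AAC", "AAC/GTT"), ("AT", "AT/AT"),
        ("TA", "TA/TA"),
    ])
    def test_examples(self, motif, expected):
        assert canonical_class(motif) == expected

    def test_rotations_stay_distinct(self):
        # TG and AC are rotations of each other yet are separate classes
        assert canonical_class("TG") != canonical_class("AC")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=10))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_involution_under_reverse_complement(self, motif):
        assert canonical_class(revcomp(motif)) == canonical_class(motif)
        x, y = canonical_class(motif).split("/")
        assert revcomp(x) == y

    def test_rejects_bad_motifs(self):
        with pytest.raises(ValueError):
            canonical_class("ACN")
        with pytest.raises(ValueError):
            canonical_class("ACGTACGTACG")  # length 11


class TestFlankEligible:
    def _locus(self, start, end, motif="AC"):
        return SSRLocus("c_T7", start, end, motif, (end - start) / len(motif), 1.0)

    def test_clean_flanks_pass(self):
        read = make_read("A" * 200)
        assert flank_eligible(read, self._locus(60, 80)) is True

    def test_short_left_flank_fails(self):
        read = make_read("A" * 200)
        assert flank_eligible(read, self._locus(30, 50)) is False

    def test_masked_bases_do_not_count(self):
        read = make_read("A" * 200, mask=[(0, 10)])
        # 55 bp left of the locus, 10 of them masked -> 45 clean < 50
        assert flank_eligible(read, self._locus(55, 75)) is False

    def test_other_ssr_bases_do_not_count(self):
        read = make_read("A" * 250)
        other = self._locus(0, 30)
        assert flank_eligible(read, self._locus(60, 80), other_loci=[other]) is False

    def test_out_of_bounds_locus_errors(self):
        with pytest.raises(ValueError):
            flank_eligible(make_read("A" * 50), self._locus(40, 60))

    def test_flank_sequences_split_read(self):
        read = make_read("AAAA" + "ACACACAC" + "GGGG")
        left, right = flank_sequences(read, self._locus(4, 12))
        assert (left, right) == ("AAAA", "GGGG")


class TestSummarize:
    def _loci(self, spec):
        out, pos = [], 0
        for read_id, motif, count in spec:
            for _ in range(count):
                out.append(SSRLocus(read_id, pos, pos + 4 * len(motif), motif, 4.0, 1.0))
                pos += 100
        return out

    def test_counts_by_period_and_class(self):
        loci = self._loci([("r1_T7", "AC", 6), ("r2_T7", "GA", 4)])
        report = summarize_ssrs(loci, other_threshold=1)
        assert report.by_period["Dimer"] == {"AC/GT": 6, "GA/TC": 4}
        assert report.total == 10
        assert report.n_reads == 2

    def test_small_classes_roll_into_other(self):
        loci = self._loci([("r1_T7", "AC", 6), ("r1_T7", "AG", 2), ("r1_T7", "AT", 1)])
        report = summarize_ssrs(loci, other_threshold=5)
        assert report.by_period["Dimer"] == {"AC/GT": 6, "Other": 3}

    def test_empty_report(self):
        report = summarize_ssrs([])
        assert report.total == 0 and report.by_period == {}

    def test_eligible_counts(self):
        loci = self._loci([("r1_T7", "AC", 4)])
        report = summarize_ssrs(loci, eligible=loci[:2])
        assert report.eligible_count == 2
        assert report.eligible_count <= report.total

    def test_sampled_class_fractions_match_configuration(self):
        """Class fractions of a multinomial draw sit within 2 s.e. of the mix."""
        rng = np.random.default_rng(11)
        mix = {"TG": 0.5, "GA": 0.3, "AAT": 0.2}
        n = 2000
        draws = rng.choice(list(mix), size=n, p=list(mix.values()))
        loci = self._loci([(f"r{i}_T7", m, 1) for i, m in enumerate(draws)])
        report = summarize_ssrs(loci, other_threshold=1)
        from beskit.ssr import canonical_class as cc
        counts = {}
        for group in report.by_period.values():
            counts.update(group)
        for motif, frac in mix.items():
            se = (frac * (1 - frac) / n) ** 0.5
            assert abs(counts[cc(motif)] / n - frac) <= 2.5 * se
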