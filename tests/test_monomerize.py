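"""Read nomination, period detection, monomer extraction, digestion."""

import numpy as np
import pytest

from satdna import simulate as sim
from satdna.core import SeqRecord, reverse_complement
from satdna.monomerize import (DEFAULT_ENZYMES, Enzyme, detect_period,
                               digest, extract_monomers, ladder_unit,
                               nominate_reads)

HINFI = Enzyme("HinfI", "GANTC")


def random_dna(n: int, rng) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


class TestNominate:
    def test_tandem_read_score_matches_kmer_count(self):
        read = SeqRecord("r", "ACGT" * 50)
        ((_, score, flagged),) = nominate_reads([read], k=8, top_fraction=1.0)
        n_kmers = len(read.seq) - 8 + 1
        assert score == pytest.approx((n_kmers - 4) / n_kmers)
        assert flagged

    def test_random_read_scores_near_zero(self):
        rng = np.random.default_rng(0)
        read = SeqRecord("r", random_dna(300, rng))
        ((_, score, _),) = nominate_reads([read], k=11)
        assert score == 0.0

    def test_array_read_ranks_first(self, family40, small_genome):
        rng = np.random.default_rng(1)
        arr = small_genome.arrays["PIVE40S"]
        reads = [SeqRecord("sat", arr[:350])] + \
            [SeqRecord(f"bg{i}", random_dna(350, rng)) for i in range(9)]
        ranked = nominate_reads(reads, k=11, top_fraction=0.1)
        assert ranked[0][0].id == "sat" and ranked[0][2]

    def test_short_read_scores_zero(self):
        ranked = nominate_reads([SeqRecord("s", "ACGT")], k=8)
        assert ranked[0][1] == 0.0


class TestDetectPeriod:
    def test_exact_repeat(self):
        call = detect_period("ACGTA" * 20, p_min=3, p_max=60)
        assert (call.period, call.score) == (5, 1.0)
        assert 10 in call.harmonic_flags

    def test_no_period_on_random(self):
        rng = np.random.default_rng(2)
        call = detect_period(random_dna(300, rng), p_min=10, p_max=100,
                             threshold=0.6)
        assert call.period is None and not call.found

    @pytest.mark.parametrize("seed", range(5))
    def test_monomer_length_recovered_within_1bp(self, family40, seed):
        arr, _ = sim.simulate_array(family40, 10, seed=seed)
        call = detect_period(arr, p_min=10, p_max=120)
        assert call.period is not None
        assert abs(call.period - 43) <= 1

    def test_dimeric_hor_reports_base_monomer_with_harmonic(self, family40):
        arr, _ = sim.simulate_array(family40, 12, seed=0)
        call = detect_period(arr, p_min=10, p_max=120)
        assert call.period == 43
        assert 86 in call.harmonic_flags

    def test_reverse_complement_invariance(self, family40):
        arr, _ = sim.simulate_array(family40, 10, seed=1)
        fwd = detect_period(arr, p_min=10, p_max=120)
        rev = detect_period(reverse_complement(arr), p_min=10, p_max=120)
        assert fwd.period == rev.period


class TestExtractMonomers:
    CONS = "ACGTTGCAATCGGATCCTTAG"  # 21 bp

    def test_exact_copies(self):
        ms = extract_monomers(SeqRecord("r", self.CONS * 4), self.CONS)
        assert [m.ordinal for m in ms] == [0, 1, 2, 3]
        assert all(m.seq == self.CONS and m.completeness == 1.0
                   and m.strand == "+" for m in ms)

    def test_reverse_strand_normalized(self):
        read = SeqRecord("r", reverse_complement(self.CONS * 3))
        ms = extract_monomers(read, self.CONS)
        assert len(ms) == 3
        assert all(m.seq == self.CONS and m.strand == "-" for m in ms)

    def test_partial_flanks_get_fractional_completeness(self):
        read = SeqRecord("r", (self.CONS * 4)[7:-5])
        ms = extract_monomers(read, self.CONS)
        assert ms[0].completeness == pytest.approx(14 / 21, abs=0.01)
        assert ms[-1].completeness == pytest.approx(16 / 21, abs=0.01)
        assert all(m.completeness == 1.0 for m in ms[1:-1])

    def test_reconstruction_of_read(self):
        read = SeqRecord("r", (self.CONS * 5)[3:-2])
        ms = extract_monomers(read, self.CONS)
        assert "".join(m.seq for m in ms) == read.seq

    def test_non_family_read_rejected(self):
        rng = np.random.default_rng(3)
        assert extract_monomers(SeqRecord("r", random_dna(200, rng)),
                                "ACGTACGTTTGGCCAATGCC") == []

    def test_recovery_against_truth_table(self, family40, small_genome):
        lib = sim.LibrarySpec("m", 40, read_len_mean=300, read_len_sd=30,
                              error_rate=0.005, abundance={"PIVE40S": 1.0})
        reads, truth = sim.simulate_library(small_genome, lib, seed=21)
        n_true = n_found = 0
        for read in reads:
            ms = sorted(extract_monomers(read, family40.consensus),
                        key=lambda m: m.ordinal)
            tm = truth.monomers[(truth.monomers.read_id == read.id)
                                & truth.monomers.complete]
            n_true += len(tm)
            if not ms:
                continue
            # reconstruct boundaries in read coordinates from monomer sizes
            bounds, pos = [], 0
            for m in ms:
                bounds.append((pos, pos + len(m.seq), m.completeness))
                pos += len(m.seq)
            if ms[0].strand == "-":
                L = len(read.seq)
                bounds = [(L - b, L - a, c) for a, b, c in bounds]
            truth_iv = list(zip(tm.start, tm.end))
            n_found += sum(
                1 for a, b, c in bounds if c >= 0.95
                and any(abs(a - ta) <= 3 and abs(b - tb) <= 3
                        for ta, tb in truth_iv))
        assert n_true > 100
        assert n_found / n_true >= 0.95


class TestDigest:
    def test_no_site_single_fragment(self):
        res = digest("AAATTTCCCGGG", HINFI)
        assert res.fragments == [12] and res.cut_positions == []

    def test_two_sites(self):
        res = digest("AAAGACTCAAAGACTCAAAA", HINFI)
        assert res.cut_positions == [3, 11]
        assert res.fragments == [3, 8, 9]

    def test_fragment_conservation_on_random_sequences(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            seq = random_dna(int(rng.integers(10, 400)), rng)
            for enz in DEFAULT_ENZYMES:
                assert sum(digest(seq, enz).fragments) == len(seq)

    def test_array_digest_concentrates_at_monomer_multiples(self, family180):
        arr, _ = sim.simulate_array(family180, 40, seed=5)
        frags = digest(arr, HINFI).fragments
        near = [f for f in frags
                if min(abs(f - k * 177) for k in (1, 2, 3, 4)) <= 3]
        assert len(near) / len(frags) >= 0.8


class TestLadderUnit:
    def test_exact_multiples(self):
        assert ladder_unit([177, 354, 531, 177]) == (177, 1.0)

    def test_simulated_digest_recovers_monomer_length(self, family180):
        arr, _ = sim.simulate_array(family180, 40, seed=6)
        unit, support = ladder_unit(digest(arr, HINFI).fragments,
                                    u_min=50, u_max=400)
        assert unit is not None and abs(unit - 177) <= 3

    @pytest.mark.parametrize("seed", range(4))
    def test_random_fragments_no_ladder(self, seed):
        rng = np.random.default_rng(seed)
        unit, support = ladder_unit(list(rng.integers(30, 900, 30)))
        assert unit is None

    def test_needs_three_fragments(self):
        with pytest.raises(ValueError, match=">= 3"):
            ladder_unit([100, 200])
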