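"""Synthetic tandem-array generator: planting, calibration, determinism."""

import itertools

import numpy as np
import pytest
from scipy import stats

from satdna import simulate as sim
from satdna.core import at_content, iupac_match, reverse_complement
from satdna.align import pairwise_identity


def hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestMakeConsensus:
    def test_pure_at(self):
        spec = sim.FamilySpec("x", monomer_length=40, at_target=1.0)
        cons, _, _ = sim.make_consensus(spec, seed=0)
        assert set(cons) <= set("AT") and len(cons) == 40

    def test_exact_at_composition(self):
        spec = sim.FamilySpec("x", monomer_length=43, at_target=0.605)
        cons, _, _ = sim.make_consensus(spec, seed=3)
        assert at_content(cons) == pytest.approx(26 / 43)

    def test_direct_and_inverted_motif_planting(self):
        spec = sim.FamilySpec(
            "x", monomer_length=43,
            motif_plan=(sim.MotifPlan("inverted", 9, 2, 1.0),))
        cons, coords, _ = sim.make_consensus(spec, seed=1)
        (k1, a1, b1), (k2, a2, b2) = coords
        assert cons[a2:b2] == reverse_complement(cons[a1:b1])

    def test_motif_identity_target(self):
        spec = sim.FamilySpec(
            "x", monomer_length=178,
            motif_plan=(sim.MotifPlan("direct", 23, 2, 0.696),))
        cons, coords, _ = sim.make_consensus(spec, seed=2)
        (_, a1, b1), (_, a2, b2) = coords
        ident = hamming_identity(cons[a1:b1], cons[a2:b2])
        assert ident == pytest.approx(16 / 23)  # round((1-0.696)*23)=7 muts

    def test_planted_site_is_unique(self):
        spec = sim.pive180_like()
        cons, _, sites = sim.make_consensus(spec, seed=4)
        (enz, start, sseq) = sites[0]
        matches = [i for i in range(len(cons) - 4)
                   if iupac_match("GANTC", cons[i:i + 5])]
        assert matches == [start]

    def test_overfull_motif_plan_rejected(self):
        spec = sim.FamilySpec(
            "x", monomer_length=20,
            motif_plan=(sim.MotifPlan("direct", 9, 2, 1.0),
                        sim.MotifPlan("direct", 8, 2, 1.0)))
        with pytest.raises(ValueError, match="pack"):
            sim.make_consensus(spec, seed=0)


class TestCalibration:
    def test_within_identity_closed_form_vs_monte_carlo(self):
        # planted per-site rate q: expected pairwise identity (1-q)^2 + q^2/3
        q = 0.05
        expected = sim.expected_pairwise_identity(q)
        assert expected == pytest.approx((1 - 0.05) ** 2 + 0.05 ** 2 / 3)
        spec = sim.FamilySpec("x", monomer_length=200,
                              within_class_divergence=q)
        fam = sim.build_family(spec, seed=0)
        copies = [s for s, *_ in sim.sample_monomers(fam, 30, seed=1)]
        idents = [hamming_identity(a, b)
                  for a, b in itertools.combinations(copies, 2)]  # 435 pairs
        assert np.mean(idents) == pytest.approx(expected, abs=0.02)

    def test_hor_calibration_hits_identity_targets(self):
        q, d = sim.calibrate_hor(0.89, 0.685)
        spec = sim.FamilySpec("x", monomer_length=177, hor_order=2,
                              within_class_divergence=q,
                              between_class_divergence=d)
        fam = sim.build_family(spec, seed=0)
        draws = sim.sample_monomers(fam, 60, seed=2)
        within, between = [], []
        for (s1, c1, *_), (s2, c2, *_) in itertools.combinations(draws, 2):
            (within if c1 == c2 else between).append(hamming_identity(s1, s2))
        assert np.mean(within) == pytest.approx(0.89, abs=0.02)
        assert np.mean(between) == pytest.approx(0.685, abs=0.02)

    def test_heterogeneous_columns_give_monomorphic_fraction(self):
        spec = sim.pive180_like()
        fam = sim.build_family(spec, seed=0)
        seqs = [s for s, *_ in sim.sample_monomers(fam, 131, seed=1)]
        arr = np.array([list(s) for s in seqs])
        mono = np.mean([len(set(arr[:, j])) == 1
                        for j in range(arr.shape[1])])
        assert mono == pytest.approx(0.5311, abs=0.02)


class TestSimulateArray:
    def test_zero_divergence_gives_exact_copies(self):
        spec = sim.FamilySpec("x", monomer_length=30)
        fam = sim.build_family(spec, seed=0)
        arr, truth = sim.simulate_array(fam, 5, seed=1)
        assert arr == fam.consensus * 5
        assert len(truth) == 5

    def test_truth_tiles_array_exactly(self, family40):
        arr, truth = sim.simulate_array(family40, 50, seed=2)
        assert truth.start.iloc[0] == 0
        assert truth.end.iloc[-1] == len(arr)
        assert (truth.start.values[1:] == truth.end.values[:-1]).all()

    def test_hor_classes_alternate(self, family40):
        _, truth = sim.simulate_array(family40, 20, seed=3)
        assert (truth.class_idx.values == np.arange(20) % 2).all()

    def test_site_intact_fraction(self, family180):
        arr, truth = sim.simulate_array(family180, 300, seed=4)
        _, start, _ = family180.site_coords[0]
        intact = [iupac_match("GANTC", arr[s + start:s + start + 5])
                  for s in truth.start]
        # binomial(300, 0.7): 3 sigma ~ 0.08
        assert np.mean(intact) == pytest.approx(0.70, abs=0.08)


class TestSimulateLibrary:
    def test_same_seed_identical_output(self, small_genome):
        lib = sim.LibrarySpec("male", 300, abundance={"PIVE40S": 0.1})
        r1, t1 = sim.simulate_library(small_genome, lib, seed=9)
        r2, t2 = sim.simulate_library(small_genome, lib, seed=9)
        assert [x.seq for x in r1] == [x.seq for x in r2]
        assert t1.reads.equals(t2.reads) and t1.monomers.equals(t2.monomers)

    def test_error_free_reads_are_substrings_of_source(self, small_genome):
        lib = sim.LibrarySpec("male", 200, error_rate=0.0,
                              abundance={"PIVE40S": 0.3})
        reads, truth = sim.simulate_library(small_genome, lib, seed=10)
        sources = {"PIVE40S": small_genome.arrays["PIVE40S"],
                   "background": small_genome.background}
        for rec, row in zip(reads, truth.reads.itertuples()):
            src = sources[row.family]
            assert rec.seq in src or reverse_complement(rec.seq) in src

    def test_abundance_within_binomial_ci(self, small_genome):
        target = 0.0393
        lib = sim.LibrarySpec("male", 10_000, abundance={"PIVE40S": target})
        _, truth = sim.simulate_library(small_genome, lib, seed=11)
        hits = (truth.reads.family == "PIVE40S").sum()
        lo, hi = stats.binom.interval(0.99, 10_000, target)
        assert lo <= hits <= hi

    def test_monomer_truth_boundaries_inside_reads(self, small_genome):
        lib = sim.LibrarySpec("f", 300, abundance={"PIVE40S": 0.5})
        reads, truth = sim.simulate_library(small_genome, lib, seed=12)
        lengths = {r.id: len(r.seq) for r in reads}
        m = truth.monomers
        assert (m.start >= 0).all()
        assert all(m.end.values <= [lengths[r] for r in m.read_id])
        assert (m.start < m.end).all()


def test_fixed_difference_planting(family180):
    variant, col = sim.plant_fixed_difference(family180)
    assert family180.consensus[col] != variant.consensus[col]
    diff = [i for i, (a, b) in enumerate(
        zip(family180.consensus, variant.consensus)) if a != b]
    assert diff == [col]
    assert not family180.mutable_mask[col]


def test_study_library_specs_scaling():
    male, female = sim.study_library_specs(scale=0.5)
    assert (male.n_reads, female.n_reads) == (52638, 41072)
    assert male.abundance["PIVE40S"] == 0.0393
    assert female.abundance["PIVE180S"] == 0.0305
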