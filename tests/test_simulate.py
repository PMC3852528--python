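"""Simulator: element anatomy, planting truth, read sampling."""

import numpy as np
import pytest

import repeatscope as rs
from repeatscope.simulate import mutate


class TestRepeatLibrary:
    def test_ltr_anatomy_prefix_equals_suffix(self):
        cfg = rs.SimulationConfig(
            genome_length=100_000, seed=3,
            families=[rs.RepeatFamilySpec("f1", "LTR-Gypsy", full_copies=1,
                                          ltr_length=300, internal_length=4000)],
        )
        lib = rs.build_repeat_library(cfg)
        seq = lib["f1"]
        assert len(seq) == 4600
        assert seq[:300] == seq[-300:]

    def test_mite_has_terminal_inverted_repeat(self):
        cfg = rs.SimulationConfig(
            genome_length=100_000, seed=3,
            families=[rs.RepeatFamilySpec("m1", "MITE", full_copies=1, element_length=350)],
        )
        seq = rs.build_repeat_library(cfg)["m1"]
        assert len(seq) == 350
        assert seq[-15:] == rs.revcomp(seq[:15])

    def test_same_seed_same_library(self):
        cfg = rs.SimulationConfig(
            genome_length=100_000, seed=11,
            families=[rs.RepeatFamilySpec("f1", "LTR-Copia", full_copies=2,
                                          ltr_length=200, internal_length=1000),
                      rs.RepeatFamilySpec("d1", "CACTA", full_copies=3, element_length=800)],
        )
        assert rs.build_repeat_library(cfg) == rs.build_repeat_library(cfg)

    @pytest.mark.parametrize("bad", [
        dict(class_label="LTR-Gypsy", ltr_length=30, internal_length=4000),
        dict(class_label="LTR-Gypsy", ltr_length=300, internal_length=100),
        dict(class_label="CACTA", element_length=500, solo_ltr_copies=3),
        dict(class_label="CACTA", element_length=0),
    ])
    def test_invalid_family_specs_rejected(self, bad):
        spec = rs.RepeatFamilySpec("bad", full_copies=1, **bad)
        cfg = rs.SimulationConfig(genome_length=10_000, seed=0, families=[spec])
        with pytest.raises(ValueError):
            rs.build_repeat_library(cfg)


class TestPlantGenome:
    def test_instance_counts_by_kind(self, small_config, small_truth):
        _lib, truth = small_truth
        kinds = {}
        for inst in truth.instances:
            kinds[(inst.family_id, inst.kind)] = kinds.get((inst.family_id, inst.kind), 0) + 1
        assert kinds[("gA", "full")] == 10
        assert kinds[("gA", "solo_ltr")] == 5
        assert kinds[("mA", "full")] == 20
        assert sum(v for (f, k), v in kinds.items() if k == "gene") == 4
        assert sum(v for (f, k), v in kinds.items() if k == "tandem") == 3

    def test_zero_divergence_copies_identical_to_canonical(self):
        cfg = rs.SimulationConfig(
            genome_length=60_000, seed=5,
            families=[rs.RepeatFamilySpec("f1", "LTR-Gypsy", full_copies=5,
                                          ltr_length=100, internal_length=500,
                                          divergence=0.0)],
        )
        lib = rs.build_repeat_library(cfg)
        truth = rs.plant_genome(lib, cfg)
        for inst in truth.instances:
            if inst.kind == "full":
                assert truth.genome_sequence[inst.start : inst.end] == lib["f1"]

    def test_divergence_hamming_distance_in_binomial_band(self):
        # 20 solo LTR copies of a 300 nt LTR at 5% divergence: total
        # substituted sites ~ Binomial(6000, 0.05); 99% band via the
        # normal approximation around 300 +/- 2.58 * sqrt(n p (1-p))
        cfg = rs.SimulationConfig(
            genome_length=120_000, seed=9,
            families=[rs.RepeatFamilySpec("f1", "LTR-Gypsy", full_copies=1,
                                          ltr_length=300, internal_length=500,
                                          solo_ltr_copies=20, divergence=0.05)],
        )
        lib = rs.build_repeat_library(cfg)
        truth = rs.plant_genome(lib, cfg)
        canonical_ltr = lib["f1"][:300]
        total = 0
        n_sites = 0
        for inst in truth.instances:
            if inst.kind != "solo_ltr":
                continue
            copy = truth.genome_sequence[inst.start : inst.end]
            total += sum(a != b for a, b in zip(copy, canonical_ltr))
            n_sites += 300
        mean = 0.05 * n_sites
        sd = np.sqrt(n_sites * 0.05 * 0.95)
        assert abs(total - mean) < 2.58 * sd

    def test_instances_non_overlapping_and_in_bounds(self, small_truth):
        _lib, truth = small_truth
        ordered = sorted(truth.instances, key=lambda i: i.start)
        prev_end = 0
        for inst in ordered:
            assert 0 <= inst.start < inst.end <= len(truth.genome_sequence)
            assert inst.start >= prev_end
            prev_end = inst.end

    def test_per_base_class_covers_every_position(self, small_truth):
        _lib, truth = small_truth
        arr = truth.per_base_class()
        assert arr.size == len(truth.genome_sequence)
        fractions = truth.class_genome_fractions()
        assert abs(sum(fractions.values()) - 1.0) < 1e-9

    def test_overfull_genome_rejected(self):
        cfg = rs.SimulationConfig(
            genome_length=5_000, seed=0,
            families=[rs.RepeatFamilySpec("f1", "CACTA", full_copies=10, element_length=1000)],
        )
        lib = rs.build_repeat_library(cfg)
        with pytest.raises(ValueError):
            rs.plant_genome(lib, cfg)


class TestSimulateReads:
    def test_read_count_matches_coverage_arithmetic(self):
        cfg = rs.SimulationConfig(genome_length=1_000_000, seed=1)
        truth = rs.plant_genome(rs.build_repeat_library(cfg), cfg)
        profile = rs.ReadProfile("il", length=101)
        reads = rs.simulate_reads(truth, profile, 0.86, 2)
        assert abs(len(reads) - int(np.ceil(0.86 * 1_000_000 / 101))) <= 1

    def test_coverage_conservation(self, small_truth):
        _lib, truth = small_truth
        profile = rs.ReadProfile("v", length_mean=180.0, length_sd=40.0, min_length=50)
        reads = rs.simulate_reads(truth, profile, 0.5, 3)
        total = sum(len(r) for r in reads)
        target = 0.5 * len(truth.genome_sequence)
        assert abs(total - target) / target < 0.01

    def test_error_free_reads_are_exact_substrings(self, small_truth):
        _lib, truth = small_truth
        profile = rs.ReadProfile("clean", length=101)
        reads = rs.simulate_reads(truth, profile, 0.2, 4)
        for read in reads:
            source, start, end, strand = read.origin
            src = truth.genome_sequence if source == "nuclear" else truth.organellar_sequence
            fragment = src[start:end]
            expect = fragment if strand == "+" else rs.revcomp(fragment)
            assert read.sequence == expect

    def test_organellar_fraction_in_binomial_band(self):
        cfg = rs.SimulationConfig(genome_length=1_000_000, seed=6,
                                  organellar_length=20_000, organellar_read_fraction=0.09)
        truth = rs.plant_genome(rs.build_repeat_library(cfg), cfg)
        profile = rs.ReadProfile("il", length=101)
        reads = rs.simulate_reads(truth, profile, 13.13, 8)
        n = len(reads)
        organellar = sum(r.origin[0] == "organellar" for r in reads)
        mean, sd = 0.09 * n, np.sqrt(n * 0.09 * 0.91)
        assert abs(organellar - mean) < 2.58 * sd

    def test_same_seed_identical_reads(self, small_truth):
        _lib, truth = small_truth
        profile = rs.ReadProfile("e", length=101, substitution_rate=0.01, indel_rate=0.002)
        a = rs.simulate_reads(truth, profile, 0.3, 5)
        b = rs.simulate_reads(truth, profile, 0.3, 5)
        assert [(r.read_id, r.sequence, r.origin) for r in a] == \
               [(r.read_id, r.sequence, r.origin) for r in b]


class TestExpectedSoloLtrRatio:
    @pytest.mark.parametrize("full,solo,expected", [(10, 0, 2.0), (10, 5, 2.5), (4, 18, 6.5)])
    def test_closed_form(self, full, solo, expected):
        spec = rs.RepeatFamilySpec("f", "LTR-Gypsy", full_copies=full, ltr_length=300,
                                   internal_length=4000, solo_ltr_copies=solo)
        assert rs.expected_solo_ltr_ratio(spec) == expected

    def test_planted_base_copy_counts_match_closed_form(self):
        # independent oracle: count LTR vs internal base copies directly
        # from the planted truth intervals
        spec = rs.RepeatFamilySpec("f1", "LTR-Gypsy", full_copies=4, ltr_length=100,
                                   internal_length=300, solo_ltr_copies=18)
        cfg = rs.SimulationConfig(genome_length=60_000, seed=2, families=[spec])
        truth = rs.plant_genome(rs.build_repeat_library(cfg), cfg)
        ltr_bases = sum(i.end - i.start for i in truth.instances if i.kind == "solo_ltr")
        ltr_bases += sum(2 * 100 for i in truth.instances if i.kind == "full")
        internal_bases = sum(300 for i in truth.instances if i.kind == "full")
        oracle = (ltr_bases / 100) / (internal_bases / 300)
        assert oracle == rs.expected_solo_ltr_ratio(spec) == 6.5

    def test_errors(self):
        non_ltr = rs.RepeatFamilySpec("d", "CACTA", full_copies=3, element_length=500)
        with pytest.raises(ValueError):
            rs.expected_solo_ltr_ratio(non_ltr)
        empty = rs.RepeatFamilySpec("f", "LTR-Copia", full_copies=0, ltr_length=100,
                                    internal_length=300)
        with pytest.raises(ValueError):
            rs.expected_solo_ltr_ratio(empty)


def test_same_config_same_seed_byte_identical_outputs(small_config):
    lib1 = rs.build_repeat_library(small_config)
    lib2 = rs.build_repeat_library(small_config)
    t1 = rs.plant_genome(lib1, small_config)
    t2 = rs.plant_genome(lib2, small_config)
    assert t1.genome_sequence == t2.genome_sequence
    assert t1.organellar_sequence == t2.organellar_sequence
    assert [(i.family_id, i.start, i.end, i.kind) for i in t1.instances] == \
           [(i.family_id, i.start, i.end, i.kind) for i in t2.instances]


def test_mutate_rate_zero_and_bounds():
    rng = np.random.default_rng(0)
    seq = "ACGT" * 50
    assert mutate(seq, 0.0, rng) == seq
    out = mutate(seq, 0.3, rng)
    assert len(out) == len(seq)
    assert set(out) <= set("ACGT")
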