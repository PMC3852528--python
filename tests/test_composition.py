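"""Composition tables, class ratios and the LTR / inter-LTR analysis,
cross-checked against the published sunflower survey values."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import repeatscope as rs
from repeatscope import datasets as ds
from repeatscope.composition import round_half_up
from repeatscope.core import Placement


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (0.005, 2, 0.01), (2.555, 2, 2.56), (2.2924, 1, 2.3), (52.1322, 2, 52.13),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestCompositionArithmetic:
    def test_published_survey_top_level_percentages(self):
        counts = {
            "Repeated": ds.SUNFLOWER_READ_COUNTS["repeated"],
            "Unique or low redundant": ds.SUNFLOWER_READ_COUNTS["unique_or_low_redundant"],
        }
        table = rs.composition_table(
            counts, ds.SUNFLOWER_TOTAL_NUCLEAR, ds.SUNFLOWER_READ_COUNTS["organellar"]
        )
        assert table.pct_of_total("Repeated") == 52.13
        assert table.pct_of_matched("Repeated") == 80.92
        assert table.pct_of_total("Unique or low redundant") == 12.29
        assert table.pct_of_matched("Unique or low redundant") == 19.08
        assert table.matched_total == 76_447_216
        assert round_half_up(100 * table.matched_total / table.total_nuclear) == 64.42
        assert table.total_reads == ds.SUNFLOWER_TOTAL_READS

    def test_published_class_breakdown_percentages(self):
        # class percentages in the survey's breakdown are relative to the
        # matched-read total (76,447,216)
        counts = ds.SUNFLOWER_CLASS_READ_COUNTS
        matched = ds.SUNFLOWER_READ_COUNTS["repeated"] + \
            ds.SUNFLOWER_READ_COUNTS["unique_or_low_redundant"]
        assert matched == 76_447_216
        gypsy = counts["Retrotransposons / LTR-Gypsy"]
        assert round_half_up(100 * gypsy / matched) == 49.22
        retro = sum(v for k, v in counts.items() if k.startswith("Retrotransposons"))
        assert retro == ds.SUNFLOWER_RETRO_SUBCLASS_TOTAL == 60_797_746
        assert round_half_up(100 * retro / matched) == 79.53

    def test_single_class_is_hundred_percent_of_matched(self):
        table = rs.composition_table({"only": 50}, 100, 0)
        assert table.pct_of_matched("only") == 100.0

    def test_accounting_violation_raises(self):
        with pytest.raises(ValueError):
            rs.composition_table({"a": 200}, 100, 0)

    def test_by_class_tally_and_identity(self):
        placements = [Placement(f"r{i}", "rep1", 0, 50, "+", 50, 1.0) for i in range(6)]
        placements += [Placement(f"s{i}", "low1", 0, 50, "+", 50, 1.0) for i in range(2)]
        table = rs.composition_by_class(placements, ["rep1"], {"rep1": "LTR-Gypsy"},
                                        total_nuclear=10, organellar=3)
        assert table.count("LTR-Gypsy") == 6
        assert table.count("Unique or low redundant") == 2
        assert table.matched_total + table.unmatched == table.total_nuclear
        assert table.matched_total + table.unmatched + table.organellar == 13

    def test_missing_annotation_for_repeated_contig_raises(self):
        placements = [Placement("r0", "rep1", 0, 50, "+", 50, 1.0)]
        with pytest.raises(ValueError):
            rs.composition_by_class(placements, ["rep1"], {}, 10, 0)


class TestClassRatio:
    def test_published_abundance_ratios(self):
        counts = ds.SUNFLOWER_CLASS_READ_COUNTS
        assert rs.class_ratio(counts["Retrotransposons / LTR-Gypsy"],
                              counts["Retrotransposons / LTR-Copia"]) == 2.56
        assert rs.class_ratio(ds.SUNFLOWER_DB_GYPSY_COUNT,
                              ds.SUNFLOWER_DB_COPIA_COUNT, decimals=1) == 2.3

    def test_identity_and_zero_denominator(self):
        assert rs.class_ratio(123, 123) == 1.0
        with pytest.raises(ZeroDivisionError):
            rs.class_ratio(1, 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=10**7), st.integers(min_value=1, max_value=10**7))
    def test_ratio_antisymmetry_within_rounding(self, a, b):
        fwd = rs.class_ratio(a, b, decimals=6)
        rev = rs.class_ratio(b, a, decimals=6)
        # rounding the smaller ratio to 6 decimals bounds the product error
        tol = 1e-6 * (max(a, b) / min(a, b)) + 1e-9
        assert abs(fwd * rev - 1.0) <= tol


class TestRepeatDatabaseBookkeeping:
    def test_low_copy_count_is_difference(self):
        assert ds.SUNFLOWER_WGSAS_SIZE - ds.SUNFLOWER_REPEAT_DB_SIZE \
            == ds.SUNFLOWER_LOW_COPY_SIZE == 235_876

    def test_largest_family_share(self):
        pct = round_half_up(
            100 * ds.SUNFLOWER_LARGEST_FAMILY_SIZE / ds.SUNFLOWER_REPEAT_DB_SIZE
        )
        assert pct == 0.20

    def test_threshold_from_reference_gene_coverage(self):
        assert ds.SUNFLOWER_REFERENCE_GENE_MEAN_COVERAGE * ds.SUNFLOWER_THRESHOLD_MULTIPLIER \
            == pytest.approx(33.0)


class TestLtrInterLtrRatios:
    def test_all_published_ratios_reproduced(self):
        for rec, printed in zip(ds.SUNFLOWER_LTR_COVERAGE_RECORDS,
                                ds.SUNFLOWER_LTR_PRINTED_RATIOS):
            assert round_half_up(rec.ratio) == printed, rec.element_id

    def test_spot_ratios(self):
        by_id = {r.element_id: r for r in ds.SUNFLOWER_LTR_COVERAGE_RECORDS}
        assert round_half_up(by_id["DESRLC1"].ratio) == 1.25
        assert round_half_up(by_id["LTPRLG2"].ratio) == 6.58

    def test_solo_flag_count(self):
        flags = sum(r.solo_ltr_flag for r in ds.SUNFLOWER_LTR_COVERAGE_RECORDS)
        assert flags == 9  # 9 of 19 elements show the solo-LTR signal

    def test_group_and_overall_means_over_unrounded_ratios(self):
        group_means, overall = rs.ratio_means(ds.SUNFLOWER_LTR_COVERAGE_RECORDS)
        assert group_means == {"Copia": 1.36, "Gypsy": 3.62, "Unknown": 1.23}
        assert overall == 2.27
        # independent mean oracle over the printed coverage pairs
        ratios = [r.ltr_avg_cov / r.internal_avg_cov
                  for r in ds.SUNFLOWER_LTR_COVERAGE_RECORDS]
        assert round_half_up(sum(ratios) / len(ratios)) == 2.27

    def test_means_over_rounded_ratios_would_differ(self):
        # the printed group means only come out when the *unrounded* ratios
        # are averaged; averaging the printed (rounded) ratios drifts
        copia = [r for r in ds.SUNFLOWER_LTR_COVERAGE_RECORDS if r.superfamily == "Copia"]
        rounded_mean = sum(round_half_up(r.ratio) for r in copia) / len(copia)
        unrounded_mean = sum(r.ratio for r in copia) / len(copia)
        assert round_half_up(unrounded_mean) == 1.36
        assert abs(rounded_mean - unrounded_mean) > 1e-4


class TestLtrRatioFromPlacements:
    def _element(self):
        return rs.LTRElementModel(
            element_id="e1", superfamily="Gypsy",
            ltr_intervals=((0, 100), (500, 600)), internal_interval=(100, 500),
        )

    def test_uniform_coverage_gives_ratio_two(self):
        # one read per position at depth 1 everywhere: both LTRs pooled
        # over a single LTR length doubles the LTR coverage
        placements = [Placement(f"r{i}", "e1", s, s + 50, "+", 50, 1.0)
                      for i, s in enumerate(range(0, 551, 50))]
        rec = rs.ltr_inter_ltr_ratio(self._element(), placements, 600)
        assert rec.ratio == pytest.approx(2.0)
        assert not rec.solo_ltr_flag  # strict inequality at exactly 2

    def test_extra_ltr_coverage_flags_solo(self):
        placements = [Placement(f"r{i}", "e1", s, s + 50, "+", 50, 1.0)
                      for i, s in enumerate(range(0, 551, 50))]
        placements += [Placement(f"x{i}", "e1", 0, 100, "+", 100, 1.0) for i in range(3)]
        rec = rs.ltr_inter_ltr_ratio(self._element(), placements, 600)
        assert rec.ratio > 2.0 and rec.solo_ltr_flag

    def test_zero_internal_coverage_infinite_sentinel(self):
        placements = [Placement("r0", "e1", 0, 100, "+", 100, 1.0)]
        rec = rs.ltr_inter_ltr_ratio(self._element(), placements, 600)
        assert math.isinf(rec.ratio) and rec.solo_ltr_flag
        group_means, overall = rs.ratio_means([rec])
        assert group_means == {} and overall is None

    def test_invalid_interval_order_rejected(self):
        bad = rs.LTRElementModel("e1", "Gypsy", ((0, 100), (90, 190)), (100, 90))
        with pytest.raises(ValueError):
            rs.ltr_inter_ltr_ratio(bad, [], 200)


class TestRatioMeans:
    def test_single_and_pair(self):
        recs = [rs.LTRRatioRecord("a", "Gypsy", 2.0, 2.0),
                rs.LTRRatioRecord("b", "Gypsy", 6.0, 2.0)]
        group_means, overall = rs.ratio_means(recs)
        assert group_means == {"Gypsy": 2.0}
        assert overall == 2.0


class TestSoloLtrRecovery:
    def test_join_with_closed_form(self):
        spec = rs.RepeatFamilySpec("f1", "LTR-Gypsy", full_copies=10, ltr_length=300,
                                   internal_length=2000, solo_ltr_copies=10)
        rec = rs.LTRRatioRecord("f1", "Gypsy", 120.0, 41.0)
        [(fid, expected, observed, err)] = rs.solo_ltr_recovery([spec], [rec])
        assert fid == "f1" and expected == 3.0
        assert observed == pytest.approx(120.0 / 41.0)
        assert err == pytest.approx(abs(observed - 3.0))

    def test_empty_records_empty_report(self):
        spec = rs.RepeatFamilySpec("f1", "LTR-Gypsy", full_copies=1, ltr_length=300,
                                   internal_length=2000)
        assert rs.solo_ltr_recovery([spec], []) == []
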