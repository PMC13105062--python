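"""Region collapse, direct/indirect classification, site counting, association."""

import numpy as np
import pandas as pd
import pytest

from snaparray.regions import (
    classify_region,
    collapse_to_regions,
    count_distinct_sites,
    differential_association,
    indirect_fraction,
    indirect_fraction_from_counts,
)

from conftest import truth_by_locus


def _probes(intervals, intensities=None, chrom="chr1"):
    n = len(intervals)
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": [chrom] * n,
        "start": [a for a, _ in intervals],
        "end": [b for _, b in intervals],
        "intensity": intensities if intensities is not None else np.ones(n),
    })


class TestCollapse:
    def test_overlapping_probes_merge(self):
        regions = collapse_to_regions(_probes([(0, 48), (6, 54)]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 54)

    def test_disjoint_probes_stay_separate(self):
        regions = collapse_to_regions(_probes([(0, 48), (100, 148)]))
        assert len(regions) == 2

    def test_abutting_probes_not_merged(self):
        regions = collapse_to_regions(_probes([(0, 48), (48, 96)]))
        assert len(regions) == 2

    def test_tiling_chain_union_span(self):
        intervals = [(6 * i, 6 * i + 48) for i in range(10)]
        regions = collapse_to_regions(_probes(intervals))
        assert len(regions) == 1
        assert regions[0].end - regions[0].start == 48 + 9 * 6
        assert len(regions[0].probe_ids) == 10

    def test_max_intensity_recorded(self):
        regions = collapse_to_regions(_probes([(0, 48), (6, 54)], [1.5, 7.0]))
        assert regions[0].max_intensity == 7.0

    def test_probes_without_coordinates_excluded(self, caplog):
        df = _probes([(0, 48)])
        df.loc[len(df)] = {"probe_id": "ctrl", "chrom": None, "start": None,
                           "end": None, "intensity": 2.0}
        regions = collapse_to_regions(df)
        assert len(regions) == 1 and regions[0].probe_ids == ["p0"]


class TestClassify:
    @pytest.mark.parametrize("max_i,expected", [(5.2, "direct"),
                                                (3.0, "indirect"),
                                                (0.9, "indirect")])
    def test_strict_threshold(self, max_i, expected):
        (region,) = collapse_to_regions(_probes([(0, 48)], [max_i]))
        assert classify_region(region) == expected

    def test_monotone_in_threshold(self):
        (region,) = collapse_to_regions(_probes([(0, 48)], [4.0]))
        classes = [classify_region(region, t) for t in (1.0, 3.0, 3.9999, 4.0, 10.0)]
        # once indirect at some threshold, stays indirect at higher ones
        flipped = [c == "indirect" for c in classes]
        assert flipped == sorted(flipped)


class TestSiteCounting:
    def _region(self, intensities):
        intervals = [(6 * i, 6 * i + 48) for i in range(len(intensities))]
        probes = _probes(intervals, intensities)
        (region,) = collapse_to_regions(probes)
        return region, probes

    def test_two_separated_runs(self):
        region, probes = self._region([1, 1, 9, 8, 1, 1, 7, 1])
        assert count_distinct_sites(region, probes, threshold=3.0) == 2

    def test_all_below_threshold(self):
        region, probes = self._region([1, 2, 1])
        assert count_distinct_sites(region, probes) == 0

    def test_all_above_threshold(self):
        region, probes = self._region([9, 9, 9, 9])
        assert count_distinct_sites(region, probes) == 1


class TestDifferentialAssociation:
    def _regions_with_flags(self, flags, chrom="chr1", offset=0):
        probes = _probes([(offset + 1000 * i, offset + 1000 * i + 48)
                          for i in range(len(flags))], chrom=chrom)
        return collapse_to_regions(probes)

    def test_independence_gives_zero_statistic(self):
        direct = self._regions_with_flags([True] * 100)
        indirect = self._regions_with_flags([True] * 100, offset=500_000)
        seqs = {}
        for i, r in enumerate(direct + indirect):
            seqs[r.region_id] = "AGGTCA" + "T" * 42 if i % 2 == 0 else "T" * 48
        res = differential_association(direct, indirect, pattern="RGGTCA",
                                       sequences=seqs, feature_name="era")
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_computed_contingency(self):
        # [[30,10],[10,30]]: all expected cells 20, sum (O-E)^2/E = 20
        direct = self._regions_with_flags([True] * 40)
        indirect = self._regions_with_flags([True] * 40, offset=500_000)
        seqs = {}
        for i, r in enumerate(direct):
            seqs[r.region_id] = ("AGGTCA" + "T" * 42) if i < 30 else "T" * 48
        for i, r in enumerate(indirect):
            seqs[r.region_id] = ("AGGTCA" + "T" * 42) if i < 10 else "T" * 48
        res = differential_association(direct, indirect, pattern="RGGTCA",
                                       sequences=seqs, feature_name="era")
        np.testing.assert_array_equal(res["table"], [[30, 10], [10, 30]])
        assert res["chi2"] == pytest.approx(20.0)
        assert res["p_value"] < 0.05

    def test_peak_overlap_flags(self):
        direct = self._regions_with_flags([True] * 2)
        indirect = self._regions_with_flags([True] * 2, offset=500_000)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        res = differential_association(direct, indirect, peaks=peaks,
                                       feature_name="chip")
        assert res["table"][0].tolist() == [1, 1]
        assert res["table"][1].tolist() == [0, 2]
        assert res["low_expected"]  # tiny table triggers the exact-test advice

    def test_empty_class_rejected(self):
        direct = self._regions_with_flags([True])
        with pytest.raises(ValueError):
            differential_association(direct, [], pattern="RGGTCA", sequences={})


class TestIndirectFraction:
    def test_published_scale_arithmetic(self):
        assert indirect_fraction_from_counts(1585, 6151) == 25.8

    def test_degenerate_cases(self):
        assert indirect_fraction_from_counts(0, 10) == 0.0
        assert indirect_fraction_from_counts(10, 10) == 100.0
        with pytest.raises(ValueError):
            indirect_fraction_from_counts(0, 0)


def test_classification_recovers_simulated_truth(sim_array, sim_normalized):
    """Direct/indirect recovery >= 0.95 sensitivity and specificity."""
    regions = collapse_to_regions(sim_normalized)
    truth = truth_by_locus(sim_array)
    tp = tn = fp = fn = 0
    for r in regions:
        classify_region(r, sim_array.config.direct_threshold)
        true_class = truth[(r.chrom, r.start)]["true_class"]
        if true_class == "direct":
            tp, fn = (tp + 1, fn) if r.binding_class == "direct" else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if r.binding_class == "indirect" else (tn, fp + 1)
    assert tp + tn + fp + fn == len(regions)
    assert tp / (tp + fn) >= 0.95
    assert tn / (tn + fp) >= 0.95
    # partition invariant
    classes = [r.binding_class for r in regions]
    assert classes.count("direct") + classes.count("indirect") == len(regions)
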