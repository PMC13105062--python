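"""Probe-library construction: tiling, mismatch and dimer libraries, hairpins."""

import logging
from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from snaparray.design import (
    DEFAULT_SCAFFOLD,
    Probe,
    ProbeDesignSpec,
    build_dimer_mismatch_library,
    build_dimer_spacing_library,
    build_hairpin_probe,
    build_monomer_mismatch_library,
    enumerate_mismatch_variants,
    tile_region,
)
from snaparray.motifs import hamming, min_window_distance, revcomp

CONSENSUS = "AACCGGTT"


@pytest.mark.parametrize("k,expected", [(0, 1), (1, 24), (2, 252), (3, 1512), (4, 5670)])
def test_enumerate_mismatch_variant_counts(k, expected):
    variants = enumerate_mismatch_variants(CONSENSUS, k)
    assert len(variants) == expected == comb(8, k) * 3**k
    assert len(set(variants)) == len(variants)
    assert all(hamming(v, CONSENSUS) == k for v in variants)
    assert (CONSENSUS in variants) == (k == 0)
    assert variants == sorted(variants)  # deterministic ordering


def test_enumerate_mismatch_variants_k_out_of_range():
    with pytest.raises(ValueError):
        enumerate_mismatch_variants(CONSENSUS, 9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=5), st.data())
def test_enumeration_partitions_full_sequence_space(motif, data):
    """Variant classes partition all 4^L sequences by Hamming distance."""
    from itertools import product

    k = data.draw(st.integers(min_value=0, max_value=len(motif)))
    variants = set(enumerate_mismatch_variants(motif, k))
    brute = {
        "".join(s)
        for s in product("ACGT", repeat=len(motif))
        if hamming("".join(s), motif) == k
    }
    assert variants == brute


class TestTiling:
    spec = ProbeDesignSpec()

    def test_exactly_one_window(self):
        probes = tile_region("A" * 20 + CONSENSUS + "C" * 20, ("chr1", 100, 148), self.spec)
        assert len(probes) == 1
        assert (probes[0].start, probes[0].end) == (100, 148)

    def test_offset_count(self):
        seq = (DEFAULT_SCAFFOLD * 2)[:102]
        probes = tile_region(seq, ("chr1", 0, 102), self.spec)
        assert len(probes) == 10  # offsets 0..54 by 6
        assert [p.start for p in probes] == list(range(0, 60, 6))

    def test_round_trip_substrings(self):
        seq = (DEFAULT_SCAFFOLD * 3)[:150]
        for p in tile_region(seq, ("chr2", 1000, 1150), self.spec):
            off = p.start - 1000
            assert p.sequence == seq[off : off + 48]
            assert p.end - p.start == self.spec.probe_len
            assert off % self.spec.tile_step == 0

    def test_short_region_skipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert tile_region("A" * 47, ("chr1", 0, 47), self.spec) == []
        assert "shorter than probe length" in caplog.text

    def test_oversized_region_excluded(self, caplog):
        seq = (DEFAULT_SCAFFOLD * 20)[:1100]
        with caplog.at_level(logging.WARNING):
            assert tile_region(seq, ("chr1", 0, 1100), self.spec) == []
        assert "exceeds" in caplog.text


class TestDimerSpacing:
    def test_ff_orientation_one_base_spacer(self):
        (probe,) = build_dimer_spacing_library(CONSENSUS, spacings=[1],
                                               orientations=["FF"])
        i = probe.sequence.find(CONSENSUS)
        assert probe.sequence[i + 9 : i + 17] == CONSENSUS
        assert probe.metadata["spacing"] == 1
        assert probe.metadata["center_spacing"] == 9

    def test_rf_orientation(self):
        (probe,) = build_dimer_spacing_library(CONSENSUS, spacings=[3],
                                               orientations=["RF"])
        left = probe.metadata["left_offset"]
        right = probe.metadata["right_offset"]
        assert probe.sequence[left : left + 8] == revcomp(CONSENSUS)
        assert probe.sequence[right : right + 8] == CONSENSUS
        assert right - (left + 8) == 3

    def test_full_series_size_and_uniform_length(self):
        probes = build_dimer_spacing_library(CONSENSUS, spacings=range(33),
                                             orientations=["FF", "RF"])
        assert len(probes) == 66
        assert {len(p.sequence) for p in probes} == {48}

    def test_spacing_too_large(self):
        with pytest.raises(ValueError, match="spacing"):
            build_dimer_spacing_library(CONSENSUS, spacings=[33])

    def test_flank_bases_come_from_scaffold(self):
        (probe,) = build_dimer_spacing_library(CONSENSUS, spacings=[2],
                                               orientations=["FF"])
        left = probe.metadata["left_offset"]
        right = probe.metadata["right_offset"]
        for i, ch in enumerate(probe.sequence):
            inside = left <= i < left + 8 or right <= i < right + 8
            if not inside:
                assert ch == DEFAULT_SCAFFOLD[i]


class TestDimerMismatch:
    def test_identical_pairing_one_mismatch(self):
        probes = build_dimer_mismatch_library(CONSENSUS, 1, 1, "identical")
        assert len(probes) == 24
        for p in probes:
            assert p.metadata["left_variant"] == p.metadata["right_variant"]
            assert p.metadata["left_mismatches"] == 1

    def test_consensus_dimer(self):
        (probe,) = build_dimer_mismatch_library(CONSENSUS, 0, 0, "identical")
        assert probe.sequence.count(CONSENSUS) >= 2

    def test_left_only(self):
        probes = build_dimer_mismatch_library(CONSENSUS, 2, 0, "left_only")
        assert len(probes) == 252
        assert all(p.metadata["right_variant"] == CONSENSUS for p in probes)

    def test_incompatible_pairing(self):
        with pytest.raises(ValueError):
            build_dimer_mismatch_library(CONSENSUS, 1, 2, "identical")
        with pytest.raises(ValueError):
            build_dimer_mismatch_library(CONSENSUS, 1, 1, "left_only")


class TestHairpin:
    def test_forced_construction(self):
        probe = build_hairpin_probe("A" * 25)
        assert probe.sequence == "A" * 25 + "TTT" + "T" * 25
        assert len(probe.sequence) == 53

    def test_self_complementarity_outside_loop(self):
        half = (DEFAULT_SCAFFOLD[:5] + CONSENSUS + DEFAULT_SCAFFOLD[13:25])[:25]
        probe = build_hairpin_probe(half)
        seq = probe.sequence
        comp = dict(zip("ACGT", "TGCA"))
        for i in range(25):
            assert seq[len(seq) - 1 - i] == comp[seq[i]]

    def test_motif_on_both_arms(self):
        half = DEFAULT_SCAFFOLD[:5] + CONSENSUS + DEFAULT_SCAFFOLD[13:25]
        probe = build_hairpin_probe(half[:25])
        # palindromic motif appears in the duplex arm and its complement arm
        assert probe.sequence.count(CONSENSUS) == 2

    def test_wrong_half_length(self):
        with pytest.raises(ValueError):
            build_hairpin_probe("ACGT")


def test_scaffold_contains_no_near_consensus_window():
    assert min_window_distance(DEFAULT_SCAFFOLD, CONSENSUS) >= 3


def test_monomer_mismatch_library():
    probes = build_monomer_mismatch_library(CONSENSUS, k=2)
    assert len(probes) == 252
    assert {len(p.sequence) for p in probes} == {48}


def test_probe_validation():
    with pytest.raises(ValueError):
        Probe("x", "ACGN", "genomic")
    with pytest.raises(ValueError):
        Probe("x", "ACGT", "mystery_class")
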