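"""Region chaining, strand classification, mixed splitting and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ggaasat.motif_scan import MotifOccurrence, find_motif_occurrences
from ggaasat.region_builder import (
    MIXED,
    PURE_FORWARD,
    PURE_REVERSE,
    StrandRunSummary,
    build_repeat_regions,
    classify_strand,
    compute_region_stats,
    filter_microsatellites,
    make_region,
    per_chromosome_profile,
    per_strand_runs,
    scan_sequence,
    split_mixed_region,
)

from .oracles import oracle_scan, random_motif_sequence


def occs(*items, chrom="chr1"):
    return [MotifOccurrence(chrom, s, s + 4, strand) for s, strand in items]


class TestChaining:
    def test_gap_of_20_merges(self):
        """The boundary case: motifs separated by exactly 20 insertions are
        one region."""
        regions = build_repeat_regions(occs((0, "+"), (24, "+")))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 28)
        assert regions[0].total_motifs == 2

    def test_gap_of_21_splits_and_singletons_dropped(self):
        assert build_repeat_regions(occs((0, "+"), (25, "+"))) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            build_repeat_regions(occs((24, "+"), (0, "+")))

    def test_multichromosome_input_rejected(self):
        mixed = occs((0, "+")) + occs((4, "+"), chrom="chr2")
        with pytest.raises(ValueError, match="chromosome"):
            build_repeat_regions(mixed)

    def test_region_bounds_are_motif_bounds(self):
        regions = build_repeat_regions(occs((5, "+"), (12, "-"), (20, "+")))
        assert (regions[0].start, regions[0].end) == (5, 24)

    def test_max_gap_monotonicity(self, rng):
        """Raising max_gap only coarsens the chaining: chained motifs never
        decrease and every smaller-gap region stays inside one larger-gap
        region."""
        layout = sorted(rng.choice(2000, size=60, replace=False) * 5)
        items = occs(*[(int(s), "+") for s in layout])
        prev = None
        prev_motifs = None
        for gap in (5, 10, 20, 40):
            regions = build_repeat_regions(items, max_gap=gap)
            n_motifs = sum(r.total_motifs for r in regions)
            if prev is not None:
                assert n_motifs >= prev_motifs
                for small in prev:
                    assert any(r.start <= small.start and small.end <= r.end
                               for r in regions)
            prev, prev_motifs = regions, n_motifs


class TestClassifyAndSplit:
    @pytest.mark.parametrize(
        "layout,expected",
        [
            ([(0, "+"), (4, "+")], PURE_FORWARD),
            ([(0, "+"), (8, "-")], MIXED),
            ([(0, "-"), (8, "-"), (16, "-")], PURE_REVERSE),
        ],
    )
    def test_strand_class(self, layout, expected):
        assert classify_strand(occs(*layout)) == expected

    def test_one_plus_one_mixed_discarded(self):
        region = make_region(occs((0, "+"), (10, "-")))
        assert split_mixed_region(region) == []

    def test_split_partitions_by_strand_runs(self):
        region = make_region(occs((0, "+"), (4, "+"), (12, "-")))
        parts = split_mixed_region(region)
        assert [(p.start, p.end, p.strand_class, p.total_motifs) for p in parts] == [
            (0, 8, PURE_FORWARD, 2),
            (12, 16, PURE_REVERSE, 1),
        ]

    def test_split_on_pure_region_is_contract_violation(self):
        region = make_region(occs((0, "+"), (4, "+")))
        with pytest.raises(ValueError):
            split_mixed_region(region)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("+-"), min_size=3, max_size=12),
           st.data())
    def test_split_conserves_occurrences(self, strands, data):
        """Every occurrence of a split mixed region appears in exactly one
        fragment (the 1+1 case is covered above)."""
        gaps = [data.draw(st.integers(min_value=0, max_value=20))
                for _ in range(len(strands) - 1)]
        layout = []
        pos = 0
        for i, strand in enumerate(strands):
            layout.append((pos, strand))
            pos += 4 + (gaps[i] if i < len(gaps) else 0)
        region = make_region(occs(*layout))
        if region.strand_class != MIXED:
            return
        parts = split_mixed_region(region)
        recovered = sorted(
            (o.start, o.strand) for p in parts for o in p.occurrences
        )
        assert recovered == sorted(layout)


class TestStats:
    def test_all_adjacent(self):
        stats = compute_region_stats(occs((0, "+"), (4, "+"), (8, "+")))
        assert stats == (3, 3, 100.0, 12)

    def test_gap_breaks_run_density_formula(self):
        """GGAAGGAA + 2 nt + GGAA: 3 motifs, longest run 2, density
        3*4/14*100."""
        stats = compute_region_stats(occs((0, "+"), (4, "+"), (10, "+")))
        assert stats.total_motifs == 3
        assert stats.max_consecutive == 2
        assert stats.length == 14
        assert stats.density == pytest.approx(3 * 4 / 14 * 100)

    def test_strand_switch_breaks_run(self):
        stats = compute_region_stats(occs((0, "+"), (4, "-"), (8, "-")))
        assert stats.max_consecutive == 2

    def test_density_100_iff_all_adjacent(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            gaps = rng.integers(0, 4, size=n - 1)
            layout, pos = [], 0
            for i in range(n):
                layout.append((pos, "+"))
                pos += 4 + (int(gaps[i]) if i < n - 1 else 0)
            stats = compute_region_stats(occs(*layout))
            assert 0 < stats.density <= 100
            assert (stats.density == 100) == all(g == 0 for g in gaps)


class TestMicrosatelliteFilter:
    def test_threshold_boundary(self):
        r2 = make_region(occs((0, "+"), (4, "+"), (12, "+")))  # runs 2,1
        r3 = make_region(occs((0, "+"), (4, "+"), (8, "+")))
        assert filter_microsatellites([r2, r3]) == [r3]

    def test_counts_by_threshold_match_brute_force(self, rng):
        regions = []
        for _ in range(100):
            n = int(rng.integers(2, 10))
            layout, pos = [], 0
            for i in range(n):
                layout.append((pos, "+"))
                pos += 4 + int(rng.integers(0, 3))
            regions.append(make_region(occs(*layout)))
        for thr in (1, 2, 3, 5):
            got = filter_microsatellites(regions, thr)
            assert got == [r for r in regions if r.max_consecutive >= thr]


class TestPerStrandRuns:
    @pytest.mark.parametrize(
        "layout,expected",
        [
            ([(0, "+"), (4, "+"), (12, "-")], (2, 1, 2, 1)),
            ([(0, "+"), (8, "-"), (12, "-")], (1, 2, 1, 2)),
        ],
    )
    def test_examples(self, layout, expected):
        summary = per_strand_runs(make_region(occs(*layout)))
        assert summary == StrandRunSummary(*expected)


class TestChromosomeProfile:
    def test_single_class_proportion_one(self):
        regions = [make_region(occs((i * 50, "+"), (i * 50 + 10, "+")))
                   for i in range(5)]
        profile = per_chromosome_profile(regions)
        assert profile["proportion"].tolist() == [1.0]
        assert profile["consecutive_class"].tolist() == ["1"]

    def test_planted_composition_recovered(self):
        regions = []
        # chr1: 3 regions of class 2, 1 of class 3; chr2: 2 of class 1
        for i in range(3):
            regions.append(make_region(occs((i * 100, "+"), (i * 100 + 4, "+"))))
        regions.append(make_region(occs((900, "+"), (904, "+"), (908, "+"))))
        for i in range(2):
            regions.append(
                make_region(occs((i * 100, "-"), (i * 100 + 10, "-"), chrom="chr2"))
            )
        profile = per_chromosome_profile(regions)
        chr1 = profile[profile.chrom == "chr1"].set_index("consecutive_class")
        assert chr1.loc["2", "proportion"] == pytest.approx(0.75)
        assert chr1.loc["3", "proportion"] == pytest.approx(0.25)
        totals = profile.groupby("chrom")["proportion"].sum()
        assert np.allclose(totals, 1.0)


class TestFullChainOracle:
    def test_scan_matches_brute_force(self, rng):
        """scan -> chain -> split -> stats agrees exactly with the
        transitive-closure reference on motif-rich random sequences."""
        for _ in range(50):
            seq = random_motif_sequence(rng)
            got = scan_sequence(seq, "c").final
            expected = oracle_scan(seq)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert (g.start, g.end, g.total_motifs, g.max_consecutive) == (
                    e["start"], e["end"], e["total"], e["max_consecutive"])
                assert g.density == pytest.approx(e["density"])

    def test_rebuild_idempotence(self, rng):
        """Re-running the builder on a final region's own occurrences
        reproduces the region."""
        seq = random_motif_sequence(rng)
        for region in scan_sequence(seq, "c").final:
            if region.total_motifs < 2:
                continue
            rebuilt = build_repeat_regions(list(region.occurrences))
            assert len(rebuilt) == 1
            assert rebuilt[0].key() == region.key()
            assert rebuilt[0].max_consecutive == region.max_consecutive
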