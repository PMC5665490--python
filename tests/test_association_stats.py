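"""Peak-microsatellite assignment, Spearman/LOESS, quadrant statistics."""

import math

import numpy as np
import pytest

from ggaasat.association_stats import (
    AssociationRecord,
    annotate_associations,
    assign_bound_microsatellites,
    filter_for_length_analysis,
    loess_trend,
    null_band,
    peaks_per_mb,
    quadrant_correlations,
    spearman,
    stratify_quadrants,
)
from ggaasat.io_formats import DERecord, GeneRecord, Peak
from ggaasat.motif_scan import MotifOccurrence
from ggaasat.region_builder import make_region
from ggaasat.synthetic_data import gaussian_copula_sample

from .oracles import oracle_spearman


def msat_at(midpoint, n_adjacent=3, chrom="chr1"):
    start = midpoint - 2 * n_adjacent
    occs = [MotifOccurrence(chrom, start + 4 * i, start + 4 * i + 4, "+")
            for i in range(n_adjacent)]
    return make_region(occs)


def peak_at(summit, fe=5.0, chrom="chr1", name="p"):
    return Peak(chrom=chrom, start=summit - 100, end=summit + 100, summit=summit,
                fold_enrichment=fe, name=name)


class TestAssignment:
    def test_nearest_midpoint_to_summit(self):
        msats = [msat_at(800), msat_at(1050)]
        records = assign_bound_microsatellites([peak_at(1000)], msats)
        assert len(records) == 1
        assert records[0].microsatellite.midpoint == 1050
        assert records[0].dist_to_summit == 50

    def test_equidistant_tie_smaller_start(self):
        msats = [msat_at(900), msat_at(1100)]
        records = assign_bound_microsatellites([peak_at(1000)], msats)
        assert records[0].microsatellite.midpoint == 900

    def test_dedup_keeps_strongest_peak(self):
        msats = [msat_at(1000)]
        peaks = [peak_at(990, fe=3.0, name="weak"), peak_at(1020, fe=9.0, name="strong")]
        records = assign_bound_microsatellites(peaks, msats)
        assert len(records) == 1
        assert records[0].peak.name == "strong"
        assert records[0].fold_enrichment == 9.0

    def test_peak_without_microsatellite_chromosome_unassigned(self):
        records = assign_bound_microsatellites([peak_at(1000, chrom="chrY")],
                                               [msat_at(1000)])
        assert records == []

    def test_matches_exhaustive_oracle(self, rng):
        msats = [msat_at(int(m)) for m in
                 np.sort(rng.choice(10**6, size=200, replace=False) + 100)]
        peaks = [peak_at(int(rng.integers(200, 10**6)), fe=float(i + 1), name=f"p{i}")
                 for i in range(300)]
        records = assign_bound_microsatellites(peaks, msats)
        expected = {}
        for p in peaks:
            best = min(msats, key=lambda m: (abs(m.midpoint - p.summit), m.start))
            cur = expected.get(best.key())
            if cur is None or p.fold_enrichment > cur.fold_enrichment:
                expected[best.key()] = p
        assert {r.microsatellite.key(): r.peak.name for r in records} == {
            k: p.name for k, p in expected.items()}


class TestLengthFilter:
    def test_cap_boundary(self):
        r20 = AssociationRecord(microsatellite=msat_at(1000, n_adjacent=20))
        r21 = AssociationRecord(microsatellite=msat_at(2000, n_adjacent=21))
        assert filter_for_length_analysis([r20, r21]) == [r20]

    def test_exclusion_count(self, rng):
        records = [AssociationRecord(microsatellite=msat_at(1000 + 500 * i,
                                                            n_adjacent=int(n)))
                   for i, n in enumerate(rng.integers(3, 40, size=60))]
        kept = filter_for_length_analysis(records)
        assert len(records) - len(kept) == sum(
            1 for r in records if r.max_consecutive > 20)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).r == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_too_few_or_degenerate(self):
        assert spearman([1, 2], [3, 4]).r is None
        assert spearman([1, 1, 1], [1, 2, 3]).r is None

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        """50 random tied-value vectors agree with midrank + Pearson to
        1e-12."""
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman(x, y)
            assert res.r == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100) + 0.5 * x
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base)
        assert spearman(x, y**3).r == pytest.approx(base)

    def test_copula_parameter_recovery(self, rng):
        """Gaussian-copula sample with target rank correlation 0.45 at
        n = 500 recovers Spearman r within 0.1."""
        x, y = gaussian_copula_sample(0.45, 500, rng)
        assert spearman(x, y).r == pytest.approx(0.45, abs=0.10)


class TestLoess:
    def test_reproduces_exact_line(self, rng):
        x = np.linspace(0, 10, 60)
        y = 3.0 * x - 2.0
        fit = loess_trend(x, y, degree=1)
        assert np.allclose(fit.mean, 3.0 * fit.x_grid - 2.0, atol=1e-8)
        fit2 = loess_trend(x, y, degree=2)
        assert np.allclose(fit2.mean, 3.0 * fit2.x_grid - 2.0, atol=1e-8)

    def test_constant_y_band_shrinks_with_n(self, rng):
        widths = []
        for n in (20, 200):
            x = np.linspace(0, 1, n)
            y = np.full(n, 2.5) + rng.normal(0, 0.1, size=n)
            fit = loess_trend(x, y)
            assert np.all(fit.band_low <= fit.mean)
            assert np.all(fit.mean <= fit.band_high)
            widths.append(np.mean(fit.band_high - fit.band_low))
        assert widths[1] < widths[0]

    def test_single_point_matches_direct_wls(self, rng):
        """The fit at one query point equals a directly solved
        tricube-weighted least squares."""
        x = np.sort(rng.uniform(0, 10, size=40))
        y = np.sin(x) + rng.normal(0, 0.2, size=40)
        x0 = 5.0
        span, degree = 0.5, 2
        fit = loess_trend(x, y, span=span, degree=degree, x_grid=[x0])
        k = math.ceil(span * len(x))
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3
        X = np.vander(x[idx] - x0, degree + 1, increasing=True)
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y[idx]))
        assert fit.mean[0] == pytest.approx(beta[0], rel=1e-8)

    def test_span_too_small_fatal(self):
        with pytest.raises(ValueError, match="span"):
            loess_trend(np.arange(12), np.arange(12.0), span=0.1, degree=2)


def _record(dist, regulation, lfc, fe=5.0, n_adjacent=4, mid=10_000):
    rec = AssociationRecord(microsatellite=msat_at(mid, n_adjacent=n_adjacent))
    rec.dist_to_tss = dist
    rec.regulation = regulation
    rec.log2fc = lfc
    rec.fold_enrichment = fe
    return rec


class TestQuadrants:
    def test_examples(self):
        quads, counts = stratify_quadrants([
            _record(4000, "activated", 2.0),
            _record(6000, "repressed", -1.0),
        ])
        assert len(quads[("promoter_like", "activated")]) == 1
        assert len(quads[("enhancer_like", "repressed")]) == 1
        assert counts["n"].sum() == 2

    def test_unchanged_excluded_partition_exhaustive(self, rng):
        records = []
        planted = {q: 0 for q in
                   [("promoter_like", "activated"), ("enhancer_like", "activated"),
                    ("promoter_like", "repressed"), ("enhancer_like", "repressed")]}
        for i in range(200):
            reg = ["activated", "repressed", "unchanged"][int(rng.integers(0, 3))]
            dist = float(rng.integers(0, 20_000))
            records.append(_record(dist, reg, 1.0 if reg == "activated" else -1.0,
                                   mid=1000 + 40 * i))
            if reg != "unchanged":
                rc = "promoter_like" if dist <= 5000 else "enhancer_like"
                planted[(rc, reg)] += 1
        quads, counts = stratify_quadrants(records)
        assert {k: len(v) for k, v in quads.items()} == planted
        n_unchanged = sum(1 for r in records if r.regulation == "unchanged")
        assert counts["n"].sum() == len(records) - n_unchanged

    def test_noiseless_monotone_enrichment_gives_r_one(self):
        records = [_record(1000, "activated", 1.0, fe=float(n), n_adjacent=n,
                           mid=10_000 * n)
                   for n in range(3, 15)]
        table = quadrant_correlations(records)
        r = table.loc[table.pair == "enrichment_vs_max_consecutive", "r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_independent_noise_within_null_band(self, rng):
        records = [_record(1000, "activated", float(rng.normal(1, 0.3)),
                           fe=float(rng.uniform(1, 10)),
                           n_adjacent=int(rng.integers(3, 20)), mid=10_000 + 50 * i)
                   for i in range(400)]
        table = quadrant_correlations(records)
        r = table.loc[table.pair == "expression_vs_max_consecutive", "r"].iloc[0]
        assert abs(r) < 0.15


class TestRegulationAnnotation:
    def test_fdr_and_sign_rules(self):
        msats = [msat_at(1000), msat_at(50_000)]
        records = [AssociationRecord(microsatellite=m, fold_enrichment=2.0)
                   for m in msats]
        genes = [GeneRecord("GA", "GA", "chr1", "+", 1500),
                 GeneRecord("GR", "GR", "chr1", "+", 49_000)]
        de = [DERecord("GA", 1.2, 0.01), DERecord("GR", -0.8, 0.2)]
        out = annotate_associations(records, genes, de)
        assert out[0].regulation == "activated"
        assert out[0].range_class == "promoter_like"
        assert out[1].regulation == "unchanged"  # fdr above cutoff
        de2 = [DERecord("GA", 1.2, 0.05), DERecord("GR", -0.8, 0.05)]
        out2 = annotate_associations(records, genes, de2)
        assert [r.regulation for r in out2] == ["activated", "repressed"]


def test_peaks_per_mb():
    peaks = [peak_at(1000 + i * 2000, chrom="chr1") for i in range(10)]
    table = peaks_per_mb(peaks, {"chr1": 2_000_000, "chr2": 1_000_000})
    by = table.set_index("chrom")
    assert by.loc["chr1", "peaks_per_mb"] == pytest.approx(5.0)
    assert by.loc["chr2", "peaks_per_mb"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        peaks_per_mb(peaks, {"chr1": 0})


def test_null_band_shrinks():
    assert null_band(101) == pytest.approx(1.96 / 10, abs=1e-3)
    assert null_band(401) < null_band(101)
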