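"""Stitching, tangent-cutoff ranking and nearest-gene assignment."""

import numpy as np
import pandas as pd
import pytest

import cistrio as c
from cistrio.superenhancer import StitchedRegion

from conftest import make_peaks, make_track, random_peakset


def regions_from_signals(signals, spacing=20_000, width=500):
    return [
        StitchedRegion(
            c.GenomicInterval("chr1", spacing * i + 1, spacing * i + 1 + width),
            1,
            (),
            float(s),
        )
        for i, s in enumerate(signals)
    ]


class TestStitch:
    def test_within_gap_merged(self):
        sites = make_peaks("e", [("chr1", 10_000, 10_500), ("chr1", 15_000, 15_500)])
        regions = c.stitch(sites)
        assert len(regions) == 1
        assert regions[0].constituent_count == 2
        assert (regions[0].interval.start, regions[0].interval.end) == (10_000, 15_500)

    def test_beyond_gap_separate(self):
        sites = make_peaks("e", [("chr1", 10_000, 10_500), ("chr1", 31_000, 31_500)])
        assert len(c.stitch(sites)) == 2

    def test_idempotent_and_coverage_superset(self, rng):
        sites = random_peakset(rng, 100, span=2_000_000, max_len=800)
        regions = c.stitch(sites)
        spans = make_peaks("spans", [
            (r.interval.chrom, r.interval.start, r.interval.end) for r in regions
        ])
        again = c.stitch(spans)
        assert len(again) == len(regions)
        # every input site is contained in some stitched region
        for row in sites.df.itertuples(index=False):
            assert any(
                r.interval.chrom == row.chrom
                and r.interval.start <= row.start
                and r.interval.end >= row.end
                for r in regions
            )

    def test_input_order_insensitive(self, rng):
        triples = [("chr1", int(s), int(s) + 400) for s in rng.integers(0, 500_000, 40)]
        a = c.stitch(make_peaks("x", triples))
        b = c.stitch(make_peaks("x", list(reversed(triples))))
        assert [(r.interval.start, r.interval.end) for r in a] == [
            (r.interval.start, r.interval.end) for r in b
        ]

    def test_tss_exclusion_drops_promoter_constituents(self):
        sites = make_peaks("e", [("chr1", 10_000, 10_500), ("chr1", 50_000, 50_500)])
        tss = pd.DataFrame(
            {"gene": ["G1"], "chrom": ["chr1"], "pos": [10_300], "strand": ["+"]}
        )
        regions = c.stitch(sites, tss_table=tss, tss_window=2000)
        assert len(regions) == 1
        assert regions[0].interval.start == 50_000


class TestScoreRegions:
    def test_signal_is_constituent_sum(self):
        sites = make_peaks("e", [("chr1", 10_000, 10_500), ("chr1", 15_000, 15_500)])
        regions = c.stitch(sites)
        track = make_track("k27", {"chr1": [10_100, 10_200, 15_100]}, 10_000_000)
        scored = c.score_regions(regions, track)
        assert scored[0].signal == pytest.approx(3.0)

    def test_control_subtraction_floored(self):
        sites = make_peaks("e", [("chr1", 10_000, 10_500)])
        regions = c.stitch(sites)
        track = make_track("k27", {"chr1": [10_100]}, 10_000_000)
        control = make_track("input", {"chr1": [10_100, 10_200, 10_300]}, 10_000_000)
        scored = c.score_regions(regions, track, control=control)
        assert scored[0].signal == 0.0


class TestRankAndCut:
    def test_quadratic_closed_form(self):
        # scaled curve y = x^2: tangent slope 1 at x = 0.5, cutoff y = 0.25
        n = 101
        res = c.rank_and_cut(regions_from_signals(np.linspace(0, 1, n) ** 2))
        assert res.cutoff_signal == pytest.approx(0.25, abs=1e-9)
        assert res.n_super == 50  # top half of the rank curve

    def test_linear_curve_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            res = c.rank_and_cut(regions_from_signals(np.linspace(0, 1, 50)))
        assert res.n_super == 0

    def test_all_equal_signals_rejected(self):
        with pytest.raises(ValueError):
            c.rank_and_cut(regions_from_signals(np.ones(10)))
        with pytest.raises(ValueError):
            c.rank_and_cut(regions_from_signals([1.0, 2.0]))

    def test_flags_invariant_under_affine_rescaling(self, rng):
        signals = rng.gamma(2.0, 1.0, size=500)
        signals[rng.choice(500, 20, replace=False)] += 40
        r1 = c.rank_and_cut(regions_from_signals(signals))
        r2 = c.rank_and_cut(regions_from_signals(3.5 * signals + 11.0))
        np.testing.assert_array_equal(r1.super_flags, r2.super_flags)

    def test_pareto_tail_recovery(self):
        cfg = c.SimulationConfig()
        signals, is_tail = c.simulate_enhancer_signals(cfg, 6000, 123)
        res = c.rank_and_cut(regions_from_signals(signals))
        flagged = res.n_super / 6000
        assert 0.02 <= flagged <= 0.08
        super_sigs = {round(r.signal, 9) for r in res.supers}
        recall = np.mean([round(s, 9) in super_sigs for s in signals[is_tail]])
        assert recall >= 0.9


class TestAssignNearestGene:
    def _tss(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [10_250, 50_000, 7_000],
                "strand": ["+", "-", "+"],
            }
        )

    def test_exact_tss_distance_zero(self):
        region = StitchedRegion(c.GenomicInterval("chr1", 10_000, 10_500), 1, (), 1.0)
        assignments, n = c.assign_nearest_gene([region], self._tss())
        assert assignments[0].gene == "A"
        assert assignments[0].distance == 0
        assert n == 1

    def test_shared_gene_deduplicated(self):
        r1 = StitchedRegion(c.GenomicInterval("chr1", 49_000, 49_200), 1, (), 1.0)
        r2 = StitchedRegion(c.GenomicInterval("chr1", 51_000, 51_200), 1, (), 1.0)
        assignments, n = c.assign_nearest_gene([r1, r2], self._tss())
        assert len(assignments) == 2
        assert n == 1

    def test_missing_chromosome_unassigned(self):
        region = StitchedRegion(c.GenomicInterval("chrY", 100, 200), 1, (), 1.0)
        assignments, n = c.assign_nearest_gene([region], self._tss())
        assert assignments == [] and n == 0

    def test_distance_tie_broken_lexicographically(self):
        tss = pd.DataFrame(
            {"gene": ["ZZZ", "AAA"], "chrom": ["chr1", "chr1"],
             "pos": [900, 1100], "strand": ["+", "+"]}
        )
        region = StitchedRegion(c.GenomicInterval("chr1", 950, 1050), 1, (), 1.0)
        assignments, _ = c.assign_nearest_gene([region], tss)
        assert assignments[0].gene == "AAA"

    def test_matches_exhaustive_oracle(self, rng):
        tss = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(200)],
                "chrom": rng.choice(["chr1", "chr2"], size=200),
                "pos": rng.integers(0, 1_000_000, size=200),
                "strand": "+",
            }
        )
        regions = []
        for i in range(50):
            s = int(rng.integers(0, 1_000_000))
            chrom = str(rng.choice(["chr1", "chr2"]))
            regions.append(StitchedRegion(c.GenomicInterval(chrom, s, s + 100), 1, (), 1.0))
        assignments, _ = c.assign_nearest_gene(regions, tss)
        for region, a in zip(regions, assignments):
            center = region.interval.center
            sub = tss[tss["chrom"] == region.interval.chrom]
            d = (sub["pos"] - center).abs()
            best = sub[d == d.min()]["gene"].min()
            assert a.gene == best
            assert a.distance == int(d.min())


class TestReadTss:
    def test_four_column_tsv(self, tmp_path):
        p = tmp_path / "tss.tsv"
        p.write_text("GENE1\tchr1\t1000\t+\nGENE2\tchr2\t2000\t-\n")
        df = c.read_tss(p)
        assert list(df["gene"]) == ["GENE1", "GENE2"]
        assert list(df["pos"]) == [1000, 2000]

    def test_bed6_strand_aware(self, tmp_path):
        p = tmp_path / "tss.bed"
        p.write_text("chr1\t1000\t2000\tGENE1\t0\t+\nchr1\t5000\t6000\tGENE2\t0\t-\n")
        df = c.read_tss(p)
        assert list(df["pos"]) == [1000, 5999]
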