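"""Binned density computation, normalization, and intensity correlation."""

import numpy as np
import pytest

import cistrio as c

from conftest import make_peaks, make_track


TEN_M = 10_000_000


class TestTagTrack:
    def test_tags_sorted_and_counted(self):
        t = make_track("t", {"chr1": [30, 10, 20]}, TEN_M)
        assert list(t.tags_for("chr1")) == [10, 20, 30]
        assert t.n_tags == 3

    def test_total_mapped_validation(self):
        with pytest.raises(ValueError):
            make_track("t", {"chr1": [1, 2, 3]}, total_mapped=2)
        with pytest.raises(ValueError):
            make_track("t", {}, total_mapped=0)

    def test_negative_positions_rejected(self):
        with pytest.raises(ValueError):
            make_track("t", {"chr1": [-5, 10]})


class TestBinnedDensity:
    def test_default_geometry_40_bins_of_100bp(self):
        sites = make_peaks("s", [("chr1", 10_000, 10_500)])
        track = make_track("t", {"chr1": [10_250]}, TEN_M)
        m = c.binned_density(sites, track)
        assert m.values.shape == (1, 40)
        assert m.bin_width == 100
        assert m.window == 4000

    def test_single_tag_unit_density(self):
        # 3 tags in one 100-bp bin of a 10M-read library -> density 3.0
        sites = make_peaks("s", [("chr1", 10_000, 10_500)])
        center = 10_250
        track = make_track("t", {"chr1": [center + 10, center + 20, center + 30]}, TEN_M)
        m = c.binned_density(sites, track)
        assert m.values[0, 20] == pytest.approx(3.0)
        assert m.values.sum() == pytest.approx(3.0)

    def test_zero_tag_row(self):
        sites = make_peaks("s", [("chr1", 10_000, 10_500)])
        track = make_track("t", {"chr1": []}, TEN_M)
        assert (c.binned_density(sites, track).values == 0).all()

    def test_boundary_tag_goes_to_right_bin(self):
        sites = make_peaks("s", [("chr1", 10_000, 10_500)])
        track = make_track("t", {"chr1": [10_250 - 2000 + 100]}, TEN_M)
        m = c.binned_density(sites, track)
        assert m.values[0, 0] == 0
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_depth_doubling_invariance(self, rng):
        sites = make_peaks("s", [("chr1", 10_000, 10_300), ("chr1", 50_000, 50_400)])
        tags = np.sort(rng.integers(8_000, 52_000, size=500))
        t1 = make_track("t", {"chr1": tags}, 1_000_000)
        t2 = make_track("t", {"chr1": np.sort(np.concatenate([tags, tags]))}, 2_000_000)
        m1 = c.binned_density(sites, t1)
        m2 = c.binned_density(sites, t2)
        np.testing.assert_allclose(m1.values, m2.values)

    def test_density_scales_with_library_size(self, rng):
        sites = make_peaks("s", [("chr1", 10_000, 10_300)])
        tags = np.sort(rng.integers(8_000, 12_000, size=200))
        m1 = c.binned_density(sites, make_track("t", {"chr1": tags}, 1_000_000))
        m5 = c.binned_density(sites, make_track("t", {"chr1": tags}, 5_000_000))
        np.testing.assert_allclose(m1.values, 5 * m5.values)

    def test_window_below_zero_clipped(self, caplog):
        sites = make_peaks("s", [("chr1", 100, 300)])
        track = make_track("t", {"chr1": [0, 50, 150]}, TEN_M)
        m = c.binned_density(sites, track)
        assert m.values.shape == (1, 40)
        assert m.values.sum() == pytest.approx(3.0)

    def test_bad_geometry_rejected(self):
        sites = make_peaks("s", [("chr1", 10_000, 10_500)])
        track = make_track("t", {"chr1": [1]}, TEN_M)
        with pytest.raises(ValueError):
            c.binned_density(sites, track, flank=2000, bin_width=300)


class TestMeanProfile:
    def test_identical_rows_and_halving(self):
        row = np.arange(40, dtype=float)
        m = c.BinnedMatrix(["a", "b"], 40, 100, np.vstack([row, row]))
        np.testing.assert_allclose(c.mean_profile(m), row)
        m2 = c.BinnedMatrix(["a", "b"], 40, 100, np.vstack([np.zeros(40), row]))
        np.testing.assert_allclose(c.mean_profile(m2), row / 2)

    def test_matches_columnwise_oracle(self, rng):
        vals = rng.random((100, 40))
        m = c.BinnedMatrix([str(i) for i in range(100)], 40, 100, vals)
        expected = np.array([vals[:, j].sum() / 100 for j in range(40)])
        np.testing.assert_allclose(c.mean_profile(m), expected)

    def test_empty_matrix_rejected(self):
        m = c.BinnedMatrix([], 40, 100, np.zeros((0, 40)))
        with pytest.raises(ValueError):
            c.mean_profile(m)


class TestSiteSignal:
    def test_zero_track_and_unit_tag(self):
        sites = make_peaks("s", [("chr1", 100, 200)])
        assert c.site_signal(sites, make_track("t", {"chr1": []}, TEN_M))[0] == 0.0
        assert c.site_signal(sites, make_track("t", {"chr1": [150]}, TEN_M))[0] == pytest.approx(1.0)

    def test_conservation_vs_binned_density(self, rng):
        # a site spanning exactly its own 4-kb window: bin sums == site_signal
        starts = rng.integers(10_000, 500_000, size=50)
        sites = make_peaks("s", [("chr1", int(s), int(s) + 4000) for s in starts])
        tags = np.sort(rng.integers(0, 600_000, size=20_000))
        track = make_track("t", {"chr1": tags}, TEN_M)
        m = c.binned_density(sites, track)
        np.testing.assert_allclose(m.values.sum(axis=1), c.site_signal(sites, track))


class TestCoverageTrack:
    def test_expected_counts_from_steps(self):
        cov = c.CoverageTrack(
            "bg", {"chr1": (np.array([100, 200]), np.array([200, 300]), np.array([1.0, 2.0]))},
            TEN_M,
        )
        assert cov.count_in("chr1", 150, 250) == pytest.approx(50 * 1.0 + 50 * 2.0)
        assert cov.count_in("chr1", 0, 50) == 0.0
        sites = make_peaks("s", [("chr1", 100, 300)])
        assert c.site_signal(sites, cov)[0] == pytest.approx(300.0)

    def test_bedgraph_reader(self, tmp_path):
        p = tmp_path / "x.bedgraph"
        p.write_text("chr1\t0\t100\t0.5\nchr1\t100\t200\t1.5\n")
        cov = c.CoverageTrack.from_bedgraph(p, TEN_M)
        assert cov.count_in("chr1", 50, 150) == pytest.approx(50 * 0.5 + 50 * 1.5)


class TestIntensityCorrelation:
    def test_affine_relation_r2_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = c.intensity_correlation(x, 2 * x + 1)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["r"] == pytest.approx(1.0)

    def test_orthogonal_r2_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert c.intensity_correlation(x, y)["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            c.intensity_correlation(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            c.intensity_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_ligand_independent_binding_high_r2(self):
        # two libraries from the same per-site rates (no condition effect):
        # peak intensities should correlate strongly across conditions
        from dataclasses import replace
        cfg = replace(c.SimulationConfig(seed=4), n_latent_sites=5000)
        sim = c.simulate_cistromes(cfg)
        enrich = cfg.anchor_enrichment_by_cardinality
        mult = np.array([enrich[int(x)] for x in sim.cardinality()])
        pre = c.simulate_tags(cfg, sim.anchor, mult, 101, "pre")
        post = c.simulate_tags(cfg, sim.anchor, mult, 202, "post")
        r2 = c.intensity_correlation(
            c.site_signal(sim.anchor, pre), c.site_signal(sim.anchor, post)
        )["r_squared"]
        assert r2 > 0.8
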