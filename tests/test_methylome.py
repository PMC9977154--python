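"""CpG tiling, coverage filtering, the beta-binomial DMR test and DMD
merging/clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oomics import methylome, simulate


def records_from_arrays(chrom, pos, meth, unmeth):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "unmeth": unmeth})


@pytest.fixture(scope="module")
def dense_genome():
    """Single chromosome dense in CpGs: ~2,200 100-CpG tiles."""
    return simulate.make_genome(
        sizes={"chr1": 5_000_000}, n_genes=30, n_cgis=50, n_ervs=10,
        cpg_density=0.042, seed=11,
    )


class TestTiling:
    def test_250_cpgs_give_2_tiles(self):
        pos = np.arange(250) * 10
        spans = methylome.tile_spans_from_positions(pos, n=100)
        assert len(spans) == 2
        assert spans[0].tolist() == [0, 991]
        assert spans[1].tolist() == [1000, 1991]

    def test_exactly_100_cpgs_span_first_to_last(self):
        pos = np.arange(100) * 7 + 3
        spans = methylome.tile_spans_from_positions(pos, n=100)
        assert spans.tolist() == [[3, 3 + 99 * 7 + 1]]

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            methylome.tile_spans_from_positions(np.array([5, 3, 9]))

    def test_tiles_partition_cpgs(self, dense_genome):
        pos = dense_genome.cpg_positions["chr1"]
        spans = methylome.tile_spans_from_positions(pos)
        assert len(spans) * 100 <= len(pos)
        # non-overlapping, ordered
        assert (spans[1:, 0] >= spans[:-1, 1]).all()


class TestCoverageFilterAndPercent:
    def _tiles(self, cov_a, cov_b):
        pos = np.arange(100)
        def spread(total):
            v = np.zeros(100, dtype=int)
            v[: min(total, 100)] = 1
            v[0] += max(total - 100, 0)
            return v
        rec = {
            "s1": records_from_arrays("chr1", pos, np.zeros(100, int), spread(cov_a)),
            "s2": records_from_arrays("chr1", pos, np.zeros(100, int), spread(cov_b)),
        }
        return methylome.tile_by_cpg(rec)

    def test_boundary_at_10_observed_cytosines(self):
        kept = methylome.coverage_filter(self._tiles(10, 10))
        assert len(kept.tiles) == 1
        dropped = methylome.coverage_filter(self._tiles(9, 1000))
        assert len(dropped.tiles) == 0

    def test_high_coverage_retention(self, dense_genome):
        rec, _, _ = simulate.simulate_bisulfite(
            dense_genome, {"control": 70.0, "mutant": 70.0},
            coverage_mean=30.0, n_replicates=2, seed=4,
        )
        tiles = methylome.tile_by_cpg(rec, positions=dense_genome.cpg_positions)
        kept = methylome.coverage_filter(tiles)
        assert len(kept.tiles) / len(tiles.tiles) >= 0.99

    def test_perbase_vs_pooled_modes(self):
        # CpG at 100% with coverage 10; CpG at 0% with coverage 1000
        rec = {"s": records_from_arrays("chr1", [0, 5], [10, 0], [0, 1000])}
        tiles = methylome.tile_by_cpg(rec, n=2)
        assert methylome.tile_percent(tiles, "per-base-mean")["s"].iloc[0] == pytest.approx(50.0)
        assert methylome.tile_percent(tiles, "pooled")["s"].iloc[0] == pytest.approx(
            10 / 1010 * 100, abs=0.01
        )

    def test_fully_methylated_both_modes(self):
        rec = {"s": records_from_arrays("chr1", np.arange(100), np.full(100, 7), np.zeros(100))}
        tiles = methylome.tile_by_cpg(rec)
        assert methylome.tile_percent(tiles, "per-base-mean")["s"].iloc[0] == 100.0
        assert methylome.tile_percent(tiles, "pooled")["s"].iloc[0] == 100.0

    def test_modes_agree_at_equal_coverage(self):
        rng = np.random.default_rng(0)
        meth = rng.integers(0, 21, 100)
        rec = {"s": records_from_arrays("chr1", np.arange(100), meth, 20 - meth)}
        tiles = methylome.tile_by_cpg(rec)
        assert methylome.tile_percent(tiles, "per-base-mean")["s"].iloc[0] == pytest.approx(
            methylome.tile_percent(tiles, "pooled")["s"].iloc[0]
        )


class TestDmrTest:
    def _tiles_from_counts(self, per_sample):
        """per_sample: dict name -> (meth_total, unmeth_total) on one tile."""
        rec = {}
        for name, (m, u) in per_sample.items():
            # whole totals on the first CpG (integer counts required by
            # the beta-binomial likelihood)
            meth = np.zeros(100, dtype=int)
            unmeth = np.zeros(100, dtype=int)
            meth[0], unmeth[0] = m, u
            rec[name] = records_from_arrays("chr1", np.arange(100), meth, unmeth)
        return methylome.tile_by_cpg(rec)

    def test_identical_groups_give_p_1(self):
        tiles = self._tiles_from_counts(
            {"a1": (50, 50), "a2": (60, 40), "b1": (50, 50), "b2": (60, 40)}
        )
        res = methylome.dmr_test(tiles, ["a1", "a2"], ["b1", "b2"])
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["diff"].iloc[0] == pytest.approx(0.0)

    def test_extreme_difference_agrees_with_fisher_oracle(self):
        # pooled (95,5) vs (5,95), split over 2 replicates each
        tiles = self._tiles_from_counts(
            {"a1": (48, 2), "a2": (47, 3), "b1": (2, 48), "b2": (3, 47)}
        )
        res = methylome.dmr_test(tiles, ["a1", "a2"], ["b1", "b2"])
        p_fisher = stats.fisher_exact([[95, 5], [5, 95]]).pvalue
        assert res["p"].iloc[0] > 0
        # deep-tail likelihood-ratio vs exact hypergeometric p-values:
        # the G-test runs slightly hotter (measured ratio ~20x here)
        assert abs(np.log10(res["p"].iloc[0]) - np.log10(p_fisher)) <= 1.5
        assert res["diff"].iloc[0] == pytest.approx(-90.0, abs=1.0)

    def test_zero_counts_in_group_skipped(self):
        tiles = self._tiles_from_counts(
            {"a1": (0, 0), "a2": (0, 0), "b1": (50, 50), "b2": (50, 50)}
        )
        res = methylome.dmr_test(tiles, ["a1", "a2"], ["b1", "b2"])
        assert np.isnan(res["p"].iloc[0])

    def test_null_pvalues_uniform_at_zero_dispersion(self, dense_genome):
        rec, grp, _ = simulate.simulate_bisulfite(
            dense_genome, {"control": 70.0, "mutant": 70.0},
            coverage_mean=30.0, beta_dispersion=0.0, n_replicates=2, seed=33,
        )
        tiles = methylome.coverage_filter(
            methylome.tile_by_cpg(rec, positions=dense_genome.cpg_positions)
        )
        ga = [s for s, g in grp.items() if g == "control"]
        gb = [s for s, g in grp.items() if g == "mutant"]
        res = methylome.dmr_test(tiles, ga, gb)
        p = res["p"].dropna().to_numpy()
        assert len(p) >= 2000
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCallAndMerge:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tile_id", "diff", "p"])
        df["n_cpgs"] = 100
        df["mean_a"] = 50.0
        df["mean_b"] = 50.0 + df["diff"]
        return df

    def test_difference_gate_blocks_small_effects(self):
        res = self._results([("chr1", 0, 1000, 0, 19.9, 1e-10)])
        dmrs = methylome.call_dmrs(res)
        assert not dmrs["call"].any()

    def test_direction_partition_exhaustive_exclusive(self):
        res = self._results(
            [("chr1", i * 1000, i * 1000 + 900, i, d, 1e-8)
             for i, d in enumerate([25, -30, 40, -22])]
        )
        dmrs = methylome.call_dmrs(res)
        assert dmrs["call"].all()
        assert set(dmrs["direction"]) == {"hyper", "hypo"}
        assert ((dmrs["direction"] == "hyper") == (dmrs["diff"] > 0)).all()

    def test_adjacent_same_direction_merge(self):
        res = self._results(
            [("chr1", 0, 1000, 0, 30, 1e-9), ("chr1", 1000, 2000, 1, 28, 1e-9)]
        )
        dmds = methylome.merge_dmrs(methylome.call_dmrs(res))
        assert len(dmds) == 1
        assert dmds["end"].iloc[0] == 2000

    def test_opposite_directions_never_merge(self):
        res = self._results(
            [("chr1", 0, 1000, 0, 30, 1e-9), ("chr1", 1000, 2000, 1, -28, 1e-9)]
        )
        dmds = methylome.merge_dmrs(methylome.call_dmrs(res))
        assert len(dmds) == 2

    def test_one_tile_gap_merges_two_does_not(self):
        res = self._results(
            [("chr1", 0, 1000, 0, 30, 1e-9), ("chr1", 2000, 3000, 2, 28, 1e-9),
             ("chr1", 6000, 7000, 5, 31, 1e-9)]
        )
        dmds = methylome.merge_dmrs(methylome.call_dmrs(res))
        assert len(dmds) == 2

    def test_merge_idempotent_and_order_invariant(self):
        rows = [("chr1", i * 1000, i * 1000 + 900, i, 30 if i % 3 else -30, 1e-9)
                for i in range(12)]
        res = methylome.call_dmrs(self._results(rows))
        a = methylome.merge_dmrs(res)
        b = methylome.merge_dmrs(res.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(a, b)


class TestClusterDomains:
    def test_planted_common_unique_blocks_recovered(self):
        rng = np.random.default_rng(5)
        dom = pd.DataFrame(
            {
                "direction": ["hyper"] * 40 + ["hypo"] * 40,
                "cko": np.r_[rng.normal(30, 3, 20), rng.normal(0, 3, 20),
                             rng.normal(-28, 3, 20), rng.normal(0, 3, 20)],
                "cdko": np.r_[rng.normal(30, 3, 40), rng.normal(-28, 3, 40)],
            }
        )
        out = methylome.cluster_domains(dom, ["cko", "cdko"])
        truth = np.array((["common"] * 20 + ["unique"] * 20) * 2)
        assert (out["cluster"].to_numpy() == truth).mean() >= 0.95

    def test_identical_columns_all_common(self):
        rng = np.random.default_rng(1)
        v = rng.normal(25, 5, 30)
        dom = pd.DataFrame({"direction": ["hyper"] * 30, "cko": v, "cdko": v})
        out = methylome.cluster_domains(dom, ["cko", "cdko"])
        # both k=2 clusters have zero cko-cdko gap; the deterministic
        # tie-break labels the lower-indexed cluster common
        assert (out.loc[out["cluster"] == "common"].shape[0] >= 1)
        rerun = methylome.cluster_domains(dom, ["cko", "cdko"])
        assert (out["cluster"] == rerun["cluster"]).all()

    def test_single_domain_labelled_common(self):
        dom = pd.DataFrame({"direction": ["hyper"], "cko": [20.0], "cdko": [25.0]})
        out = methylome.cluster_domains(dom, ["cko", "cdko"])
        assert (out["cluster"] == "common").all()


class TestRegionMethylation:
    def test_region_covering_tile_equals_tile_percent(self, dense_genome):
        rec, _, _ = simulate.simulate_bisulfite(
            dense_genome, {"control": 80.0, "mutant": 80.0},
            coverage_mean=20.0, n_replicates=1, seed=8,
        )
        tiles = methylome.tile_by_cpg(rec, positions=dense_genome.cpg_positions)
        first = tiles.tiles.iloc[0]
        region = pd.DataFrame(
            {"chrom": [first["chrom"]], "start": [first["start"]], "end": [first["end"]]}
        )
        rm = methylome.region_methylation(region, rec)
        for s in rec:
            assert rm[s].iloc[0] == pytest.approx(tiles.pct[s].iloc[0])

    def test_fully_methylated_region_is_100(self):
        rec = {"s": records_from_arrays("chr1", np.arange(50), np.full(50, 5), np.zeros(50))}
        rm = methylome.region_methylation(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}), rec
        )
        assert rm["s"].iloc[0] == 100.0

    def test_partition_recombines_with_cpg_weights(self):
        rng = np.random.default_rng(2)
        meth = rng.integers(0, 10, 60)
        rec = {"s": records_from_arrays("chr1", np.arange(60) * 10, meth, 10 - meth)}
        whole = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [600]})
        parts = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 300], "end": [300, 600]}
        )
        rw = methylome.region_methylation(whole, rec)["s"].iloc[0]
        rp = methylome.region_methylation(parts, rec)["s"]
        n1 = ((np.arange(60) * 10) < 300).sum()
        n2 = 60 - n1
        assert rw == pytest.approx((rp.iloc[0] * n1 + rp.iloc[1] * n2) / 60)

    def test_uncovered_region_flagged_nan(self):
        rec = {"s": records_from_arrays("chr1", [1000], [1], [1])}
        rm = methylome.region_methylation(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}), rec
        )
        assert np.isnan(rm["s"].iloc[0])


class TestBisulfiteSimulator:
    def test_fully_methylated_group_has_no_unmethylated_calls(self, small_genome):
        rec, _, _ = simulate.simulate_bisulfite(
            small_genome, {"control": 100.0, "mutant": 100.0},
            coverage_mean=10.0, beta_dispersion=0.05, n_replicates=1, seed=2,
        )
        for df in rec.values():
            assert (df["unmeth"] == 0).all()

    def test_planted_30_point_shift_realised(self, dense_genome):
        eff = simulate.plant_dmr_tiles(
            dense_genome, n_tiles=200, effect=30.0, hyper_fraction=1.0, seed=5
        )
        rec, grp, _ = simulate.simulate_bisulfite(
            dense_genome, {"control": 50.0, "mutant": 50.0}, eff,
            coverage_mean=30.0, beta_dispersion=0.02, n_replicates=2, seed=22,
        )
        tiles = methylome.tile_by_cpg(rec, positions=dense_genome.cpg_positions)
        ga = [s for s, g in grp.items() if g == "control"]
        gb = [s for s, g in grp.items() if g == "mutant"]
        diff = tiles.pct[gb].mean(axis=1) - tiles.pct[ga].mean(axis=1)
        realised = diff.iloc[eff["tile_id"].to_numpy()].mean()
        assert realised == pytest.approx(30.0, abs=3.0)

    def test_null_two_proportion_z_uniform(self, dense_genome):
        rec, grp, _ = simulate.simulate_bisulfite(
            dense_genome, {"control": 60.0, "mutant": 60.0},
            coverage_mean=30.0, beta_dispersion=0.0, n_replicates=1, seed=44,
        )
        tiles = methylome.coverage_filter(
            methylome.tile_by_cpg(rec, positions=dense_genome.cpg_positions)
        )
        m = tiles.meth.to_numpy(float)
        t = tiles.obs.to_numpy(float)
        p1, p2 = m[:, 0] / t[:, 0], m[:, 1] / t[:, 1]
        pool = m.sum(axis=1) / t.sum(axis=1)
        se = np.sqrt(pool * (1 - pool) * (1 / t[:, 0] + 1 / t[:, 1]))
        z = (p1 - p2) / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_determinism(self, small_genome):
        a, _, _ = simulate.simulate_bisulfite(
            small_genome, {"control": 70.0, "mutant": 70.0}, seed=9
        )
        b, _, _ = simulate.simulate_bisulfite(
            small_genome, {"control": 70.0, "mutant": 70.0}, seed=9
        )
        for s in a:
            pd.testing.assert_frame_equal(a[s], b[s])
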